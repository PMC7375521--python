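lab_id,period,site,taxon,element,pct_N_bone,yield_mg_g,pct_C_coll,pct_N_coll,cn_ratio,d13C,d15N
PLC-79,MP,BS,Canis lupus,Radius,1.7,56.0,34.0,11.8,3.4,-20.1,10.6
PLC-35,MP,HS,Canis lupus,Ulna,2.2,64.7,35.2,12.4,3.3,-20.0,7.7
PLC-37,MP,HS,Canis lupus,Mandible,1.1,33.8,34.6,12.1,3.3,-20.1,8.5
PLC-38,MP,HS,Canis lupus,Mandible,2.1,74.4,33.6,11.8,3.3,-19.4,10.0
PLC-48,MP,VH,Canis lupus,Astragalus,2.4,104.5,38.8,13.6,3.3,-19.2,8.3
PLC-49,MP,VH,Canis lupus,Tibia,2.3,119.2,42.2,14.4,3.4,-19.7,7.3
PLC-76,MP,BS,Vulpes lagopus,Mandible,0.9,27.3,40.0,13.3,3.5,-21.4,1.0
PLC-80,MP,BS,Vulpes vulpes,Tibia,0.8,41.7,26.4,9.1,3.4,-19.7,10.0
PLC-82,MP,BS,Vulpes vulpes,Radius,1.5,71.5,42.5,15.0,3.3,-20.2,7.8
PLC-83,MP,BS,Vulpes vulpes,Humerus,2.7,135.2,43.1,15.3,3.3,-20.4,8.2
PLC-84,MP,BS,Vulpes vulpes,Mandible,0.9,34.0,26.7,9.2,3.4,-20.1,9.0
VLP-10,MP,HF,Vulpes vulpes,Tibia,3.7,73.2,42.0,14.9,3.3,-21.1,3.0
PLC-39,MP,HS,Vulpes vulpes,Mandible,2.8,142.4,39.8,14.0,3.3,-20.3,8.4
PLC-40,MP,HS,Vulpes vulpes,Ulna,2.5,103.5,41.7,14.6,3.3,-19.9,8.6
PLC-78,A,BS,Canis lupus,Tibia,2.9,107.0,41.0,14.6,3.3,-19.5,8.5
JK2175,A,HF,Canis lupus,Ulna,2.5,67.2,34.4,12.2,3.3,-19.5,10.7
JK2180,A,HF,Canis lupus,Humerus,3.1,110.3,40.9,14.6,3.3,-18.6,8.3
JK2184,A,HF,Canis lupus,Metacarpal IV,3.4,96.8,40.2,14.3,3.3,-18.9,10.0
PLC-24,A,HS,Canis lupus,Mandible,1.0,43.6,17.2,6.1,3.3,-19.1,9.5
PLC-25,A,HS,Canis lupus,Mandible,0.6,14.9,34.8,12.2,3.3,-19.0,9.6
PLC-29,A,HS,Canis lupus,Ulna,2.8,108.4,41.8,14.8,3.3,-19.4,10.7
PLC-30,A,HS,Canis lupus,Atlas,2.5,85.0,40.1,14.1,3.3,-19.7,9.2
PLC-31,A,HS,Canis lupus,Ulna,1.9,74.7,42.2,14.6,3.4,-19.0,9.8
PLC-32,A,HS,Canis lupus,Humerus,3.2,158.8,41.9,14.8,3.3,-19.5,8.5
PLC-2,A,VH,Canis lupus,Radius,3.2,145.1,41.7,14.7,3.3,-20.2,9.1
PLC-3,A,VH,Canis lupus,Atlas,0.9,27.9,35.9,12.5,3.3,-21.0,9.4
PLC-44,A,VH,Canis lupus,Metacarpal,2.8,127.0,42.8,14.9,3.3,-18.9,9.6
PLC-45,A,VH,Canis lupus,Tibia,1.6,63.4,41.7,14.7,3.3,-20.4,9.5
PLC-46,A,VH,Canis lupus,Ulna,3.2,132.7,40.7,14.5,3.3,-19.7,9.3
PLC-47,A,VH,Canis lupus,Ulna,2.3,77.4,38.1,13.4,3.3,-19.2,8.9
PLC-62,A,Si,Gulo gulo,Femur,2.1,67.3,34.8,12.4,3.3,-19.1,9.4
PLC-17,A,GK,Lynx lynx,Phalanx,,117.6,40.0,14.1,3.3,-19.3,7.7
PLC-23,A,HS,Lynx lynx,Humerus,2.6,79.8,40.4,14.2,3.3,-19.3,10.2
PLC-63,A,Si,Lynx lynx,Tibia,2.9,132.7,43.2,15.1,3.3,-19.8,7.0
VLP-1,A,GK,Vulpes lagopus,Tibia,3.1,105.3,43.8,15.4,3.3,-20.6,9.1
VLP-3,A,HF,Vulpes lagopus,Radius,2.8,76.0,43.1,15.1,3.3,-19.9,8.6
PLC-22,A,HS,Vulpes lagopus,Mandible,2.9,133.8,42.8,14.7,3.4,-20.2,5.4
PLC-28,A,HS,Vulpes lagopus,Mandible,2.1,62.9,35.9,12.6,3.3,-19.7,8.6
PLC-55,A,HS,Vulpes lagopus,Mandible,1.6,31.2,16.9,6.1,3.2,-20.1,8.9
PLC-1,A,VH,Vulpes lagopus,Tibia,2.6,113.6,41.9,14.6,3.4,-18.4,8.7
PLC-16,A,VH,Vulpes lagopus,Mandible,1.2,50.6,32.7,11.6,3.3,-19.4,9.4
PLC-15,A,VH,Vulpes sp.,Mandible,1.4,56.7,35.1,12.2,3.4,-20.4,8.9
PLC-85,A,BS,Vulpes vulpes,Tibia,2.5,112.4,43.9,15.5,3.3,-20.2,8.3
PLC-26,A,HS,Vulpes vulpes,Mandible,0.8,30.9,27.2,9.6,3.3,-19.8,8.1
PLC-27,A,HS,Vulpes vulpes,Humerus,0.6,23.9,17.2,6.2,3.2,-20.2,8.2
PLC-66,A,Si,Vulpes vulpes,Mandible,1.8,76.3,40.5,13.8,3.4,-20.3,8.0
PLC-67,A,Si,Vulpes vulpes,Mandible,2.6,143.8,42.2,14.8,3.3,-21.0,8.2
PLC-68,A,Si,Vulpes vulpes,Humerus,2.7,138.6,42.6,14.8,3.4,-20.4,6.0
PLC-69,A,Si,Vulpes vulpes,Tibia,3.2,150.0,43.4,15.1,3.4,-20.0,4.8
PLC-10,A,VH,Vulpes vulpes,Tibia,1.1,36.2,37.7,13.1,3.4,-19.2,8.2
PLC-11,A,VH,Vulpes vulpes,Radius,3.2,148.2,42.3,14.9,3.3,-19.6,9.1
PLC-13,A,VH,Vulpes vulpes,Mandible,2.3,112.6,38.9,13.6,3.3,-20.0,4.7
PLC-14,A,VH,Vulpes vulpes,Mandible,1.1,42.8,34.1,11.9,3.4,-20.0,5.5
PLC-8,A,VH,Vulpes vulpes,Femur,2.8,58.4,40.7,14.4,3.3,-20.1,8.3
PLC-9,A,VH,Vulpes vulpes,Tibia,1.6,44.7,31.6,11.2,3.3,-19.4,5.7
JK2174,G,HF,Canis lupus,Scapula,3.5,144.8,39.6,14.1,3.3,-20.2,9.7
JK2183,G,HF,Canis lupus,Calcaneus,3.4,155.7,40.9,14.4,3.3,-20.2,9.3
JK2178,G,HF,Canis lupus,Metacarpale II,3.7,11.9,40.6,14.5,3.3,-19.5,8.9
PLC-70,G,Si,Gulo gulo,Scapula,3.1,165.1,41.7,14.8,3.3,-19.1,7.6
PLC-18,G,GK,Lynx lynx,Rib,2.0,96.2,42.5,14.8,3.3,-19.5,8.4
PLC-19,G,GK,Lynx lynx,Mandible,3.6,137.2,42.6,14.8,3.3,-18.7,8.0
PLC-77,G,BS,Vulpes lagopus,Ulna,2.2,97.6,41.6,14.7,3.3,-20.1,8.7
PLC-42,G,Si,Vulpes lagopus,Mandible,2.8,138.2,42.4,14.8,3.3,-20.3,7.6
VLP-4,G,GK,Vulpes vulpes,Tibia,3.2,109.8,44.2,15.3,3.4,-19.7,7.1
VLP-5,G,GK,Vulpes vulpes,Tibia,3.1,109.7,44.3,15.3,3.4,-19.7,9.7
PLC-43,G,Si,Vulpes vulpes,Mandible,3.2,166.9,43.9,15.1,3.4,-19.7,4.0
PLC-71,G,Si,Vulpes vulpes,Humerus,3.1,157.9,43.0,14.7,3.4,-20.5,6.0
PLC-72,G,Si,Vulpes vulpes,Mandible,2.6,139.4,42.5,14.7,3.4,-19.4,6.7
PLC-73,G,Si,Vulpes vulpes,Humerus,2.8,135.5,44.0,14.9,3.4,-19.6,3.7
PLC-75,G,Si,Vulpes vulpes,Tibia,1.5,54.4,32.3,11.2,3.4,-20.3,9.2
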