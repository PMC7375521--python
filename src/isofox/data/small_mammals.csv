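lab_id,period,site,taxon,element,pct_N_bone,yield_mg_g,pct_C_coll,pct_N_coll,cn_ratio,d13C,d15N
SJM-54,A,HF,Dicrostonyx sp.,Mandible,,33.4,31.3,11.3,3.2,-21.2,6.4
SJM-55,A,HF,Dicrostonyx sp.,Mandible,,41.5,29.5,10.6,3.2,-20.3,7.1
SJM-56,A,HF,Dicrostonyx sp.,Mandible,,68.6,23.9,8.7,3.2,-20.9,5.2
SJM-57,A,HF,Lemmus lemmus,Mandible,,51.0,36.8,13.0,3.3,-21.4,5.2
SJM-58,A,HF,Lemmus lemmus,Mandible,,47.6,27.7,9.7,3.3,-22.8,6.6
SJM-59,A,HF,Lemmus lemmus,Mandible,,59.5,28.4,10.1,3.3,-21.6,3.9
SJM-60,A,HF,Lemmus lemmus,Mandible,,57.5,30.1,10.6,3.3,-20.9,5.6
SJM-61,A,HF,Lemmus lemmus,Mandible,,51.9,32.2,11.5,3.3,-21.7,4.2
SJM-62,A,HF,Microtus arvalis/agrestis,Mandible,,31.2,21.9,7.6,3.4,-22.1,3.8
SJM-63,A,HF,Microtus arvalis/agrestis,Mandible,,41.3,23.3,8.0,3.4,-21.8,4.5
SJM-50,G,HF,Dicrostonyx sp.,Mandible,,64.5,31.9,11.5,3.2,-21.1,3.6
SJM-51,G,HF,Dicrostonyx sp.,Mandible,,75.6,32.4,11.4,3.3,-21.3,6.1
SJM-52,G,HF,Dicrostonyx sp.,Mandible,,71.8,34.7,12.3,3.3,-20.2,3.5
VLP-12,G,GK,Lepus sp.,Tibia,3.0,92.2,43.4,15.3,3.3,-20.4,2.8
VLP-13,G,GK,Lepus sp.,Tibia,2.6,59.1,43.6,15.5,3.3,-20.2,3.5
SJM-53,G,HF,Microtus arvalis/agrestis,Mandible,,20.4,30.9,11.1,3.2,-21.7,3.0
SJM-7,MP,HF,Dicrostonyx sp.,Mandible,,61.0,33.1,11.7,3.3,-21.2,5.5
SJM-8,MP,HF,Dicrostonyx sp.,Mandible,,42.1,29.7,10.7,3.2,-21.0,6.7
SJM-9,MP,HF,Dicrostonyx sp.,Mandible,,70.1,32.9,11.6,3.3,-21.2,7.1
SJM-11,MP,HF,Dicrostonyx sp.,Mandible,,86.8,25.1,8.0,3.6,-25.1,-1.5
SJM-1,MP,HF,Lemmus lemmus,Mandible,,52.3,34.7,12.2,3.3,-21.8,5.9
SJM-2,MP,HF,Lemmus lemmus,Mandible,,60.1,33.6,11.8,3.3,-22.2,4.8
SJM-3,MP,HF,Lemmus lemmus,Mandible,,44.8,32.7,11.5,3.3,-20.7,6.5
SJM-4,MP,HF,Lemmus lemmus,Mandible,,55.4,35.4,12.2,3.4,-22.0,5.8
SJM-5,MP,HF,Lemmus lemmus,Mandible,,69.5,33.8,11.7,3.4,-21.9,7.3
SJM-6,MP,HF,Lemmus lemmus,Mandible,,72.0,32.0,11.4,3.3,-21.8,6.8
SJM-12,MP,HF,Lemmus lemmus,Mandible,,54.7,30.9,11.3,3.2,-23.1,1.0
SJM-13,MP,HF,Lemmus lemmus,Mandible,,70.3,31.1,11.3,3.2,-23.2,5.2
SJM-14,MP,HF,Lemmus lemmus,Mandible,,68.0,25.3,9.2,3.2,-24.9,-0.6
SJM-15,MP,HF,Lemmus lemmus,Mandible,,86.0,27.7,9.3,3.5,-24.6,1.0
SJM-16,MP,HF,Lemmus lemmus,Mandible,,70.5,26.0,8.4,3.6,-24.5,0.6
SJM-17,MP,HF,Lemmus lemmus,Mandible,,79.3,28.5,10.5,3.2,-22.9,2.5
SJM-18,MP,HF,Lemmus lemmus,Mandible,,60.2,26.7,8.9,3.5,-23.5,2.5
SJM-10,MP,HF,Microtus arvalis/agrestis,Mandible,,63.1,30.4,10.9,3.3,-22.4,7.3
SJM-29,MP,HF,Microtus arvalis/agrestis,Mandible,,44.3,27.8,9.4,3.5,-22.5,7.9
SJM-30,MP,HF,Microtus arvalis/agrestis,Mandible,,48.2,25.7,9.0,3.3,-22.1,4.5
SJM-31,MP,HF,Microtus arvalis/agrestis,Mandible,,30.1,25.2,8.6,3.4,-22.6,6.7
SJM-32,MP,HF,Microtus arvalis/agrestis,Mandible,,59.3,26.9,9.2,3.4,-23.0,7.4
SJM-33,MP,HF,Microtus arvalis/agrestis,Mandible,,45.1,25.7,8.7,3.4,-23.1,5.4
SJM-34,MP,HF,Microtus arvalis/agrestis,Mandible,,67.1,21.4,7.9,3.2,-22.0,5.7
SJM-35,MP,HF,Microtus arvalis/agrestis,Mandible,,47.3,25.1,8.8,3.3,-22.7,4.4
SJM-36,MP,HF,Microtus arvalis/agrestis,Mandible,,59.3,23.2,7.9,3.5,-22.2,5.9
SJM-37,MP,HF,Microtus arvalis/agrestis,Mandible,,65.6,22.6,8.2,3.2,-21.8,5.7
SJM-38,MP,HF,Microtus arvalis/agrestis,Mandible,,63.1,23.4,8.4,3.2,-23.0,6.2
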