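# isofox

Stable-isotope trophic ecology of bone collagen: quality control,
isotopic-niche geometry, and Bayesian mixing-model diet reconstruction.

The package is built for palaeoecologists working with δ13C/δ15N collagen
records — its packaged study data are the Middle Palaeolithic, Aurignacian
and Gravettian foxes, large carnivores and small mammals of the Swabian
Jura cave sites — but every component takes ordinary tabular isotope data
and works for any bivariate isospace.

## What it computes

**Collagen QC.** Samples are screened by atomic C:N ratio (2.9 ≤ C:N ≤ 3.6,
bounds inclusive) and collagen nitrogen content (%N > 5, strict), the
standard diagenesis criteria; rejected samples carry reason codes.

**Niche geometry.** For a group of points in isospace (x = δ13C, y = δ15N):

- total area `TA` — the convex-hull area (the "complete niche");
- standard ellipse area `SEA = π·sqrt(det S)` with S the sample covariance
  (the 1-SD ellipse, covering 1 − e^(−1/2) ≈ 40% of a bivariate normal —
  the "core niche");
- small-sample correction `SEAc = SEA·(n−1)/(n−2)`;
- a Bayesian posterior for the ellipse area under a vague
  normal–inverse-Wishart prior;
- pairwise SEAc-ellipse overlap by polygon clipping, reported in ‰² and as
  a percentage of each ellipse's own area.

**Diet reconstruction.** A Bayesian mixing model over K prey sources with
a trophic enrichment factor Δ (defaults Δ13C = 1.1 ± 1.1‰,
Δ15N = 3.2 ± 1.8‰). For diet proportions p on the simplex, isotope j of a
consumer is normal with

    mean_j = Σ_k p_k (μ_kj + Δ_j)        var_j = Σ_k p_k² (σ_kj² + σ_Δj²)

under a Dirichlet(1) prior, sampled by random-walk Metropolis in isometric
log-ratio coordinates with step adaptation during burn-in. Convergence is
reported as Gelman–Rubin R̂ (acceptable ≤ 1.1, strict ≤ 1.01) and per-chain
Geweke z-scores (first 10% vs last 50%, AR-spectral long-run variances).

A synthetic-data module generates bivariate-normal source/niche clouds and
forward-model consumers with known diets, so the whole pipeline is testable
end to end with recorded ground truth.

## Worked example

```python
import numpy as np
from isofox import Period, StandardEllipse, DietMixingModel, datasets

# core niche of the Middle-Palaeolithic high-d15N foxes (n = 6)
pts = datasets.fox_niche_points("high", Period.MP)
niche = StandardEllipse().fit(pts)
print(f"SEA {niche.sea_:.2f}  SEAc {niche.seac_:.2f}")

# diet of the two low-d15N foxes against the four published prey groups
X = datasets.fox_niche_points("low")
model = DietMixingModel(sources=datasets.prey_group_sources(),
                        chains=3, iterations=100_000, burn_in=50_000,
                        random_state=1).fit(X)
print(model.posterior_.summary_percent()[["mean", "sd", "q50"]])
print("max Rhat", max(model.convergence_.rhat.values()))
```

prints

```
SEA 0.38  SEAc 0.47
          mean   sd   q50
Horse      5.7  5.1   4.3
Mammoth    4.5  4.0   3.4
Reindeer   7.8  6.6   6.1
Rodents   82.0  7.8  82.6
max Rhat 1.0002622700736619
```

The ellipse areas are the published core-niche values for that group, and
the posterior says the two low-δ15N foxes drew about four fifths of their
dietary protein from rodents — the classic rodent-hunting fox, in contrast
to the carrion-feeding high-δ15N niche.

The same pipeline is scriptable from the shell:

```sh
isofox all --seed 1 --profile ci --out run1   # qc -> group -> niche -> diet
isofox simulate --seed 7 --out sim1           # synthetic study + truth file
```

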