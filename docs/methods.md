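# Methods

This note documents the models implemented in `isofox`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Data model and quality control

A record is one bone: lab id, period (Middle Palaeolithic, Aurignacian,
Gravettian), site code, taxon, skeletal element, the collagen-chemistry
block (%N of whole bone, collagen yield in mg/g, %C and %N of the extract,
atomic C:N) and the isotope pair δ13C (‰ vs V-PDB) and δ15N (‰ vs AIR).
Validation bounds (δ13C ∈ (−35, −5), δ15N ∈ (−10, +25), C:N > 0) are broad
plausibility checks for collagen, not QC.

QC keeps a sample when 2.9 ≤ C:N ≤ 3.6 **and** %N_coll > 5. The C:N bounds
are inclusive — the packaged small-mammal table contains a reported record
with C:N exactly 3.6 — while the nitrogen threshold is strict ("higher
than 5%"). The nitrogen criterion is applied to collagen %N, not whole-bone
%N: every packaged %N_coll value exceeds 5, consistent with that reading,
whereas %N_bone values are all below 4. Samples missing either field are
rejected with reason `MISSING`, never imputed. All 114 packaged records
pass (C:N spans 3.2–3.6).

Group summaries are arithmetic means and sample SDs (n−1); SDs are
reported as missing for n = 1. Report output rounds ‰ to one decimal.

Two-sample t-tests offer the pooled-variance statistic
(df = n₁ + n₂ − 2, the default) and Welch with Satterthwaite df. On the
packaged rodent data (Aurignacian vs Gravettian δ13C) both variants give
p ≈ 0.35; for δ15N they differ (pooled 0.12, Welch 0.19) — the Welch flag
exists for exactly this kind of sensitivity check.

## Niche assignment

Fox niches are defined by closed δ15N windows: high [+7.1, +10.0],
intermediate [+3.7, +6.7], low [+1.0, +3.0] ‰, applied to the pooled fox
samples (red fox, Arctic fox and indeterminate *Vulpes* together, since
the two species are isotopically indistinguishable in this assemblage).
Windows must be disjoint, so assignment is order-independent and
idempotent; values outside every window are flagged unassigned.

Ward hierarchical clustering (Euclidean distance on raw ‰ coordinates, no
axis standardization — the larger δ15N spread is *meant* to dominate) is
provided as an advisory cross-check. On the packaged data it reproduces
the threshold memberships for the Middle Palaeolithic and Aurignacian; in
the Gravettian the high/intermediate boundary (6.7 vs 7.1‰) is narrower
than within-niche gaps and no agglomerative cut reproduces it, which is
why the window rules, not the clustering, are the canonical path. Cluster
labels are relabelled by first appearance, making the output deterministic
for a fixed input order.

## Niche geometry

With S the n−1 sample covariance of a group's (δ13C, δ15N) points:

* `TA` — convex-hull area (shoelace formula on the hull vertices; needs
  ≥ 3 non-collinear points). Sensitive to n by construction.
* `SEA = π √det S` — area of the 1-SD standard ellipse, containing
  1 − e^(−1/2) ≈ 39.35% ("40%") of a bivariate normal. No χ² coverage
  rescaling is applied: this definition reproduces the published
  core-niche areas exactly.
* `SEAc = SEA (n−1)/(n−2)` — the small-sample correction.
* Bayesian ellipse area: conjugate normal–inverse-Wishart with prior mean
  at the sample mean, prior strength κ₀ = 10⁻³, scale matrix 10⁻³·I and
  ν₀ = 3 degrees of freedom (all configurable). The covariance posterior
  is IW(ν₀ + n, 10⁻³·I + (n−1)S); each draw contributes π√det Σ. With the
  prior mean tied to the sample mean the mean-update term vanishes, so
  κ₀ only matters if a fixed prior mean is supplied. The vague prior
  shrinks the posterior median slightly below the ML area at small n
  (≈ 0.25 vs 0.38 ‰² for a six-point group); tests validate the sampler
  against an independent Bartlett chi-square-decomposition oracle rather
  than asserting closeness to the ML value.

Overlap is computed between **SEAc-scaled** ellipses (covariance times
(n−1)/(n−2)), consistent with the published overlap percentages; both
one-sided percentages (area / own SEAc) are reported. Ellipse boundaries
are polygonized at 4096 vertices and clipped with shapely; the polygonal
area error is O(vertex count⁻²), relative error < 10⁻³ at the default,
and the Monte-Carlo equivalence test holds the result to 3 MC standard
errors against 10⁶-point rejection sampling.

### Reconstructed carnivore-group members

The per-period large-carnivore groups combine newly analysed samples
(packaged) with literature values whose raw coordinates are not
redistributed here. The missing members (1 of 7 in the MP, 3 of 23 in the
Aurignacian, 5 of 11 in the Gravettian) are reconstructed by weighted
least squares against the published group statistics — mean, per-isotope
SD, and SEA — with a weak pull toward the group centroid to select a
unique solution when the system is underdetermined
(`isofox.synthetic_members`). These stand-ins are synthetic: they pin the
group's mean and covariance (up to the sign of the isotope correlation,
which the least-squares solution resolves), so ellipse-based quantities
(SEA, SEAc, overlap) are well constrained — the MP and Aurignacian
overlaps recompute to the published values within print precision — while
point-based quantities (TA) are not. The Gravettian group, with most
members reconstructed, is the least constrained and its overlap is
indicative only.

## Diet mixing model

Sources enter as summary statistics (mean ± SD per isotope and n), which
is exactly what is published for the four prey groups (horse, mammoth,
reindeer, rodents); a raw-data path exists via `group_from_points` for
synthetic work. The trophic enrichment factor defaults to
Δ13C = 1.1 ± 1.1‰, Δ15N = 3.2 ± 1.8‰, applied identically to every source.

For diet proportions p (shared by all consumers in a group), isotope j of
each consumer is independent normal with mean Σ p_k(μ_kj + Δ_j) and
variance Σ p_k²(σ_kj² + σ_Δj²) — the "process error" form, in which the
consumer averages over many prey individuals, so source variance enters
with weight p². An optional `process_plus_residual` model adds a
per-isotope residual variance with a half-normal prior (scale 1‰ by
default, sampled on the log scale); with the study's group sizes (2–26
consumers) the residual term is weakly identified and the process model
is the default.

The prior is symmetric Dirichlet(α), α = 1. Sampling is random-walk
Metropolis in isometric log-ratio coordinates (orthonormal Helmert
basis); the pullback of the Dirichlet density onto ILR space contributes
a Jacobian ∝ Π p_k, giving a log-target of log-likelihood + α·Σ log p_k
(constants dropped). The proposal scale adapts every 1000 iterations
during burn-in only (×1.2 if window acceptance > 40%, ÷1.2 if < 20%),
targeting the 20–40% band appropriate for low-dimensional random walks;
freezing adaptation after burn-in preserves detailed balance in the
retained draws. Chains initialize from prior draws, re-drawing on
non-finite targets. Chain streams come from `SeedSequence(seed).spawn`,
so a run is bit-reproducible for a given seed and chain count.

Schedules: the study-scale profile is 3 chains × 1,000,000 iterations
with 500,000 burn-in (available as the `full` preset, thinned ×10); the
scaled-down default used by the tests and the acceptance script is
3 × 100,000 / 50,000 unthinned, which leaves 150,000 retained draws —
with acceptance rates ~0.25–0.35 and R̂ < 1.001 on the study fits, ample
for posterior means, and it keeps a full three-niche reconstruction
under a minute on one CPU. Posterior summaries report mean, SD and the
2.5/5/25/50/75/95/97.5% quantiles, with a percent view rounded to one
decimal.

With only group-level proportions and no residual/random-effect
structure, posterior *means* reproduce the published dietary table within
a few percentage points, while posterior SDs are somewhat narrower than
the published ones (which come from a richer hierarchical error model
fitted jointly across all niches and periods); this package fits each
consumer group independently.

## Convergence diagnostics

* Gelman–Rubin R̂: classic (non-split) form from m chains of length n,
  R̂ = sqrt(((n−1)/n·W + B/n)/W). Cross-checked against arviz's
  "identity"-method rhat in the tests. Thresholds reported at 1.1
  (acceptable) and 1.01 (strict).
* Geweke z: mean of the first 10% of a chain vs the last 50%, scaled by
  long-run (spectral-at-zero) variance estimates of each segment. The
  spectral density is estimated by Yule–Walker AR fits with AIC order
  selection (order ≤ 20) — the conventional `spectrum0.ar` construction.
  Constant segments are guarded to z = 0. Calibration: on white noise the
  empirical |z| > 1.96 rate is ≈ 4.5% over 200 replicates.

## Synthetic data

The generator mirrors the two distributional assumptions of the analysis:

* **Source/niche clouds** are independent bivariate normals
  (zero δ13C–δ15N correlation by default, configurable) at the published
  prey-group and fox-niche statistics, with QC fields filled with passing
  values. The default fixture uses the study's group sizes (26/10/2 foxes
  per niche) and niche-cloud SDs of 0.3–0.4‰ in δ15N so the clouds stay
  inside their defining windows.
* **Forward-model consumers** are drawn from the mixing model's
  predictive normal at a known p (low niche: rodents = 0.80), with the
  truth recorded for recovery tests.

These two mechanisms are deliberately separate: the observed low-δ15N fox
values (+1 to +3‰) lie *below* the minimum enriched source mean
(3.8 + 3.2 = 7.0‰), so no forward-model diet can generate a cloud at the
low-niche centroid — the real low-fox consumers are in the tail of the
mixing likelihood, which is precisely why their posterior pins the
highest-variance source (rodents). Niche-cloud data exercise QC,
assignment and geometry; forward-model data exercise inference.

What passing synthetic tests show: the sampler recovers generating
proportions at nominal credible-interval coverage when the model is
correctly specified, and the pipeline is deterministic given a seed. What
they do not show: robustness to TEF misspecification, within-group
isotope correlation, or the hierarchical error structure of real
multi-consumer assemblages.

## Numerical choices and limitations

* Coordinates are always (x = δ13C, y = δ15N) in ‰; areas in ‰².
* Hull/ellipse routines reject < 3 points, collinear sets and singular
  covariances rather than returning degenerate areas.
* Simplex draws are validated to sum to 1 within 10⁻⁹ in tests; the ILR
  inverse uses a max-subtracted softmax for overflow safety.
* The t-test, clustering, hull, and inverse-Wishart sampling delegate to
  scipy; polygon clipping to shapely; AR fitting to statsmodels. The
  mixing sampler and diagnostics are implemented here for auditability.
* No concentration-dependence, isotopic routing, covariates, or model
  comparison; no Layman metrics beyond TA; niche space is strictly 2-D.
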