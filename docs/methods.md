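# Methods

This note documents the models, conventions and design choices behind
`structdhi`, in the spirit of a statistical-software methods appendix.
Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The question and the estimand

The pipeline quantifies the redundancy between two indicator families —
six forest structural attributes (predictors) and the three Dynamic
Habitat Indices (responses) — as the constrained fraction of response
variance in a redundancy analysis (RDA), decomposed further into
fractions unique to the *primary* attributes (canopy height, canopy
cover, structural complexity), unique to the *modelled* attributes
(basal area, aboveground biomass, gross stem volume), and shared.

## 2. Synthetic data model

### 2.1 Landscape

A gridded landscape (default 200×200 pixels) carries co-registered
rasters: six structure bands, a zone map, a forest-type map and a
disturbance-year map.

* **Zones** are contiguous vertical strips (n_zones, default 4), higher
  index read as colder. Contiguity is guaranteed by construction.
* **Forest types** (coniferous, broadleaf, mixedwood, wetland-treed,
  plus a non-treed background) are drawn iid per pixel and
  majority-smoothed with one 3×3 pass so pure neighbourhoods exist.
  Default proportions (0.50/0.18/0.10/0.07, non-treed 0.15) follow the
  rank order of western-Canadian forest composition (coniferous
  dominant) but are flattened enough that every zone × type stratum is
  populated on a desk-scale grid.
* **Structure bands** share a spatially smooth latent productivity
  field `L` (Gaussian-filtered white noise, σ = 3 px, unit variance):
  on the log scale, attribute j is `w_j L + sqrt(1 − w_j²) ε_j` with
  attribute-specific noise `ε_j` itself smoothed (σ = 1.5 px) —
  imputed structure rasters vary gradually, not pixel-to-pixel. The
  attributes are then **log-normal**, `median_j · exp(logsd_j · z)`,
  e.g. canopy height median 18 m (log-sd 0.45), biomass median
  140 t/ha (log-sd 0.55); canopy cover is clipped at 100%.
  Log-normality encodes local variability proportional to level, the
  same right-skew that motivates the ln transform at analysis time.
  Pairwise correlations are `w_j w_k` on the log scale (modelled
  attributes use w ≈ 0.88–0.92, so they are mutually correlated at
  r ≳ 0.7 on the natural scale as well). Non-treed pixels carry NaN.
* **Disturbance years** hit a fraction of pixels (default 0.15)
  uniformly over the 50 years before the reference year (2015 analog),
  so the 35-year stand-age filter excludes some disturbed pixels and
  admits others.

### 2.2 Coupling (the known ground truth)

With `X` the standardized **log-scale** structure (z-scored over treed
pixels) the latent response signal is

    S = X B + E,   E_jk ~ N(0, noise_sd_k²).

* **Direct mode** emits `(X, S)` rows as a sample table with
  independent standard-normal predictors; the population variance
  explained is `mean_k b_kᵀC b_k / (b_kᵀC b_k + σ_k²)` with `C = I`
  (`true_variance_explained`).
* **Raster mode** uses column 0 of `S` to shift each pixel's seasonal
  NDVI baseline and column 1 its amplitude (×`phenology_scale`,
  default 0.05 NDVI units per signal unit). Because the coupling acts
  on the same log-scale standardized attributes that the analysis
  standardizes, the signal stays linear end to end.

`coupling_for_r2(r2, p, q, cov=C)` constructs `B` in closed form with
channels orthogonal in the `C` inner product, so *any* linear mixture
of the response channels — and the DHIs are such mixtures — has the
same population variance explained. For raster-mode ground truth, `C`
is the correlation of the log-scale standardized bands, estimated once
by Monte Carlo from a fixed-seed calibration landscape
(`empirical_structure_covariance`); the analytic `w wᵀ` form holds
exactly only before the cover clip.

### 2.3 Scenes

Ten years (reference ± 5) of one mid-month scene per calendar month.
The seasonal curve is a sinusoid clamped below by a winter (snow)
floor:

    ndvi(m) = max(baseline + amplitude · cos(2π(m − peak)/12), floor),

with per-forest-type defaults (e.g. coniferous baseline 0.50, amplitude
0.42) and the floor lowered by `zone_floor_step` (default 0.08) per
zone index — colder zones hit the snow floor for more of the year, so
minimum DHI decouples from the canopy signal there. Observation noise
(sd 0.02) is added, the result clamped to [−1, 1], and red/NIR are
back-solved under constant brightness red + NIR = 0.5, so recomputed
NDVI equals the noisy truth exactly and reflectance stays in [0, 1].
QA flags (cloud/shadow) are planted independently per pixel per scene
with probability `cloud_prob` (default 0.15). The irregular revisit of
a real satellite archive is deliberately not emulated: median
compositing makes cadence immaterial.

All randomness flows from one root seed through named substreams
(landscape / scenes / sampling / direct), so stages are independently
reproducible and fixed seeds give bit-identical outputs.

## 3. Compositing and DHIs

NDVI = (NIR − red)/(NIR + red); QA-flagged or zero-denominator pixels
become nodata (counted in the log). The synthetic year takes, per pixel
and calendar month, the **median** of all unmasked observations of that
month across years, year labels disregarded; an even count takes the
mean of the central pair. Months with no valid observation are invalid;
by default pixels with any invalid month are excluded from DHIs (the
real analysis consumed gap-free composites — the assumption is made
explicit), with an optional circular linear `gapfill`.

DHIs: cumulative = Σx, minimum = min x, variation = σ(x)/x̄ with the
**sample** (n−1) standard deviation — the common software default;
configurable via `ddof` since the population convention is equally
defensible. Negative monthly NDVI flows into cumulative/minimum (snow
scenes legitimately go negative); the CV alone is guarded: undefined at
zero mean, flagged (sign-ambiguous) at negative mean.

## 4. Sampling

Strata are zone × forest-type. Eligibility requires (a) a treed class,
(b) all 8 neighbours of the same type, (c) 3×3 coefficient of variation
of canopy cover **and** canopy height strictly below 0.5 (sample sd
over the 9 values), (d) stand age strictly over 35 years at the
reference year; border pixels are ineligible. Within a stratum,
eligible pixels are visited in seeded random order and accepted
greedily iff at least 1 km (planar Euclidean, centre-to-centre) from
every already-accepted pixel, stopping at 500 per stratum. Open
conventions resolved here: the spacing rule is applied **globally**
across strata (conservative; a per-stratum option exists); exhausting a
stratum before the cap simply takes what passed.

## 5. Ordination

Variables are ln(x + offset) transformed (offset 1.0; structure and
DHI values are ≥ 0-ish on forested samples) then z-scored; rows with
any value + offset ≤ 0 are dropped and counted. Stratified reruns
**reuse the full-sample means/sds** via the returned transform record,
keeping strata on one scale (their column means are then legitimately
nonzero).

RDA: centre X and Y, solve the multivariate least squares (SVD-based;
rank cutoff 1e-10 relative to the largest singular value — for partial
models, relative to the *original* predictor scale, so predictors
annihilated by the covariates contribute nothing rather than amplified
rounding noise), then SVD of the fitted values. λ_k = s_k²/(n − 1);
R² = Σλ_k / tr(cov Y); site scores U·s; loadings are Pearson r of the
original variables with site scores. Partial RDA residualizes X and Y
on the covariates; its proportions are reported against the
**original** response variance by default (fractions then commensurable
across partitions; `proportion_basis="conditional"` switches).

Axis significance is a **sequential permutation pseudo-F test** (the
convention of the ordination software tradition, where the named
"ANOVA/F-test" is permutational): axis k is tested conditioning on
axes 1…k−1 via their site scores, F = λ_k·df_res/RSS on the
residualized problem, rows of residualized Y permuted, p = (1 + #{F* ≥
F})/(1 + n_perm), retention requires p < α (default 0.1) for the axis
and all earlier axes. n_perm ≥ 99 is enforced (resolution at α = 0.1).
A parametric overall F approximation (`overall_f_test`) is provided
purely as a cross-check. Per-loading significance (t-test of the
correlation at α = 0.1, applied to retained axes) is an
interpretation, not a claim about how any published figure was made.

Sign convention: per axis, if the cumulative-DHI loading is negative,
all loadings and site scores of that axis are negated (idempotent;
eigenvalues untouched), so loading directions are comparable across
strata.

Variation partitioning fits RDAs for X1, X2 and X1∪X2:
a = R²_full − R²_2, c = R²_full − R²_1, b = R²_1 + R²_2 − R²_full,
residual = 1 − R²_full; both raw and Ezekiel-adjusted
(1 − (1 − R²)(n − 1)/(n − m − 1)) versions are always reported —
adjusted unique/shared fractions can be slightly negative, and small
published fractions can differ materially between the two conventions,
so neither is privileged.

## 6. Validation design and problem sizes

* **Oracles.** The RDA core is checked to 1e-8 against an explicit
  hat-matrix projection oracle (H = X(XᵀX)⁻¹Xᵀ, eigendecomposition of
  (HY)ᵀHY/(n−1)) on 100 random instances, against closed forms
  (single-predictor R² = mean squared correlation), and against R's
  `vegan::rda` (plain and partial) on a small fixture.
* **Calibration.** Under a null coupling the axis-1 permutation test
  rejects at 0.10 ± 0.03 over 500 replicate datasets (n = 200,
  n_perm = 199).
* **Recovery.** Direct mode recovers true R² = 0.30 within ±0.04 per
  seed (n = 2000, 20 seeds). The full raster pipeline uses a
  controlled-recovery configuration (`make_recovery_config`): uniform
  seasonal parameters, no zone floor gradient, winter floor low enough
  never to bind, 100 m pixels so a 200×200 grid (20 km) retains a few
  hundred sample units under 1-km spacing, coupling built for true
  R² = 0.40 under the empirical log-scale structure correlation. Mean
  recovered R² over seeds falls within ±0.08 of truth; the residual
  gap comes from the ln transform of bounded ratio quantities (the
  variation DHI), the min-of-noisy-months bias, and finite-sample R²
  inflation at n ≈ 260.
* Problem sizes throughout (48–200 pixel grids, 120 scenes, n ≤ 5000,
  ≤ 500 permutation replicates) were chosen as the smallest at which
  the statistical claims above are distinguishable from noise.

## 7. What the generator does and does not emulate

It emulates: correlated log-normal structure attributes on a zoned,
typed landscape; per-forest-type seasonal NDVI with a zone-dependent
snow floor; cloud/shadow QA dropout; disturbance history; and a linear
structure→phenology coupling with known variance explained. It does
**not** emulate: radiative-transfer or topographic effects, irregular
satellite revisit or orbit gaps, sensor harmonization, spatially
correlated cloud masks, NDVI saturation at high leaf area, or
non-linear structure–productivity relationships. Passing recovery
tests therefore demonstrate that the *pipeline machinery* is unbiased
and calibrated under the stated data model — not that real-world
structure–productivity redundancy equals any particular value.

## 8. Known limitations

* The QA model is a 3-level code collapsing to a binary mask; real
  cloud-mask bitfields are richer and their failure modes (haze,
  shadow edges) are not represented.
* Greedy sequential spatial thinning is order-dependent; it matches
  common practice but is not a maximal independent set.
* The permutation scheme is "reduced model by axis"; marginal tests
  would give different (generally more conservative) later-axis
  p-values.
* Adjusted unique fractions can be negative; they are reported as-is.
* With ~260 spaced samples the raster-mode R² estimate carries a
  standard error of roughly 0.03; single-seed comparisons against the
  analytic truth should use the multi-seed means that the acceptance
  script reports.
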