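# structdhi

**How much do satellite indicators of forest structure and forest
productivity overlap?** `structdhi` is a tested, fully reproducible
pipeline for answering that question with redundancy analysis. It links
two families of ecosystem-level remote-sensing indicators:

* **Forest structural attributes** — canopy height (95th return
  percentile, m), canopy cover (% returns above 2 m) and structural
  complexity (CV of return heights), which are *primary* lidar
  measurements, plus basal area (m²/ha), aboveground biomass (t/ha) and
  gross stem volume (m³/ha), which are *modelled* from lidar and
  ancillary data.
* **Dynamic Habitat Indices (DHIs)** — three intra-annual summaries of a
  "synthetic year" of monthly NDVI, x₁…x₁₂:

  | index | formula | hypothesis |
  |---|---|---|
  | cumulative DHI | Σᵢ xᵢ | available energy |
  | minimum DHI | min{x₁,…,x₁₂} | environmental stress |
  | variation DHI | σ(x)/x̄ | environmental stability |

Because the wall-to-wall rasters such analyses normally consume are tens
of gigabytes, the package ships a first-class **synthetic landscape
generator** with a *known* structure→productivity coupling: phenology
parameters per pixel follow `S = XB + E`, where `X` is the (log-scale)
standardized structure, `B` a user-chosen coupling matrix and `E`
Gaussian noise, so the population variance explained is available in
closed form (`true_variance_explained`). Every stage — QA-filtered
monthly-median NDVI compositing, DHI computation, constrained stratified
sampling, ln+z standardization, RDA with permutation axis tests, and
two-set variation partitioning — can therefore be validated against
analytic ground truth.

The ordination core is written from first principles (no ordination
package): RDA is the multivariate least-squares regression of responses
on predictors followed by an SVD of the fitted values; canonical
eigenvalues λₖ partition the explained variance, R² = Σλₖ / tr(cov Y);
loadings are Pearson correlations of variables with site scores; partial
RDA residualizes both sides on covariates; variation partitioning
decomposes R² of two predictor sets into unique and shared fractions
(raw and Ezekiel-adjusted). It matches R's `vegan::rda` to machine
precision (cross-checked in the test suite).

## Worked example

```python
import numpy as np
import structdhi as sd

spec = sd.CouplingSpec(grid_rows=120, grid_cols=120, pixel_size=100.0, seed=7)
land = sd.generate_landscape(spec)                  # 6 structure bands + strata
series = sd.generate_scene_series(land, spec)       # 120 monthly (red, NIR, QA) scenes
year = sd.build_synthetic_year(series)              # monthly median NDVI composite
dhis = sd.compute_dhis(year)                        # cumulative / minimum / variation

config = sd.SamplingConfig(min_distance=1000.0, cap=500, seed=7)
table = sd.draw_sample(land, dhis, config)          # constrained stratified sample
print(f"sample units: {len(table)}")

Xs = sd.transform_standardize(table, list(sd.STRUCTURE_ATTRS))
Ys = sd.transform_standardize(table, list(sd.DHI_NAMES))
model = sd.fit_rda(Ys, Xs)
model.permutation_test(n_permutations=199, random_state=7)
model.normalize_signs("dhi_cum")

print(f"constrained variance (R2): {model.r2_:.3f}")
print("axis proportions:", np.round(model.proportions_, 3))
print("axis p-values:   ", np.round(model.axis_pvalues_, 3))
print(model.response_loadings_.round(2))
vp = sd.variation_partition(
    Ys.values, Xs.values[list(sd.PRIMARY_ATTRS)], Xs.values[list(sd.MODELLED_ATTRS)]
)
print(f"primary-unique {vp.a:.3f} | shared {vp.b:.3f} | "
      f"modelled-unique {vp.c:.3f} | residual {vp.residual:.3f}")
```

Output:

```
sample units: 96
constrained variance (R2): 0.445
axis proportions: [0.422 0.023 0.   ]
axis p-values:    [0.005 0.48  1.   ]
         RDA1  RDA2  RDA3
dhi_cum  0.72  0.20  0.00
dhi_min  0.61 -0.10 -0.01
dhi_var -0.62  0.13 -0.01
primary-unique 0.048 | shared 0.295 | modelled-unique 0.102 | residual 0.555
```

Reading this: structure explains 44.5% of DHI variance on this synthetic
landscape, almost all of it on a single significant axis (p = 0.005; the
second axis fails the 0.1 permutation threshold). The first axis behaves
as an overall-productivity axis — cumulative and minimum DHIs load
positively, the variation DHI negatively (productive pixels are also the
stable ones). After sign normalization the cumulative-DHI loading is
non-negative on every axis by convention, so loadings are comparable
across strata. The partition attributes most of the explained variance
to information shared between primary and modelled attributes, which are
strongly collinear by construction.

`run_full_analysis(RunConfig(...))` wraps the chain above, adds
per-zone and per-forest-type reruns (reusing full-sample transform
statistics so strata stay on one scale), and writes
`rda_<stratum>.json`, `loadings_<stratum>.csv` and
`varpart_<stratum>.csv` under an output directory. The same stages are
available as a CLI:

```bash
structdhi simulate --seed 7 --out run/
structdhi composite --scenes run/scenes --out run/year.tif
structdhi dhi --in run/year.tif --out run/dhi.tif
structdhi run --seed 7 --out run/
```

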