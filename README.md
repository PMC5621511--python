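# macrorich

Species-richness gradients are rarely uniform: for many clades most species
pile up in one energetically rich region while surrounding regions hold
nested subsets of that pool.  `macrorich` implements, as one reusable and
fully tested pipeline, the inferential chain used to dissect such a pattern
on gridded range data:

1. **Probabilistic hotspot delineation.**  Global spatial autocorrelation of
   richness with Moran's *I* (`E[I] = -1/(n-1)`), per-cell Getis–Ord Gi\*
   Z-scores

   `Z_i = (Σ_j w_ij x_j − X̄ Σ_j w_ij) / (S √[(n Σ_j w_ij² − (Σ_j w_ij)²)/(n−1)])`

   with self-inclusive contiguity weights, then FDR-corrected significance
   and queen-connected cluster labelling.  A "hotspot" is a statistically
   delimited cluster of cells richer than expected by chance — not an
   arbitrary top-percentile cut.
2. **Nestedness.**  Matrix temperature *T* (isocline formulation, 0 =
   perfectly nested), Brualdi–Sanderson discrepancy *BR*, and *NODF* with
   its row (incidence) and column (composition) components, each tested
   against a Monte-Carlo null with **fixed rows / equiprobable columns**
   (every species keeps its occurrence count; occurrences land uniformly
   across sites).
3. **Co-occurrence.**  The checkerboard C-score
   `CU_ij = (r_i − S_ij)(r_j − S_ij)` averaged over species pairs, with the
   standardized effect size `SES = (obs − null mean)/null sd`; SES < −2
   indicates aggregation (more co-occurrence than chance), SES > 2
   segregation.
4. **Environment models.**  Pearson correlations, forward-stepwise OLS
   selected by AICc, a maximum-likelihood spatial-error SAR
   (`y = Xβ + u, u = λWu + ε`), and 1st/99th-percentile quantile-regression
   lines that trace the lower/upper constraint envelope of richness against
   an energy proxy (PET, AET, ...), with rank-score permutation tests for
   slope = 0.
5. **Historical biogeography.**  Dispersal–extinction–cladogenesis (DEC and
   DEC+j) likelihoods over ranges on a dated tree, ML fitting with AIC
   comparison, and biogeographic stochastic mapping (BSM): event histories
   sampled conditional on tip ranges, summarised as a source-area ×
   destination-area matrix of mean dispersal counts.

A first-class `synthetic_data` module generates environments with a radial
energy gradient, species ranges grown by energy-weighted accretion (the
source–sink geometry: a clustered richness peak with nested composition away
from it), dated trees, and forward-simulated DEC histories with full event
logs — so every downstream stage is testable without external GIS data.

## Worked example

```python
import macrorich as mr

env = mr.make_environment((20, 20), seed=1)          # PET-like energy peak
ranges = mr.make_ranges(40, env, seed=2)             # source–sink ranges
grid = mr.stack_richness(ranges)

w = mr.build_weights(grid)
print(mr.morans_i(grid.richness.astype(float), w))

ws = mr.build_weights(grid, include_self=True)
gi = mr.getis_ord_gstar(grid.richness.astype(float), ws)
print(mr.delineate_hotspots(gi, ws).clusters)

M = mr.build_matrix(ranges).matrix
for idx in ("T", "BR", "NODF"):
    print(mr.nestedness_test(M, idx, n_iter=999, seed=3))
print(mr.cooccurrence_test(M, n_null=5000, seed=4))
```

prints (abridged):

```
Moran's I = 0.955 (E[I] = -0.0032, Z = 32.8, p = 1.8e-236)
kind  cluster  n_cells    max_z   mean_z
 hot        1       62   8.26     5.04
   T: obs =   5.35   null mean =   31.25  CI (29.81, 32.73)   p = 0.0010
  BR: obs = 467.00   null mean = 1289.16  CI (1264.0, 1314.1) p = 0.0010
NODF: obs =  82.44   null mean =   40.71  CI (39.46, 41.98)   p = 0.0010
C-score = 259.66 < null mean = 1364.49; SES = -124.93
```

— one significant richness hotspot containing the energy peak; the
community matrix is far more nested than the null (cooler *T*, lower *BR*,
higher *NODF*) and species co-occur far more than chance (strongly negative
SES).  That is the qualitative tripod a historical source–sink dynamic
predicts.

The biogeographic side runs the same way:

```python
tree = mr.simulate_tree(20, seed=5)
hist = mr.simulate_dec(tree, d=0.10, e=0.02, j=0.0,
                       areas=("A", "B", "C", "D"), root_range="B", seed=6)
fits = [mr.fit_dec(tree, hist.coding, m) for m in ("DEC", "DEC+j")]
print(mr.compare_models(fits))                # AIC table, ΔAIC < 2 flagged
best = min(fits, key=lambda f: f.aic)
print(mr.bsm(tree, hist.coding, best, n_maps=200, seed=7).dispersal)
```

Everything is also reachable from the command line (`macrorich --help`:
`run`, `richness`, `kappa`, `hotspot`, `nestedness`, `cooccur`, `biogeo`),
and `macrorich run --config pipeline.yaml` executes the whole chain with
per-stage seeds, writing CSV/JSON results plus a hash manifest.

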