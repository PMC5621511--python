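# Methods

This note documents the models behind each pipeline stage, the choices made
where the literature leaves the design open, and what the synthetic-data
generators do and do not emulate.

## Grids, matrices, map comparison

Ranges arrive as rasterized boolean occupancy grids (no polygon-overlay GIS
is attempted).  Grid convention: origin at the north-west corner, row-major,
0-based cells.  Richness is the per-cell count of overlapping ranges;
`Σ_cells richness = Σ_species range size` by construction.  The
presence–absence matrix keeps one column per cell with at least one record,
because sites without records carry no information for nestedness or
co-occurrence and would bias the equiprobable-columns null.

Regridding to a coarser resolution aggregates each species by any-presence
within the coarse cell and then recounts richness — never by summing
fine-cell richness, which would double-count species spanning several fine
cells.  The coarse cell size must be an integer multiple of the base
resolution; trailing partial blocks at the south/east edges form their own
smaller cells.

Map agreement uses Cohen's kappa (via scikit-learn) over richness classes.
The class definition is not standardized for richness maps; the default is
10 equal-width classes spanning the joint richness range of the shared
valid cells.  Kappa is 1 for a map against itself whenever at least one
class boundary separates cells, and 0 in expectation for independent maps.

## Hotspot protocol

1. Global autocorrelation: Moran's
   `I = (n/S0) Σ_ij w_ij z_i z_j / Σ_i z_i²`, expectation `−1/(n−1)`.
   Inference is normality-based by default (classic S1/S2 variance) with a
   seeded permutation option (999 shuffles, one-tailed in the observed
   direction, +1-corrected).
2. Local scores: self-inclusive Getis–Ord Gi\* with the population standard
   deviation in the denominator.  Default weights are binary queen
   contiguity plus a unit self-weight — the common default of desktop
   hotspot tools, which rarely document it.
3. Delineation: two-sided normal p-values, Benjamini–Hochberg FDR at
   α = 0.05 by default (a no-correction option exists because raw
   thresholds are also common practice); cells with corrected-significant
   Z > 0 are flagged and queen-connected components labelled as hotspot
   clusters, with coldspots (Z < 0) reported separately.  Valid cells
   without neighbours are excluded from inference and listed in the result.
   Cluster-level summaries report per-cluster size, max Z and mean Z; no
   single "cluster Z" aggregation is imposed, since none is standard.

## Nestedness

All indices validate a 0/1 matrix and are computed after (or independent
of) packing:

* **Packing** sorts rows by decreasing totals and columns by decreasing
  totals or by an external site score (e.g. AET productivity for the
  energy-ordered analysis); ties keep the original order.  Stable ties make
  packing deterministic, at the cost that T and BR are exactly
  permutation-invariant only when marginal totals are tie-free (NODF is
  always invariant, being defined through marginal comparisons).
* **NODF**: for every line pair with strictly different marginal totals,
  the paired overlap is the percentage of the sparser line's presences also
  present in the fuller line; equal-total pairs contribute 0.  Row pairs
  give NODFr (incidence), column pairs NODFc (composition), all pairs NODF;
  range 0–100, larger = more nested.
* **Matrix temperature T** follows the isocline formulation of the
  Rodríguez-Gironés & Santamaría algorithm: the packed matrix maps onto the
  unit square; the isocline `y = 1 − (1 − (1−x)^p)^(1/p)` has its exponent
  solved (closed-form beta integral, Brent root) so the area above it
  equals the fill; each unexpected presence (below the isocline) or absence
  (above it) contributes its squared diagonal distance to the isocline,
  normalized by the diagonal length; the mean is scaled by 100/0.04145.
  Cell crossings are found by 60 rounds of vectorized bisection (≈1e−18
  accuracy).  T is undefined at 0% or 100% fill.
* **Discrepancy BR** counts, after packing columns by totals, the presences
  outside each row's leftmost `r_i` positions — the minimum number of
  shifts to the maximally packed matrix with the same row sums.

**Null model** (shared with the co-occurrence test): fixed rows /
equiprobable columns — each species' `r_i` presences land on a uniform
random subset of sites, so row sums are preserved exactly in every
replicate and expected column totals are uniform.  This conditions on
species frequencies (row-sum randomization is the classic type-I-error
risk) while letting site richness vary freely, appropriate when all sites
are in principle colonizable.  Tests report the observed index, the null
mean, a percentile 95% CI, and a one-tailed Monte-Carlo p in the nested
direction with the +1 correction (p is never 0); the opposite tail is
reported too, and a `direction_conflict` flag marks matrices whose observed
value sits significantly on the anti-nested side of the null mean.

## Co-occurrence

C-score = mean checkerboard units `(r_i − S)(r_j − S)` over unordered
species pairs.  Species occupying all sites contribute CU = 0 pairs and are
retained.  The null variance is reported in population form (the `n`
divisor); at the default 50,000 replicates the distinction from the sample
variance is negligible.  SES = (observed − null mean)/null sd; under the
null ≈95% of SES values fall in [−2, 2].  Note that recomputing SES from
*rounded* summary statistics reproduces a printed SES only to input-rounding
accuracy (e.g. summary values 331.73/351.39/1.43 give −16.44 rather than an
unrounded −16.46).

## Environment models

The site table holds one row per valid cell: cell-centre coordinates,
richness, and named covariates (PET and AET in mm/yr, temperature
seasonality in %, etc.).

* **AICc** = AIC + 2k(k+1)/(n−k−1) with k counting the intercept, slopes
  and the error variance, so model comparisons are well defined across
  stages.
* **Forward stepwise OLS** greedily adds the candidate with the largest
  AICc decrease (ties broken by candidate order; deterministic) and stops
  when no addition improves AICc, so the selected model's AICc never
  exceeds the intercept-only model's.  Selected covariates are reported
  ordered by absolute standardized coefficient.  Rank-deficient designs
  raise a collinearity error naming the offending columns.
* **SAR**: the spatial-error form `y = Xβ + u, u = λWu + ε` is the default
  (the usual recommendation for gridded richness, where autocorrelation
  lives in the residual); a lag variant is available behind a flag.  The
  likelihood is concentrated over λ with the log-determinant computed from
  the eigenvalues of the row-standardized W; λ's standard error comes from
  the numeric curvature of the profile likelihood.  The reported pseudo-R²
  is the squared Pearson correlation between the trend Xβ̂ and the observed
  response (no canonical definition exists; this one is stated wherever it
  is printed).  OLS and SAR can report different conditional signs than the
  marginal correlations; both are reported, neither is "reconciled".
* **Quantile envelopes**: linear check-loss fits (statsmodels QuantReg,
  interior-point/IRLS vertex solutions) at τ = 0.01 and 0.99 trace the
  lower and upper constraint lines of a richness–covariate scatter.
  Slope = 0 is tested with a rank-score permutation test: scores
  `τ − 1{y < q̂_τ}` from the intercept-only fit, statistic
  `Σ(x − x̄)s`, reference distribution from seeded permutations of x
  (default 10,000), +1-corrected two-sided p.  Extreme-quantile fits warn
  below n = 30.

## DEC historical biogeography

States are non-empty area subsets up to a maximum range size (default: the
number of areas); the absorbing empty range is kept internally so that
extinction of single-area ranges leaks probability correctly through
`exp(Qt)`.  Anagenetic rates: area k is gained at
`d · Σ_{l∈range} m[l,k]` (dispersal multipliers default to all-ones — no
distance scaling) and each occupied area is lost at `e`.  Cladogenetic
events: sympatric copying for single-area ranges; subset sympatry and
single-area vicariance for widespread ranges (each ordered daughter pair
counted once — for two-area ranges the two vicariance orders are the
complete set); every allowed non-jump event gets equal weight.  Under DEC+j
the total jump weight `j` is split equally among single-area destinations
outside the ancestral range and the remaining `1 − j` among non-jump
events.  The root prior is uniform over allowed non-empty ranges by
default; a fixed root range can be supplied (and is what the forward/BSM
consistency test conditions on).  `df` is 2 for DEC and 3 for DEC+j;
`AIC = 2·df − 2·lnL` exactly, and ΔAIC < 2 is flagged as indistinguishable
rather than auto-resolved.

Likelihood: Felsenstein pruning with per-node rescaling; branch propagators
come from one eigendecomposition of Q reused across branches, falling back
to per-branch `expm` if the eigenbasis is ill-conditioned.  Fitting uses
bounded L-BFGS-B from two starts.

**BSM** samples joint node states (root from prior × conditional
likelihood; daughters from propagator × subtree likelihood; cladogenetic
events from their posterior weights) and branch paths by uniformization —
exact endpoint-conditioned CTMC sampling without time-discretization bias —
with a retry cap of 100 per branch.  Anagenetic dispersal counts are
attributed fractionally: a gain from a k-area range credits each source
area 1/k.  Cladogenetic jumps are counted in a separate matrix (whether
published dispersal summaries include them is ambiguous; keeping them
separate lets the reader choose), and per-event-type totals are reported.

The forward simulator (`synthetic_data.simulate_dec`) draws the same
process forward — competing-exponential anagenesis, the same cladogenetic
distribution — and logs every event, so replaying the log from the root
must reproduce the tip ranges exactly.  Replicates in which a lineage range
goes extinct are flagged and resampled (cap 100), the standard conditioning
of range-evolution simulators.

## Synthetic worlds: what they emulate, and what they do not

`make_environment` builds radial-gradient layers
`baseline + amplitude · exp(−dist/decay)` (+ optional Gaussian noise):
a PET-like energy peak (default 400 + 1600·exp(−d/decay) mm/yr), a
correlated AET layer, and a seasonality layer increasing away from the
peak.  `make_ranges` seeds each species with probability ∝ normalized
energy^6 and grows it to a heavy-tailed target size (lognormal, median 10%
of the grid, σ = 1) by rook-adjacent accretion weighted by energy rank^3.
Defaults (20 × 20 cells, 40 species in the end-to-end checks) were chosen
once so that the source–sink geometry is unambiguous: most species overlap
at the energy peak, large-ranged species extend outward, and the stacked
richness shows a single clustered peak with nested composition away from
it.

These worlds deliberately do **not** mimic real range-map geometry: no
riverine barriers, no topography, no range fragmentation, no spatial
autocorrelation in the noise, and ranges are single connected patches.
Passing tests therefore demonstrate that the *statistics* behave correctly
on data with the assumed structure (and that the qualitative
hotspot/nestedness/aggregation signal is recovered when it is truly
present); they say nothing about rasterization error, range-map
overprediction, or barrier effects in real data.

## Problem sizes and numerical choices in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to make
Monte-Carlo error small relative to the tested effects: null calibrations
at 500 draws × 1,000 nulls (SES coverage) and 400 draws × 500 nulls
(nestedness type-I); oracle equivalence on 100 random small matrices per
index (exact for integer indices, 1e−10 for floats); DEC rate recovery on
100 replicates of 50-tip trees; forward/BSM consistency on a 20-tip tree
(240 forward replicates vs 80 × 12 conditional maps, compared within
Monte-Carlo SE); envelope recovery at n = 5,000 and SAR recovery at n = 900;
and the end-to-end tripod on 100 seeded 20 × 20 worlds.  Statistical
assertions use ~3-SE binomial bands rather than 1-SE bands so that a
correct implementation fails only with negligible probability.

## Known limitations

* Spatial weights are fixed-radius contiguity only (no distance bands or
  kernels); the Gi\* implementation is the textbook statistic, not a clone
  of any particular GIS product.
* T and BR depend mildly on tie resolution in packing (documented above).
* The SAR information matrix for β is conditional on λ̂; λ's SE is from the
  profile likelihood, not a joint Hessian.
* DEC state space grows as 2^areas; the implementation is meant for the
  small area sets typical of subregion analyses (≤ ~8 areas).
* The BSM event taxonomy counts anagenetic dispersal, anagenetic local
  extinction, and the four cladogenetic kinds; finer taxonomies (e.g.
  within-area vs between-area sympatry) are not distinguished.
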