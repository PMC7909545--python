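# Methods

This note documents the models and procedures implemented in
`phyloendemix`, the defaults and why they were chosen, what the synthetic
landscapes do and do not emulate, and the numerical details a user would
otherwise have to read out of the source.

## Gridding and the community matrix

All geometry is planar; geographic coordinates must be projected before
use (an equal-area projection is assumed whenever cell areas are
compared). Cells are indexed 0-based, row-major from the lower-left
corner. A point on an interior upper/right cell boundary belongs to the
next cell; the outermost boundary is clamped inward, so the grid's
bounding box is closed. Records outside the grid are returned as an
explicit rejects list. Duplicate (taxon, cell) records collapse silently
— the analysis is presence/absence — with the collapsed count logged.
Cells with no taxa are dropped from every metric table (CWE is undefined
at zero richness) but remain recoverable from the grid specification.

## Endemism metrics

Per-cell metrics follow the standard definitions: SR and ER are row sums
over all and over endemic columns; `WE_j = Σ 1/r_i` with the range `r_i`
counted in cells; `CWE_j = WE_j / richness_j`. With ranges in cells the
canonical CWE is bounded by 1; an optional `range_scale` factor converts
ranges to other units (e.g. km² per cell) for comparability with studies
that report CWE on other scales, at the cost of the unit bound. Two exact
identities are used as invariants throughout the tests:
`Σ_j WE_j = (number of taxa)` and `Σ_j PE_j = (total retained branch
length)`.

PE is computed from a branch × cell incidence built in one postorder
sweep: a branch is present in a cell iff any descendant tip is. The full
root path is included (a flag drops the root's own branch); zero-length
branches carry incidence but no weight. Taxa absent from the matrix are
pruned from the tree first; a matrix taxon missing from the tree is an
error, never silently dropped. The RPE comparison tree keeps the topology
and sets every branch length to T/N (total length / branch count), which
preserves total length and makes RPE scale-free; multiplying all branch
lengths by a constant leaves RPE unchanged.

Native-taxon metrics (SR, WE, CWE_NAT) use all taxa; ER, WE_END, CWE_END,
PE and RPE use the endemic subset only, on the cells holding at least one
endemic. This mirrors analyses in which the categorical endemism
classification is run for the endemic flora alone.

## Nulls and p-values

The default null is the curveball (fixed-fixed) algorithm: a trade picks
two cells and re-deals the taxa found in exactly one of them, preserving
every row and column sum. Preserving ranges matters here because WE, CWE
and PE all weight by 1/range; a richness-only null (`null="richness"`,
per-cell richness fixed, ranges free) is provided for fidelity with
randomizations that reallocate occurrences without fixing ranges. The
chain burns in for 5× the number of presences and advances the same
amount between replicates (thinning a single chain rather than
restarting); both counts are configurable. The trade loop is a numba
kernel, so 999 replicates on study-scale matrices take seconds.

Rank p-values use the add-one convention `p_high = (#{null ≥ obs}+1)/(R+1)`
(and `≤` for `p_low`), so p is never 0 and ties count toward significance
in both tails. For scatter-generated (null-distributed) data these
p-values are uniform up to discreteness, which the calibration test
checks: placing each taxon's cells uniformly at random is exactly the
uniform distribution over matrices conditional on the margins, i.e. the
distribution the curveball chain samples.

## CANAPE classification

Step 1: a cell is a candidate endemism centre iff `p_high(PE_obs) < α` or
`p_high(PE_alt) < α` (α = 0.05). Step 2: among candidates,
`p_high(RPE) < α_tail` → paleo, `p_low(RPE) < α_tail` → neo (two-tailed
test at overall 0.05, so α_tail = 0.025), otherwise mixed. Step 3: mixed
candidates with both PE p-values below α_super = 0.01 are super. Super is
restricted to the mixed branch (it is defined as a subdivision of mixed),
and all three thresholds are configurable. 0.01 rather than a laxer
super-threshold keeps super centres rarer than mixed centres, as observed
in published applications of the protocol.

## Hotspots, refugia, reserves

Percentile sets use a nearest-rank threshold: the k-th most extreme value
with `k = max(1, ⌊p·n⌋)` for p ∈ {0.01, 0.05, 0.10} (L1/L2/L3), and every
cell at or beyond the threshold is a member. Ties are therefore all
included — conservative for conservation, since an equally scoring cell
is never dropped — and L1 ⊆ L2 ⊆ L3 holds on every input. Priority
Hotspots are the intersection of the high tails of endemic-taxon CWE and
PE at the same level.

Climate stability per variable is the reciprocal of the time-weighted mean
absolute change between consecutive slices (|Δv|/Δt averaged over slice
pairs), rescaled to a maximum of 1; cells with zero deviation are capped
at the finite maximum before rescaling. The combined index is the rescaled
product of the temperature and precipitation stabilities — the product is
the natural "interaction" of component stabilities — and refugia are its
top 10%.

Protected-area coverage is the exact area fraction of each cell under the
union of the non-marine polygons (union first, so stacked designations
never double-count); a priority cell with coverage below the threshold
(default 10%, the customary minimum-representation rule) is a conservation
gap. Area fraction, not centroid containment, is used because a
percentage-coverage criterion is meaningless for point-in-polygon tests.

## Spatial error models

The model is `y = Xβ + u`, `u = λWu + ε` with iid Gaussian ε, on binary
k-nearest-neighbour weights symmetrized by union and row-standardized.
λ is profiled out by golden-section search (tolerance 1e-8) on the
feasible interval `(1/e_min, 1/e_max)` given by the extreme eigenvalues of
W, computed once per W via the similar symmetric matrix `D^{-1/2}AD^{-1/2}`;
the log-determinant of `I − λW` is then exact at every candidate λ. β and
σ² follow by generalized least squares at λ̂.

Estimation profiles the *restricted* likelihood (REML) by default: plain
ML shows the familiar finite-sample downward bias in λ̂ (about −0.02 at
n = 400 with k = 4, decaying with n), which REML removes; `method="ml"`
gives the full-ML profile. Reported log-likelihood, AICc and pseudo-R² are
always full-likelihood values at the estimate, so model selection across
neighbour counts (candidate k = 1…8, lowest AICc, ties to the smaller k)
compares like with like. AICc uses q = p + 2 parameters (β including the
intercept, plus λ and σ²). The Nagelkerke pseudo-R² (GR²) is
`[1 − exp(−2(logL − logL₀)/n)] / [1 − exp(2·logL₀/n)]` with L₀ the
intercept-only non-spatial Gaussian likelihood, so the intercept-only
model scores exactly 0. With λ fixed at 0 the fit reproduces OLS
coefficients exactly. Residual spatial autocorrelation is diagnosed with a
Moran's-I correlogram over equal-width distance classes with binary
in-class weights (expectation −1/(n−1) under independence).

The predictor screen mirrors common practice: standardize to mean 0 / sd 1,
then iteratively drop, from the worst pair with |Spearman ρ| ≥ 0.7, the
variable with the larger VIF, and finally drop variables with VIF ≥ 10,
largest first. Counts (SR, ER) are modelled untransformed by default, with
an optional log1p transform left to the caller.

## Synthetic landscapes

The generator emulates the *structure* of a national flora database at a
~5 km grid — a right-skewed range-size distribution, spatially contiguous
ranges, narrow-ranged endemics, long-branch paleo-endemics, a shallow
neo-endemic radiation, autocorrelated environmental surfaces and a
reserve network — not its realism (no niche-based distributions, no real
climate layers, no taxonomic noise). Passing tests therefore demonstrate
that the pipeline recovers known structure under its own model
assumptions, not that any particular real flora would behave this way.

The standard recovery scenario uses a 20 × 25 grid of 5 km cells and 300
taxa. Background taxa draw log-normal ranges (μ = 2.5, σ = 0.8 on the log
cell scale, floored at 10 cells) realized as 4-connected spreading-dye
patches, matching the spatially coherent hotspot geometry of mountain
floras; a scatter mode provides the exactly-null placement used for
calibration. Two disjoint 2 × 5 blocks are planted: 10 paleo taxa whose
pendant branches are stretched to 10× the median pendant length and whose
ranges (2–4 cells) sit inside the paleo block, and a 25-taxon clade whose
crown is compressed to 8% of tree height with ranges inside the neo
block; block cells serve round-robin as dye seeds so every planted cell
holds planted taxa. Endemics are the lowest-range half of the taxa. Two
choices deserve comment, both made while designing the generator: the
endemic fraction (0.50) is well above the ~20% typical of a
Mediterranean-country flora, and background ranges are floored at 10
cells. Both serve the same purpose: the fixed-fixed null preserves the
planted taxa's small ranges, hence their large 1/r weights, wherever the
null places them, so if narrow-ranged planted taxa dominate the endemic
pool the null distribution of PE becomes heavy-tailed and swamps the
planted signal. A pool dominated by moderately-ranged background endemics
keeps the planted blocks' composition (all-narrow, all-planted)
distinguishable from null draws, and keeps planted cells strictly above
any background cell in CWE (planted 1/r ≥ 1/4 versus background ≤ 1/10).

Environmental predictors are Gaussian random fields (white noise smoothed
with a Gaussian kernel, σ = 3 cells, standardized); the regression
response is built exactly from the fitted model's data-generating process
(`(I − λW)u = ε` on k = 4 union-symmetrized row-standardized weights)
with β = (1.0, −0.5), λ = 0.6, σ = 1 — so parameter recovery is a clean
test of the estimator, not of model mismatch. Reserve polygons cover a
configurable fraction (default 0.8) of target cells at 30% cell area
each, comfortably above the 10% gap threshold, plus decoy polygons
elsewhere; the intended covered/uncovered split is recorded for the gap
tests. All randomness descends from one master seed through named
substreams, so every artefact is byte-reproducible.

## Problem sizes and runtime

The shipped studies use: 100 random instances of ≤ 25 tips × ≤ 30 cells
for the conservation/oracle checks; a 50 × 80 community and 999
replicates for null fidelity; 200 cells / 150 endemics / 199 replicates
for calibration; the 500-cell standard scenario at 199 replicates for
recovery; and 100 replicates of n = 400 for SAR recovery. These sizes
were chosen so the whole suite runs in well under a minute per study on a
single core while leaving Monte-Carlo error far below the margins being
tested; 999-replicate runs at full study scale remain entirely practical.

## Known limitations

- The curveball null is stricter than occurrence-reallocation nulls;
  studies wanting the latter should use `null="richness"` and expect
  wider null PE distributions.
- The comparison-tree transform implements one convention (equal branch
  lengths, total preserved); alternatives (e.g. equal-splits) are not
  provided.
- Polygon I/O is GeoJSON only, and rasters are per-cell text tables; no
  coordinate-system transformations are performed — all inputs must share
  one planar system.
- SAR variants beyond the error model (lag, Durbin), non-Gaussian
  responses and sandwich inference are out of scope; coefficients'
  z-tests are asymptotic.
- The grafting step places new tips at the midpoint of the target branch
  (configurable fraction); placement using sequence data or dating
  constraints is out of scope.
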