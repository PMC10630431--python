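# Methods

## Model

Tissue architecture is described by *p* niches, each a vector of
cell-type densities **b**ₖ (cells per unit area, measured in kernel
units; see below).  The local composition at any point of the tissue is
assumed to be a convex combination of the niches,
**c**(x) = Σₖ αₖ(x)·**b**ₖ with αₖ ≥ 0 and Σαₖ = 1, so that the cloud of
local compositions is bounded by a simplex whose vertices are the
niches.  All downstream quantities — per-site and per-cell niche
weights, interface scores, the mixing score, macroscopic containment —
derive from this single geometric assumption.

### Site composition

Sites are placed uniformly over the tissue (not on cells, so sampling is
unbiased by cell density), excluding a margin of one radius from the
image edge.  A cell at distance *d* from the site centre contributes
exp(−d²/2r²)/(2πr) to its type's entry; contributions are summed per
type.  The prefactor 1/(2πr) is used as such — a true 2-D density would
use 1/(2πr²); the two differ by a global factor *r*, to which the PCA
and the simplex fit are invariant, and a `kernel_normalization` switch
selects between them.  The kernel is not truncated; weights below 1e−12
are skipped for speed (at r = 25 μm that cutoff lies beyond 7r, where a
cell's contribution is numerically nil).  A uniform density λ yields an
expected entry of λ·r, which fixes the interpretation of the niche-bank
units below.

Defaults: r = 25 μm (the smallest radius at which composition
covariance structure is stable in multiplex data of this resolution),
100 sites per 800×800 μm sample ≈ 30 % sampling intensity (total site
area / tissue area).  When an intensity is given instead, the site
count is `round(intensity · L_x L_y / (π r²))`.

### Niche identification

PCA of the site-composition matrix is centered and unscaled (all
columns share density units; scaling would amplify sampling noise of
rare cell types).  Loading signs are fixed so each component's
largest-magnitude loading is positive.  The simplex is fitted in
*d* = *p* − 1 components because *p* − 1 dimensions suffice for a
*p*-vertex simplex; the niche count is chosen by an elbow on the
explained-variance-versus-*p* curve (largest second difference, ties
within 1 % resolved to the smaller *p*), with the final choice left to
the user.

The archetype fitter is a principal-convex-hull alternating
optimisation authored in-package: archetypes are parameterised as
convex combinations of data points (rows of a row-stochastic matrix
*C*, so they remain in the data's convex hull) and updated by projected
gradient descent with backtracking line search; the weights step is an
*exact* simplex-constrained least squares, solved by enumerating active
supports — for each non-empty subset of vertices the
equality-constrained normal equations are solved in closed form, and
the best non-negative candidate is the global optimum of the convex
program (exact for p ≤ 14, which covers all practical niche counts).
The fit is restarted from random data points (default 30 restarts, the
first seeded at greedily chosen extreme points) and the lowest-loss
fit kept; a run stops when the relative RSS improvement drops below
1e−4 (default) or the RSS reaches 1e−12 of the total sum of squares.
Constraining archetypes to the hull is what makes noiseless planted
simplexes identifiable: any *enclosing* simplex has zero residual, so
an unconstrained vertex update wanders on that degenerate set, while
the hull-constrained optimum snaps to the extreme data points.

Explained variance of a fitted model refits per-site weights by the
exact constrained least squares (the "best-fitted composition") and
evaluates residuals in full cell-type space:
1 − Σᵢₖ εᵢₖ²/Σᵢₖ(cᵢₖ−c̄ᵢ)², ε = **c** − **c₀** − U·B·α.  The k-means
comparison uses the within-cluster over total sum of squares on the raw
composition matrix.

### T-ratio significance

The t-ratio compares the volume of the minimal simplex enclosing the
data with the volume of the data's convex hull.  Because the fitted
archetypes lie inside the hull, the fitted simplex is dilated about its
centroid by the smallest factor that contains every point (closed form
from the minimum barycentric coordinate); any simplex containing the
hull has volume ≥ the hull's, so the statistic is ≥ 1 and approaches 1
exactly when the data fill a simplex.  The null distribution permutes
each cell-type column independently across sites — preserving marginals
while destroying the covariance that creates the simplex — and the
one-sided p-value is (1 + #{null ≤ observed})/(1 + n_shuffles), with
the null 95 % interval reported as the 2.5/97.5 empirical percentiles.
At least 100 shuffles are required for 0.01 p-value resolution.

### Per-cell weights, interfaces, mixing

Per-cell niche weights solve **c** = *B*α for a site centred on each
cell, with the same exact solver (KKT-verified against dense
brute-force grids in the tests).  No edge exclusion applies — every
cell receives weights.  Interface scores are the pairwise products
αᵢαⱼ (maximum 1/4); density-independent interfaces zero out the
lowest-total-density niche (automatically identified from *B*) and
renormalise, flagging cells where that niche held all the weight.  The
mixing score averages over the run's sampled sites (not a dense grid).
The binary mixed/compartmentalized call is a user threshold on the
score ranking; no universal cutoff is hard-coded.

### Niche-phenotype mapping

Markers must be partitioned into lineage (cell-type-defining) and
phenotypic sets; only phenotypic markers are tested, and cells labelled
`Unidentified` are excluded.  For each (cell type, marker, context)
triplet — context a niche (weight αᵢ) or pairwise interface (weight
αᵢαⱼ) — Spearman's ρ (mid-ranks) is computed with a two-sided
asymptotic *t* approximation, *t* = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
freedom, n the number of cells of that type.  Contexts are eligible
only if some cell of the type sits mostly there (αᵢ > 1/2 strictly; for
interfaces αᵢαⱼ > 1/8, half the maximal product); ineligible triplets
appear as ρ = 0 in heatmaps.  Constant vectors give ρ = 0, p = 1.

FDR is controlled jointly over all tested triplets by tail-area
q-values with an estimated null proportion π₀ (Storey-type smoother:
cubic-polynomial fit of #{p>λ}/(m(1−λ)) over a λ grid, evaluated at
λ = 0.95); below 100 p-values the estimate is unreliable and the filter
falls back to Benjamini–Hochberg with a logged note.  Discoveries
require q < 0.01 and ρ ≥ 0.3 (defaults).  Redundancy pruning keeps, for
each (cell type, marker), only the larger-ρ context among a niche and
its incident interfaces (exact ties keep the niche as the more
parsimonious context).  Marker exclusion lists (e.g. for spatial
signal spill-over) are applied before summarisation.  Higher-order
(≥3-niche) interfaces are implemented behind a flag but off by default.
Robust presence reports, per context, cell types whose mean abundance
over the top 1 % of sites by niche weight is at least one standard
deviation above zero.

The spatially-agnostic comparison Z-scores phenotypic markers within a
cell type, clusters hierarchically (Euclidean, Ward) cut to k groups,
and tabulates each cluster's sensitivity/specificity for predicting
niche membership (α ≥ 0.5); an ordinary-least-squares linear predictor
of the niche weight from all markers, with ROC obtained by sweeping the
predicted-weight cutoff, serves as the upper bound.

## Tissue simulator

dαᵢ/dt = βαᵢ(αᵢ⁴/(αᵢ⁵+K⁵) − 1/(2K)) + D∇²αᵢ on a 50×50 periodic
lattice, L = 800 μm (dx = 16 μm), β = 1/day, D = 40 μm²/day,
K = 1/n_niches.  The reaction term has stable fixed points at α = 0 and
α = cK with c the root of c⁵ − 2c⁴ + 1 near 1.9276 (α ≈ 2K); the high
exponent makes growth step-like around K so exactly one niche wins per
location, and diffusion smooths domain walls.  Initial conditions are
one-hot with niche 1 drawn with probability f and the rest equally.
Because coarsening eliminates small domains, the converged prevalence
of the rare niche falls well below f (f = 0.04 → ≈0.2 %, f = 0.25 →
≈25 % with seed-to-seed spread of a few points).

Integration is method-of-lines with a periodic 5-point Laplacian and
classical fixed-step RK4, dt = 0.1 day — comfortably inside the
stability region (reaction Jacobian ≲ 20/day, diffusion CFL limit
dx²/4D = 1.6 day), and step-converged: halving dt changes converged
prevalences by < 1e−9, far below the < 1e−3 requirement.  A fixed-step
explicit scheme was preferred over a generic adaptive stiff solver
because the 10⁴-dimensional flattened system makes Jacobian-based
steppers needlessly expensive while RK4 resolves the dynamics exactly
as well here.  Convergence is declared when max|dα/dt| < 1e−6/day
(checked daily); the weights are then normalised to the simplex at
every lattice point, and prevalences (lattice means of αᵢ) are measured
after this normalisation.  Positivity is monitored — the integration
aborts if any weight undershoots below −1e−9 (it does not at the
default step).  Site weights at arbitrary positions use bilinear
interpolation with periodic wrap, which preserves the simplex
constraint exactly.

### Bundled niche bank and the capture threshold

The bundled 17-cell-type × 4-niche matrix is synthetic, with the
qualitative structure of breast-tumor multiplex data: a tumor-cell-
dominated cancer niche, a sparse fibrotic/necrotic niche, a myeloid/
CD8-rich inflammatory niche and a B/CD4/DC tertiary lymphoid structure.
Entries are kernel-density units (λ·r), with column totals of
0.020/0.005/0.019/0.020 — about 130–650 cells per 800×800 μm image, the
sparser end of multiplex imaging.  The capture threshold
ε < 4.5×10⁻⁴ on the recovery RMSE (Euclidean distance of the
best-matching fitted niche column over √17) is meaningful only relative
to this scale; the bank is scaled so the threshold cleanly separates
the three regimes observed in simulation: fit jitter on captured niches
(ε ~ 10⁻⁵–2×10⁻⁴), partially-resolved niches (ε a few ×10⁻⁴–10⁻³) and
total misses (ε ≳ 1.5×10⁻³, the distance to the nearest wrong niche).
Both the threshold and the bank are configuration values.

### Power analysis

For each initial fraction f (default 9 logarithmic steps in
[0.04, 0.25]) and data size n_images, each replicate simulates a field
to convergence, samples n_s = round(n_images·L²/(πr²)) sites (326 per
image; nearest-integer rounding), synthesises X = B·A by bilinear
interpolation, refits PCA(3) + 4 archetypes and computes the rare-niche
recovery error; the capture probability is the fraction of replicates
with ε below threshold, and fields are shared across data sizes within
a replicate.  The power pipeline uses 3 restarts and 150 iterations per
fit — recovery there is limited by whether near-pure rare-niche sites
exist at all, not by restart count (fitted errors track the
best-achievable "purest-site" oracle closely), so the full 30-restart
default is reserved for data analysis.  Default replication is 25 per
condition, which resolves capture probabilities to ±0.1 and keeps the
full two-data-size scan in the tens of minutes on one CPU.

The sampling-intensity analysis fits reference niches from 1000 %
oversampled sites, then reports the composition RMSE (niches matched by
minimal-cost assignment) of refits at each intensity, averaged over
repeats.

### Synthetic cell tables

Cells are placed by an inhomogeneous Poisson draw per lattice patch and
cell type with intensity ∝ (B·α)(x, y); by default the absolute density
is the bank-implied one (λ = B·α/r), which keeps per-cell niche-weight
estimation consistent with the bank used to solve c = Bα — rescaling
the total cell count while keeping the bank for the solve distorts the
projection and is supported only for analyses that do not use per-cell
weights.  Planted phenotypic markers are baseline + slope·w + Gaussian
noise, with w the cell's true niche or interface weight from the field;
ground truth is returned for test assertions.

What the generator does *not* emulate: cell shapes and segmentation
errors, marker spill-over between neighbouring cells, batch effects and
sample-to-sample niche-composition variability, anisotropic or curved
tissue geometry, and cell-type misassignment noise.  Passing tests on
this substrate therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to those artefacts.

## Macro-scale analysis

Cell-type vocabularies are aligned through a 0/1 incidence matrix; for
each row mapped to several finer columns only the first is kept and
renamed to the row label, so both datasets project onto the
least-granular shared vocabulary (types with no counterpart are dropped
or pooled into "other", per configuration).  The macro simplex fit is
the same centered-unscaled-PCA + archetype pipeline on sample
proportions; θ are refit per sample by the exact solver, and each
sample's out-of-plane PCA remainder is stored so that
C = μ + Σθⱼbⱼ + residual holds exactly.  Dissection of endpoint *k*
renormalises the remaining weights, γⱼ = θⱼ/Σ_{l≠k}θ_l, and rebuilds
C_d = Σγⱼbⱼ + residual + μ (μ added last); samples with θₖ > 0.5 are
discarded because the small remaining weights would amplify dissection
error.  Containment is checked by projecting each composition onto the
simplex and comparing the residual distance to a tolerance.

## Numerical choices and degenerate inputs

- Exact simplex projection: support enumeration, feasibility tolerance
  1e−10, singular supports fall back to least squares; weights are
  clipped at 0 and renormalised, so rows sum to 1 to 1e−9 or better.
- Rank-deficient niche matrices trigger a warning (weights may be
  non-unique) but still solve.
- Constant composition matrices are a PCA error; zero total sum of
  squares is an explained-variance error; degenerate (zero-volume)
  hulls are a t-ratio error.
- Spearman needs ≥ 4 cells and two distinct values per vector.
- Empty cell tables produce an all-zero composition with a warning.
- Serialization (niche models as JSON, tables as CSV) round-trips all
  numeric fields at float precision and refuses to overwrite without an
  explicit flag.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the simulator at its
native scale (50×50 lattice, 326 or 1956 sites) with 20–25 replicates
per condition for power/recovery statements, 100 shuffles for t-ratio
nulls and 100 marker-shuffle replicates for the phenomapping null — the
replication chosen to resolve the probabilities being asserted while
keeping a full run in the tens of minutes on a single CPU.

## Known limitations

- Archetypes are confined to the convex hull of the observed sites;
  with heavy noise and thin sampling the fitted simplex is slightly
  shrunk toward the data (the enclosing-dilation t-ratio quantifies
  exactly this gap).
- The support-enumeration solver is exponential in the niche count and
  capped at 14 vertices.
- The π₀ smoother needs a few hundred p-values to be stable; small
  studies use Benjamini–Hochberg.
- The reaction-diffusion model produces near-binary niche fields with
  thin interfaces; tissues with broad gradients are better emulated by
  lowering β or raising D.
- Mixing-score roles (TLS/inflammatory/cancer) must be assigned by the
  user; the package does not name niches from their composition.
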