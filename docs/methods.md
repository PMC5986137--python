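# Methods

This note documents the statistical procedure implemented by `lasec`, the
choices made where the method leaves room, and what the simulation-based
tests do and do not establish.

## Shape extraction

Raw configurations (n specimens × p landmarks × d ∈ {2, 3}) are assumed
complete; missing values are a hard error and are never imputed. Generalized
Procrustes alignment (GPA) proceeds by:

1. centering each configuration and scaling it to unit centroid size
   (centroid sizes are recorded *before* scaling and keep the original
   units — they are the size variable analyzed by the size channel);
2. initializing by superimposing every configuration onto the first
   specimen. This makes the fixed point reached independent of the input
   orientations: arbitrary per-specimen rotation/translation/scaling is
   absorbed in this step, and the first specimen's own orientation only
   rotates the whole set, which the final canonicalization removes;
3. iterating: rotate each configuration onto the current mean by the
   SVD solution of the orthogonal Procrustes problem, then update the mean
   as the arithmetic average. The total squared distance of the aligned set
   to the arithmetic mean is recorded each sweep; measured this way the
   objective is provably non-increasing (each half-step minimizes it given
   the other). Iteration stops when the objective changes by less than
   `tol` (default 1e-10, absolute) or after `max_iter` sweeps (default
   100); hitting the cap returns a usable result flagged
   `gpa_converged=False` with a warning. A minority of small landmark
   subsets converge slowly (linear rate near 0.9) and trip the cap with
   residual changes around 1e-9, which is inconsequential at the precision
   of the fit statistic;
4. canonicalizing the orientation: the aligned set is unique only up to a
   common orthogonal transform, so everything is rotated onto the principal
   axes of the mean shape with a deterministic sign convention (the
   largest-magnitude coordinate of each axis made positive);
5. projecting onto the tangent space at the mean: with the flattened mean
   m̂ of unit norm, each flattened aligned row x becomes
   x − (x·m̂ − 1) m̂, the orthogonal projection onto the hyperplane tangent
   to the unit pre-shape sphere at m̂.

Reflections are permitted in the rotation step by default, consistent with
the reflection-permissive congruence statistic used downstream;
`allow_reflection=False` restricts to proper rotations for users who need
rigid-only alignment. For configurations with genuinely distinct shapes the
optimal orthogonal transform is unique, so the default rarely differs from
rigid alignment in practice.

## Congruence statistic

The fit between subsampled and parent data is *not* computed on landmark
coordinates but on the specimen constellations in shape space: both
specimen × shape-variable matrices are column-centered and scaled to unit
total sum of squares (symmetric normalization), and the Procrustes sum of
squares after optimal rotation/reflection and scaling is
PSS = 1 − (Σσᵢ)², with σᵢ the singular values of X̃ᵀỸ; fit = 1 − PSS.
Symmetric normalization makes the statistic order-independent and confines
PSS to [0, 1]. Padding the narrower matrix with zero (or constant) columns
to match statistical dimensions adds zero rows/columns to X̃ᵀỸ and leaves
its singular values unchanged, so the implementation works on the original
widths; a test asserts equality with the literally padded computation. The
implementation agrees with the PROTEST statistic of the R package vegan to
1e-9 on shared fixtures (cross-checked in the test suite) and with an
explicit rotation-grid search oracle to 1e-4.

For the one-column size channel the statistic reduces analytically to the
squared Pearson correlation of the two centroid-size vectors; because
reflections are allowed, a perfect negative linear relation also counts as
fit 1. Degenerate inputs (a constellation with zero variance, e.g. three
landmarks coincident in every specimen) raise a dedicated error at the API
level; inside the resampling loop they are recorded as fit 0 with a warning
so that curves stay complete — a measure-zero event for continuous data.

The first-axis correlation from two-block partial least squares is provided
for contrast only: because a landmark subset is a literal subset of the
parent's variables, PLS finds strongly correlated linear combinations even
at severe subsampling and systematically overstates congruence.

## The sampling curve

One iteration draws a uniform random permutation of the p landmarks and
evaluates every prefix of length k = 3 … p (three landmarks being the
minimum that defines shape): GPA is re-run from the raw coordinates of the
k-landmark subset — alignment depends on the subset, so slicing the parent's
aligned coordinates would be wrong — and both channels' fits against the
parent are recorded. The prefix scheme is equivalent to "draw three
landmarks, then add one at random" and lets a stored permutation matrix
reproduce every fit value exactly. At k = p the subsample *is* the parent up
to landmark order — a column permutation of the flat shape variables, under
which the fit statistic is invariant — so the final fit is recorded as
exactly 1 without recomputation; no other value is rounded or snapped.

Defaults: 1000 iterations; thresholds 0.90, 0.95, 0.99; the summary reports
the smallest k whose *median* fit (standard sample median) reaches each
threshold, without interpolation, since landmark counts are integers. A
single user seed spawns one independent substream per iteration
(`numpy` `SeedSequence`), so results are bit-identical across runs and
independent of execution order. Single-landmark additions can transiently
lower the fit; the consistency checked by the tests is therefore on the
median curve's smoothed trend and its endpoint, not strict monotonicity.

## The simulator

`sim_coord` draws each specimen's p·d coordinate vector independently from a
zero-mean multivariate normal with compound-symmetric covariance: common
variance (default 1) on the diagonal and a single covariance (study values
0.1 and 0.5) between every pair of coordinate variables, sampled via the
Cholesky factor; positive definiteness requires covariance/variance ∈
(−1/(p·d − 1), 1) and is validated. The mean is zero — the clouds are not
perturbations of a template shape — and the covariance is global across all
coordinate variables rather than per-landmark blocks; both choices are
deliberate and configurable nowhere, to keep study conditions fixed.

Two consequences of this structure matter when interpreting simulation
results. First, the shared component is the all-ones direction across
coordinate variables, which lies inside the per-specimen translation
subspace; alignment removes it, so after centering the effective coordinate
covariance is isotropic with variance (1 − covariance). The covariance level
therefore rescales the clouds but leaves the sampling curves essentially
unchanged — matching the observation that curve contours are nearly
identical across covariance levels. Second, such clouds have no genuine
size factor: centroid-size variation is pure sampling noise of a χ-type
statistic, and the size-channel fit of a k-landmark subset scales roughly
like k/p. The empirically familiar behavior that a handful of landmarks
suffices to capture size presupposes real size variation among specimens; on
simulated clouds it emerges only where p is modest relative to n, and the
test suite asserts it only on such panels. Passing simulation tests
establish the machinery's correctness and the qualitative
specimen-vs-landmark sampling contrasts, not quantitative landmark counts
for real data, whose variation is far more structured.

## Problem sizes

The test suite and the reproduction script run the simulation study at 50
subsampling iterations on the panel contrasts (10 × 80 vs 80 × 10 specimens
× landmarks, and 2-D vs 3-D at 10 × 40), which is sufficient for stable
medians at the thresholds examined; the package default remains 1000
iterations. Monte-Carlo calibration of the simulator uses 100 000 draws
(tolerance ±0.02 on each covariance entry).

## Limitations

- Sliding semi-landmarks are not supported; curve/surface points are treated
  as fixed landmarks, and TPS files carrying CURVES/POINTS records are
  rejected rather than silently flattened.
- The analysis quantifies how many randomly chosen landmarks suffice; it
  does not identify *which* landmarks to remove. `informed_subsample_fit`
  evaluates a user-chosen subset instead.
- GPA is a local optimizer; the first-specimen initialization and
  canonicalization make it deterministic and orientation-invariant, but, as
  with all GPA implementations, global optimality is not guaranteed.
- No significance testing is attached to fit values; the statistic is
  descriptive.
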