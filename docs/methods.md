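# Methods

## The reference-based mixture model

`scamix` treats each omics sample (a baseline-corrected mass spectrum or a
gene-expression profile with K features) as an additive linear mixture of a
small number of components. Instead of factorizing the whole N x K dataset
at once, every test sample `x` is paired with a *class reference profile* —
the feature-wise mean of the control samples, or of the disease samples —
to form a two-row mixture

    [x_ref; x] = A S,      A in R+^{2 x M},  S in R^{M x K},

with M in {2..5} postulated components. The columns of `A` are constrained
to unit l2 norm and non-negative entries, so each column is fully described
by its *mixing angle* `atan2(A[1,m], A[0,m])` measured from the reference
axis (row 0 = reference, row 1 = test sample; this axis convention is fixed
project-wide). The model assumes disease-specific features are present in
prevailing relative concentration in disease samples and control-specific
features in control samples; features whose concentration is similar in
both classes form "neutral" components. Because decomposition is local
(per sample), a feature's absolute expression may vary across samples and
it is still allocated to the same component.

Selection of components is purely geometric and never consults the labels:
with a control reference the maximal-angle component is labelled
disease-specific and the minimal-angle one control-specific; with a disease
reference the logic is reversed; everything else is neutral. Running both
pairings over all N samples yields four labelled N x K feature-vector sets
(`controlref_disease`, `controlref_control`, `diseaseref_control`,
`diseaseref_disease`) used for classifier training.

## Two-stage sparse component analysis

For M >= 3 the per-column systems are underdetermined (2 equations, M
unknowns) and are solved by a two-stage sparse component analysis:

1. **Mixing estimation.** Both rows are lifted to their analytic signal
   `x + iH(x)` (Hilbert transform along the feature axis, in file order).
   At a feature where essentially one component is active the real and
   quadrature 2-vectors point in the same or opposite direction; feature k
   is kept as a single-component point (SCP) when

       |R_k . I_k| / (||R_k|| ||I_k||) >= cos(delta_theta).

   The absolute value implements the "0 or pi" rule; `delta_theta`
   (grid {1, 3, 5} degrees) trades SCP purity against coverage.
   SCP 2-vectors are normalized, mapped to one half-plane (sign flip when
   the larger-magnitude entry is negative), and clustered by
   complete-linkage agglomerative clustering under the cosine distance into
   exactly M clusters. Hierarchical clustering is used because it is
   deterministic for a given SCP set (k-means is available behind a flag
   but depends on initialisation). Cluster centroids are arithmetic means,
   clipped to the non-negative orthant (baseline-corrected spectra can push
   a coordinate slightly below zero) and renormalized.

2. **Source recovery.** With `A` fixed, all K columns of

       min_S 0.5 ||A S - X||_F^2 + lambda ||S||_1     (optionally S >= 0)

   are solved in one batch by accelerated proximal-gradient (momentum)
   iterations: a gradient step with step size 1/L (L = largest eigenvalue
   of A^T A) followed by soft-thresholding at lambda/L, composed with
   clipping to the orthant for the non-negative variant used on
   gene-expression data. `lambda` is specified relative to
   `lambda_max = max |A^T X|`, the smallest penalty making S = 0 optimal,
   and is computed per two-row mixture (grid {1e-2, 1e-4, 1e-6} times
   lambda_max). Entries below `1e-10 * max|A^T X|` are snapped to exact
   zero on exit, which keeps noise-level residuals from inflating the
   support.

## Numerical choices

* **Solver initialisation.** For a two-row mixture the minimum-l1 exact
  representation of each feature column is a basic solution supported on at
  most two mixing columns. The solver enumerates all M(M-1)/2 column pairs
  (vectorized over K), starts each column at its best-scoring basic
  solution (clipped when the orthant constraint is on; the zero vector
  competes as a candidate), and lets the accelerated iterations perform
  shrinkage and any support corrections. From this vertex the iterations
  converge in tens of steps; a cold start at zero would instead crawl
  through the null space of the rank-2 system at a rate set by lambda and
  need tens of thousands of iterations at lambda = 1e-6 lambda_max. For
  `lambda >= lambda_max` the known optimum S = 0 is used directly and is a
  fixed point of the iterations.
* **Stopping.** Relative objective change below `tol` (default 1e-8) or
  `max_iter` (default 1000). Momentum steps are non-monotone; if the
  objective rises for 10 consecutive iterations the momentum is restarted.
  Property tests that compare final objectives against independent oracles
  (per-column coordinate descent; exact active-set enumeration for the
  non-negative case) request `tol = 1e-13, max_iter = 20000` and agree to
  better than 1e-6 on random small instances.
* **Angular diversity.** When an SCP set spans fewer than M numerically
  distinct directions, `cluster_mixing` raises an error by default; the
  decomposition pipeline instead proceeds with duplicated mixing columns
  (`strict_diversity=False`), which is what the original clustering-based
  procedure does implicitly. At the scaled study size (K = 3000, 50+50
  samples) roughly 1% of decompositions at M = 5 encounter only 4 distinct
  directions; duplicated columns leave selection by extremal angle intact
  (ties resolve to the lowest column index, logged).
* **Clustering cost.** Complete linkage is O(J^2) in the number of SCPs J.
  Oriented unit 2-vectors live on a half-circle where the cosine metric is
  monotone in the 1-D angular separation, so the SCP set is deterministically
  thinned to at most `max_cluster_points` (default 2000) points, evenly
  spaced in sorted-angle order, before linkage. This preserves the cluster
  structure while bounding runtime.
* **Ties and degenerate inputs.** Extremal-angle ties select the lowest
  column index and log a warning. Flat features (zero real or quadrature
  norm) are excluded from SCP candidacy. A constant component vector
  standardizes to the zero vector with a warning. Missing values are a hard
  error throughout.

## Classification protocol

Extracted component vectors are standardized to zero mean and unit variance
*per vector* (across its K features — standardization across the
components; for this pipeline each extracted vector coincides with the
sample it came from, and this direction works markedly better than
per-feature scaling). Support-vector machines with linear, RBF
(`exp(-||x-y||^2 / 2 sigma^2)`, sigma^2 grid 500..1500 by 100) and
polynomial (degree 2-4) kernels are trained with C = 1; only kernel
hyper-parameters are searched.

Performance is estimated by repeated stratified two-fold cross-validation:
each repetition draws a 50/50 stratified split, each half serves once as
training and once as test fold, fold metrics (sensitivity w.r.t. the
disease class, specificity, accuracy) are averaged within a repetition, and
mean and standard deviation are reported over repetitions. Two modes exist:

* `nested` (default): an inner stratified two-fold split of each training
  half selects (M, delta_theta, lambda multiplier, classifier, component
  set) by inner accuracy; the winner is refit on the full training half.
* `sweep`: every grid cell is evaluated on the outer folds and the best
  cell is reported alongside the full per-configuration table — the mode
  used for fixed-parameter validation studies.

With the default `reference_policy="train_only"` the class references are
averaged over training-fold samples only, so a test sample can never
influence the features it is evaluated on. `reference_policy="all"`
reproduces the simpler protocol of averaging all samples into the
references; it leaks a small amount of information across folds and is kept
for comparability. Training samples do contribute to their own fold's
reference average (class means make this unavoidable); no self-exclusion is
performed.

## The synthetic validation model

The generator builds `n_true_components` (default 10) orthogonal components
over K features (default 15000): feature indices are partitioned as evenly
as possible into disjoint supports (contiguous blocks by default; an
interleaved option exists), and within its support a component takes values
from Uniform[0.5, 1.5] — the amplitude law is not dictated by the model;
this default keeps all features positive and comparable in scale.
Component 0 is disease-specific, the last is control-specific, the rest are
neutral. For each sample n and component m a mixing angle `theta[n,m]` is
drawn uniformly from the role's sector — disease [50, 89.99], neutral
[25, 65], control [0.01, 40] degrees — independently per sample and
component. Disease samples mix with weights `sin^2(theta)`, control samples
with `cos^2(theta)`, so each component is shared between the two rules at
an overall concentration of exactly 1 per (sample, component). The heavy
sector overlap is intentional: in many samples neutral features outweigh
the class-specific ones, which is precisely the regime where postulating
extra neutral components (larger M) pays off.

The generator reproduces this statistical structure only: no peak shapes,
baselines, chemical noise, or feature correlations of real spectra or
arrays. Passing tests therefore demonstrate correctness of the machinery
and behaviour under the stated mixture model, not performance on real
clinical data.

## Problem sizes used in tests and the acceptance script

The validation study is run scaled down: K = 3000 features, 10 true
components, 50 + 50 samples, 10 two-fold repetitions, delta_theta = 3,
lambda = 1e-6 lambda_max, linear SVM, with the sweep protocol (the
validation design fixes these parameters rather than cross-validating
them). Under these conditions mean sensitivity and specificity stay
above 94% for every M in {2..5}, and the mean nonzero count of the
selected disease component shrinks monotonically with M (about 2900 at
M = 2 down to about 1000 at M = 5), the parsimony effect that motivates
postulating neutral components. Mixing-angle recovery is checked on
exactly-pure mixtures with interleaved supports (1500 pure features per
component), where recovery is exact to numerical precision; solver
optimality is checked on random small instances against the independent
oracles described above.

## Known limitations

* The linear mixture model is assumed; nonlinear sample models are out of
  scope.
* M is never estimated from data (no model-order selection); it is supplied
  or cross-validated over {2..5}.
* The Hilbert-transform SCP criterion depends on the feature ordering of
  the input file (m/z order); reordering features changes which features
  qualify as SCPs, though recovered components transform equivariantly
  under permutation once the mixing matrix is fixed.
* Contiguous-support synthetic data yields systematically fewer SCPs for
  interior components (quadrature leakage from the block pattern); the
  interleaved-support option avoids this artefact.
* No missing-data mechanism, no vendor format parsers, no biomarker
  ranking or annotation of the selected components.
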