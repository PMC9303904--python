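# Methods

## Data model and scope

A sample is N curves observed on one *common, strictly increasing* grid
`t_1 < … < t_T` spanning `[a, b]`, with optional class labels. Irregular or
per-subject grids are out of scope for this version: the target application
(fixed-rate biomedical signals such as archived ECG heartbeats) is regularly
sampled, and supporting sparse designs would require a conditional-expectation
score estimator rather than direct quadrature. Every integral in the package
is a trapezoidal-rule sum on the observation grid, computed by one shared
routine, so inner products, norms, eigenvalues and variance decompositions
are numerically consistent across modules.

## Functional representations

**B-splines.** Order-4 (cubic) splines by default, equally spaced interior
knots, boundary knots repeated to the order. Coefficients come from ordinary
least squares of each curve on the basis evaluation matrix; no roughness
penalty is applied, so identifiability requires `S ≤ T` and a design of full
column rank (both are checked). The default size is `S = min(25, T)`: large
enough to track heartbeat-scale morphology at typical grid lengths while
keeping the coefficient features well determined. Derivatives for the
derivative semi-metric are taken analytically on the spline representation.

**Principal components.** The decomposition is computed on the raw
discretized curves (smoothing first is possible — pass the evaluated
expansion — but not the default, since the downstream classifiers are
insensitive to small-scale noise and an extra smoothing step would add a
tuning knob). The discretized covariance eigenproblem
`W^{1/2} Cov W^{1/2}` (`W` = quadrature weights) is solved through an SVD of
the weighted centered data matrix; eigenfunctions are mapped back by
`W^{-1/2}`, making them orthonormal in the quadrature inner product, and
scores are quadrature inner products of centered curves with the
eigenfunctions. Consequences used by the tests: training scores have zero
mean and per-column sample variance exactly `λ_k`, and `Σλ_k` equals the
integrated pointwise variance.

Numerical conventions: eigenvalues below `1e-12·λ_1` are numerical rank
noise and are dropped (asking for more components than the sample rank logs
a warning and returns the rank); each eigenfunction's sign is fixed so its
largest-magnitude value is positive, which makes tree thresholds — and
therefore whole fitted models — reproducible. The number of components K is
a user choice (default 15) rather than an explained-variance cutoff:
low-variance components are often the discriminative ones in classification,
so truncating by variance would throw away exactly the features the trees
need. Test-set curves are always projected onto the training eigenfunctions
with training-mean centering; refitting on the test set would yield an
incomparable basis.

## Proximities

Three measures: (1) the weighted L2 distance
`sqrt(∫(x1−x2)² w dt / ∫w dt)` with `w ≡ 1` by default; (2) the r-th
derivative semi-metric `sqrt((1/|T|) ∫ (x1^(r)−x2^(r))² dt)` where `|T|` is
the domain length (the same normalization style as the L2 distance; with
`r = 0` the two coincide); and (3) the score semi-metric — the Euclidean
norm of the difference of K-truncated score vectors, which is what
orthonormal eigenfunctions induce. A per-component weighting (e.g. by
`λ_k`) inside the score semi-metric would be a reasonable variant but is
deliberately not implemented; the unweighted form is the standard one.

## Trees

CART with exhaustive split search: candidate thresholds are midpoints
between consecutive distinct sorted values of each candidate feature; the
split maximizing the impurity decrease (Gini by default, entropy optional)
is chosen, with deterministic tie-breaking (larger decrease, then lower
feature index, then smaller threshold). Rows with feature value strictly
below the threshold go left; equality goes right. Node class ties predict
the label that sorts first and log a warning.

Defaults mirror widespread CART tooling for comparability: `minsplit = 20`,
`minbucket = 7`, `cp = 0.01` (a gate requiring each split's size-weighted
impurity decrease to reach `cp` times the root impurity), depth cap 30.
Forest trees instead use `minsplit = 2`, `minbucket = 1`, `cp = 0` — grown
deep and unpruned.

Pruning is weakest-link cost-complexity on the misclassification risk.
`prune_tree` either prunes directly at a supplied complexity `cp` (scaled by
the root risk; `cp = 0` leaves the tree unchanged, `cp = ∞` collapses it to
the root) or, by default, chooses the penalty minimizing cross-validated
misclassification over the tree's weakest-link sequence (stratified seeded
folds, 10 by default; candidate penalties are geometric means of consecutive
sequence values; error ties prefer the larger penalty, i.e. the simpler
tree). Minimum-CV-error selection is used rather than the one-standard-error
rule — the plain optimum matches the stated goal of an accuracy/complexity
trade-off without an extra conservatism parameter.

## Forests

Bagging and the random forest share one implementation: H bootstrap samples
of size N drawn with replacement, one deep unpruned tree per sample, and a
fresh random subset of `m` features considered at *every split* (per-split,
not per-tree, matching the standard algorithm). `m = P` is exactly bagging;
the default is `m = floor(sqrt(P))`, the classical convention. Predictions
are majority votes with vote fractions returned; ties break toward the
sorted-first label and are flagged. The out-of-bag error votes on each
sample using only trees that did not see it; samples never out of bag are
excluded and reported. Permutation importance is mean decrease accuracy:
per tree, out-of-bag accuracy minus accuracy after permuting one feature
column, averaged over trees. All randomness derives from one integer seed
via `SeedSequence` spawning, so equal seeds give bit-identical models,
votes, and serialized JSON.

## Interpretation

The theoretical splitting curve of an internal node sums
`threshold × basis function` over the *distinct* features on the
root-to-node path. When a feature appears twice on a path, the deepest
threshold is used: it is the constraint actually binding at that node, and
an orthonormal expansion admits only one coefficient per component. The
empirical splitting curve searches the *whole training set* (not the node's
subset) for the curve nearest the theoretical one — under the score
semi-metric against the padded threshold vector (thresholds at path
features, zeros elsewhere, over all K model components, i.e. the exact
coordinates of the theoretical curve in the orthonormal system) for
score-based trees, or under the L2 distance for B-spline trees. Ties take
the lowest training index.

Leaf diagnostics are pointwise curves: deviance `DEV(t)`, its ratio to the
root deviance, the between-group sum of squares `FBGSS(t)` with its ratio to
`DEV(t)`, between-leaf sums of squares for one class over all leaves and
between a leaf and a reference leaf, with binary-outcome TP/FP/TN/FN
specializations. All relative measures follow one convention at degenerate
grid points: where the denominator is zero the value is *masked* (reported
as 0 when the numerator is also 0, as a masked missing value otherwise) —
never an infinity. The denominator of the pairwise relative between-leaf
measure can legitimately vanish wherever the class means coincide across
all leaves; the mask records this rather than guessing an interpretation.
The reference leaf for a class is the leaf predicting that class with the
highest correct-prediction fraction (ties: larger leaf, then lower id); an
alternative `ranking="size"` trades purity for coverage by ranking on the
count of correctly predicted members.

## Synthetic study conditions

The generator draws `x_i(t) = μ_c(t) + Σ_j z_ij ψ_j(t) + ε_i(t)` with
smooth components ψ_j orthonormalized under the grid quadrature (so the
generated eigenstructure is known in closed form), Gaussian amplitudes z and
white noise ε. The default two-class conditions place the class difference
on the *second* component (score offsets ±2, within-class sd 0.5 there — a
~4σ separation) while the first component carries sd-3 amplitude variation
common to both classes, over 100 curves per class on a 100-point unit grid
with noise sd 0.25. This mirrors the situation the method is designed for:
the dominant variance direction is uninformative and the class signal lives
in a lower-variance component, so variance-ranked feature selection would
fail while the trees should not.

What the generator does *not* emulate: physiologic ECG morphology
(P-QRS-T shapes), heteroscedastic or autocorrelated noise, warping/phase
variation, irregular sampling, class imbalance. Passing tests therefore
demonstrate algorithmic correctness and statistical behaviour under a
Gaussian, registered, balanced regime — not clinical performance.

## Problem sizes and limitations

Tests and the acceptance script use curve sets of 60–500 curves on grids of
17–1001 points, forests of up to 200 trees, and 10–20 replicate seeds per
stochastic claim; these sizes make every statistical check comfortably
significant while the full suite runs in seconds. Known limitations:
common-grid requirement; no penalized smoothing (so `S ≤ T` is enforced);
no surrogate splits or missing-value routing; no Fourier/wavelet bases; the
tree prediction loop is pure Python and intended for desk-scale N, not
streaming workloads.
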