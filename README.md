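# functree

Supervised classification of biomedical signals observed as curves —
per-heartbeat ECG traces, EEG windows, spirometry curves — with
**functional classification trees (FCTs)** and **functional random forests
(FRF)**, plus tools that translate the learned classification rules back
into the time domain.

The package is aimed at biostatisticians and methodologists who want
tree-based classifiers for curve data that remain *interpretable*: every
split is tied to a basis function with a known time-domain footprint, and
every leaf can be audited with functional variance diagnostics.

## The method

Each subject contributes a curve `x_i(t)` sampled on a common grid over
`[a, b]`. Instead of feeding the raw high-dimensional samples to a
classifier, the curves are re-expressed in one of two basis systems:

* **Functional principal components (data-driven).** The sample covariance
  operator is discretized with trapezoidal quadrature weights and
  eigendecomposed, giving orthonormal eigenfunctions `ξ_k(t)` (∫ξ_k² dt = 1,
  ∫ξ_j ξ_k dt = 0) with eigenvalues `λ_k`. The feature matrix is the score
  matrix `V = [ν_ik]`, `ν_ik = ⟨x_i − x̄, ξ_k⟩`. New curves are *projected*
  onto the training eigenfunctions, centered by the training mean — the
  decomposition is never refitted on test data.
* **B-splines (fixed basis).** Each curve is least-squares fitted to an
  order-4 B-spline system `φ_s(t)` with equally spaced knots; the feature
  matrix is the coefficient matrix `C = [c_is]`.

A CART-style tree is grown on `V` or `C` (Gini or Shannon–Wiener entropy
impurity, midpoint thresholds, weakest-link cost-complexity pruning by
cross-validation). The forest draws a size-N bootstrap sample per tree,
grows each tree deep and unpruned, and samples `m` candidate features at
every split (`m = P` recovers bagging); out-of-bag votes estimate the error
and permutation of out-of-bag feature columns measures importance (mean
decrease accuracy).

Interpretation tools:

* **TSC** (theoretical splitting curve) of a node: `Σ_{k∈R} ν_0k ξ_k(t)` —
  the thresholds on the root-to-node path, rendered as a curve.
* **ESC** (empirical splitting curve): the *training* curve nearest to the
  TSC (score semi-metric for principal components, L2 for B-splines) — a
  real curve embodying the split rule.
* **Leaf diagnostics**: functional deviance `DEV(t)`, between-group sum of
  squares `FBGSS(t)` (with `DEV = FBGSS + within` pointwise), between-leaf
  sums of squares `FBLSS_g(t)` for one class across leaves or against a
  reference leaf, and TP/FP/TN/FN specializations for binary outcomes.

## Worked example

```python
import numpy as np
import functree as ft

# two-class synthetic curves: the class difference rides on the SECOND
# smooth component; the first carries large non-discriminative variation
curves, truth = ft.generate(ft.separable_spec(), seed=42)

model, scores = ft.fit_fpca(curves, n_components=5)
print(np.round(ft.explained_variance(model), 3))
# [0.684 0.308 0.004 0.    0.   ]

feats = ft.FeatureMatrix.from_scores(scores)
tree = ft.grow_tree(feats, curves.labels)
tree = ft.prune_tree(tree, feats, curves.labels, n_folds=10, seed=42)
print(ft.render_tree(tree))
# node 0: FPC2 < 0.00343757 (n=200, counts=100/100, gain=0.5)
#   leaf 1: predict 1 (n=100, counts=0/100)
#   leaf 2: predict 0 (n=100, counts=100/0)

forest = ft.fit_forest(feats, curves.labels, n_trees=50, seed=42)
print(f"OOB accuracy: {1 - ft.oob_error(forest, feats, curves.labels).error:.3f}")
# OOB accuracy: 1.000
print(np.round(ft.permutation_importance(forest, feats, curves.labels, seed=42), 4))
# [ 3.000e-04  4.666e-01  1.100e-03 -3.000e-04 -1.500e-03]
```

The tree splits on the *second* principal component, not the first: the
leading component carries 68% of the variance but none of the class signal,
and the importance vector singles FPC2 out — exactly the behaviour the
score representation is meant to expose. `ft.tsc`/`ft.esc` then render that
root split as a curve, and `ft.leaf_diagnostics` audits the two leaves.

## Command line

```sh
functree simulate --seed 5 --out train.ts
functree fit --data train.ts --basis fpc --n-fpcs 5 --model forest \
             --n-trees 50 --seed 2 --out bundle/
functree predict   --bundle bundle/ --data test.ts  --out preds.csv
functree importance --bundle bundle/ --data train.ts --seed 2 --out imp.csv
functree fit --data train.ts --model tree --seed 2 --out tb/
functree interpret --bundle tb/ --data train.ts --out report/
```

`fit` writes a bundle directory (manifest, decomposition, model as JSON)
that `predict`/`interpret`/`importance` consume; `interpret` emits per-leaf
tables and tidy per-grid-point diagnostic curves. Readers accept UCR/UEA
`.ts` files and label-first delimited text (the common ECG archive layout).

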