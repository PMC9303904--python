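"""Splitting curves and functional leaf-variability diagnostics."""

import numpy as np
import pytest

import functree as ft
from functree.tree import TreeParams

SMALL = TreeParams(minsplit=2, minbucket=1, cp=0.0)


@pytest.fixture(scope="module")
def fitted_pipeline():
    """Curves, decomposition, features and a fitted tree on separable data."""
    curves, _ = ft.generate(ft.separable_spec(n_per_class=40, n_grid=60), seed=13)
    model, scores = ft.fit_fpca(curves, n_components=5)
    feats = ft.FeatureMatrix.from_scores(scores)
    tree = ft.grow_tree(feats, curves.labels, params=SMALL)
    return curves, model, scores, feats, tree


class TestSplittingCurves:
    def test_root_tsc_is_scaled_eigenfunction(self, fitted_pipeline):
        curves, model, _, _, tree = fitted_pipeline
        root = tree.root
        curve = ft.tsc(tree, root.node_id, model)
        expected = root.threshold * model.eigenfunctions[root.feature]
        assert np.allclose(curve, expected)

    def test_leaf_rejected(self, fitted_pipeline):
        _, model, _, _, tree = fitted_pipeline
        leaf = tree.leaves()[0]
        with pytest.raises(ValueError, match="internal"):
            ft.tsc(tree, leaf.node_id, model)

    def test_duplicate_feature_uses_deepest_threshold(self):
        """When one feature is split twice on a path, the binding (deeper)
        threshold defines the splitting curve."""
        # labels alternate along a single feature -> repeated splits on it
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        tree = ft.grow_tree(X, ["a", "b", "b", "a"], params=SMALL)
        grid = np.linspace(0, 1, 20)
        xi = np.ones((1, 20))
        model = ft.FPCAModel(
            grid=grid, mean_curve=np.zeros(20), eigenfunctions=xi,
            eigenvalues=np.array([1.0]),
            weights=ft.trapezoid_weights(grid), total_variance=1.0,
        )
        # find an internal node below the root splitting the same feature
        deeper = [n for n in tree.internal_nodes() if n.depth > 0]
        assert deeper, "fixture should produce a depth-2 tree"
        node = deeper[0]
        curve = ft.tsc(tree, node.node_id, model)
        assert np.allclose(curve, node.threshold * xi[0])

    def test_bspline_tsc(self):
        grid = np.linspace(0, 1, 50)
        basis = ft.BSplineBasis((0, 1), 6)
        rng = np.random.default_rng(0)
        coefs = rng.normal(size=(20, 6))
        labels = np.where(coefs[:, 2] > 0, "hi", "lo")
        feats = ft.FeatureMatrix.from_expansion(
            ft.BasisExpansion(basis, coefs, grid)
        )
        tree = ft.grow_tree(feats, labels, params=SMALL)
        curve = ft.tsc(tree, tree.root.node_id, basis, grid=grid)
        phi = basis.design_matrix(grid)
        assert np.allclose(curve, tree.root.threshold * phi[:, tree.root.feature])

    def test_esc_exact_match_distance_zero(self, fitted_pipeline):
        curves, model, scores, _, tree = fitted_pipeline
        target = np.zeros(scores.n_components)
        for k, theta in _path_dict(tree).items():
            target[k] = theta
        doctored_scores = ft.ScoreMatrix(
            np.vstack([target, scores.values]), scores.eigenvalues
        )
        doctored_curves = ft.CurveSet(
            curves.grid, np.vstack([curves.values[:1], curves.values])
        )
        idx, _ = ft.esc(tree, tree.root.node_id, doctored_curves,
                        train_scores=doctored_scores, basis=model)
        assert idx == 0

    def test_esc_prefers_near_zero_scores(self, fitted_pipeline):
        curves, model, _, _, tree = fitted_pipeline
        K = model.n_components
        scores = ft.ScoreMatrix(
            np.vstack([np.zeros(K), np.full(K, 10.0)]), model.eigenvalues
        )
        two = ft.CurveSet(curves.grid, curves.values[:2])
        idx, curve = ft.esc(tree, tree.root.node_id, two,
                            train_scores=scores, basis=model)
        assert idx == 0
        assert np.array_equal(curve, two.values[0])

    def test_esc_is_argmin(self, fitted_pipeline):
        curves, model, scores, _, tree = fitted_pipeline
        idx, _ = ft.esc(tree, tree.root.node_id, curves,
                        train_scores=scores, basis=model)
        target = np.zeros(scores.n_components)
        for k, theta in _path_dict(tree).items():
            target[k] = theta
        dists = np.linalg.norm(scores.values - target, axis=1)
        assert dists[idx] == dists.min()

    def test_esc_bspline_uses_l2(self):
        grid = np.linspace(0, 1, 50)
        basis = ft.BSplineBasis((0, 1), 6)
        rng = np.random.default_rng(1)
        coefs = rng.normal(size=(20, 6))
        labels = np.where(coefs[:, 2] > 0, "hi", "lo")
        exp = ft.BasisExpansion(basis, coefs, grid)
        curves = ft.CurveSet(grid, ft.evaluate_expansion(exp, grid), labels)
        tree = ft.grow_tree(ft.FeatureMatrix.from_expansion(exp), labels,
                            params=SMALL)
        idx, _ = ft.esc(tree, tree.root.node_id, curves, basis=basis)
        curve = ft.tsc(tree, tree.root.node_id, basis, grid=grid)
        dists = [ft.l2_distance(x, curve, grid) for x in curves.values]
        assert dists[idx] == min(dists)


def _path_dict(tree):
    return {tree.root.feature: tree.root.threshold}


class TestLeafVariability:
    def test_single_curve_leaf_zero_deviance(self):
        assert np.all(ft.leaf_deviance(np.ones((1, 5))) == 0)

    def test_two_constant_curves(self):
        vals = np.vstack([np.ones(4), 3 * np.ones(4)])
        assert np.allclose(ft.leaf_deviance(vals), 2.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 8))
        shifted = vals + 17.3
        assert np.allclose(ft.leaf_deviance(vals), ft.leaf_deviance(shifted))

    def test_rel_deviance_whole_set_is_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(5, 7))
        rel = ft.rel_leaf_deviance(vals, vals)
        assert np.allclose(np.ma.getdata(rel), 1.0)

    def test_rel_deviance_masks_degenerate_points(self):
        root = np.vstack([np.zeros(3), np.array([0.0, 1.0, 0.0])])
        rel = ft.rel_leaf_deviance(root[:1], root)
        assert np.ma.getmaskarray(rel)[0] and np.ma.getmaskarray(rel)[2]
        assert not np.ma.getmaskarray(rel)[1]

    def test_fbgss_singleton_groups(self):
        vals = np.vstack([np.ones(4), 3 * np.ones(4)])
        between, rel = ft.fbgss(vals, ["A", "B"])
        assert np.allclose(between, 2.0)
        assert np.allclose(np.ma.getdata(rel), 1.0)

    def test_fbgss_one_group_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(4, 6))
        between, _ = ft.fbgss(vals, ["A"] * 4)
        assert np.allclose(between, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_anova_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        vals = rng.normal(size=(n, 9))
        labels = rng.choice(["a", "b", "c"], size=n)
        between, _ = ft.fbgss(vals, labels)
        within = np.zeros(9)
        for g in np.unique(labels):
            within += ft.leaf_deviance(vals[labels == g])
        assert np.allclose(between + within, ft.leaf_deviance(vals), atol=1e-8)
        assert np.all(between <= ft.leaf_deviance(vals) + 1e-10)


class TestConfusionRoles:
    def _leaf(self, members, predicted, labels):
        diag = ft.LeafDiagnostics(
            leaf_id=1, members=np.asarray(members), n=len(members),
            predicted_class=predicted,
            group_counts={}, mean=np.zeros(3), group_means={},
            deviance=np.zeros(3), rel_deviance=np.ma.MaskedArray(np.zeros(3)),
            between_group=np.zeros(3),
            rel_between_group=np.ma.MaskedArray(np.zeros(3)),
        )
        return diag

    def test_positive_leaf_roles(self):
        leaf = self._leaf([0, 1, 2], "+", None)
        roles = ft.confusion_roles(leaf, np.array(["+", "+", "-"]), "+")
        assert list(roles) == ["TP", "TP", "FP"]

    def test_negative_leaf_roles(self):
        leaf = self._leaf([0, 1], "-", None)
        roles = ft.confusion_roles(leaf, np.array(["-", "+"]), "+")
        assert list(roles) == ["TN", "FN"]

    def test_multiclass_rejected(self):
        leaf = self._leaf([0, 1, 2], "a", None)
        with pytest.raises(ValueError, match="binary"):
            ft.confusion_roles(leaf, np.array(["a", "b", "c"]), "a")


class TestBetweenLeaves:
    @staticmethod
    def _diag(leaf_id, values_by_group):
        values = np.vstack([v for vs in values_by_group.values() for v in vs])
        counts = {g: len(vs) for g, vs in values_by_group.items()}
        means = {g: np.mean(vs, axis=0) for g, vs in values_by_group.items()}
        pred = max(counts, key=counts.get)
        return ft.LeafDiagnostics(
            leaf_id=leaf_id, members=np.arange(values.shape[0]),
            n=values.shape[0], predicted_class=pred, group_counts=counts,
            mean=values.mean(axis=0), group_means=means,
            deviance=ft.leaf_deviance(values),
            rel_deviance=np.ma.MaskedArray(np.zeros(values.shape[1])),
            between_group=np.zeros(values.shape[1]),
            rel_between_group=np.ma.MaskedArray(np.zeros(values.shape[1])),
        )

    def test_single_leaf_group_zero(self):
        d = self._diag(1, {"g": [np.ones(4)] * 3})
        assert np.allclose(ft.fblss_all([d], "g"), 0.0)

    def test_two_leaf_hand_computation(self):
        # group g split as {0} in leaf 1 and {4,4,4} in leaf 2:
        # pooled mean 3, FBLSS = 1*9 + 3*1 = 12
        d1 = self._diag(1, {"g": [np.zeros(5)]})
        d2 = self._diag(2, {"g": [np.full(5, 4.0)] * 3})
        total = ft.fblss_all([d1, d2], "g")
        assert np.allclose(total, 12.0)
        pair, rel = ft.fblss_pair([d1, d2], 1, 2, "g")
        assert np.allclose(pair, 12.0)
        assert np.allclose(np.ma.getdata(rel), 1.0)
        assert not np.any(np.ma.getmaskarray(rel))

    def test_weighted_centering_identity(self):
        rng = np.random.default_rng(8)
        leaves = [
            self._diag(1, {"g": list(rng.normal(size=(3, 6)))}),
            self._diag(2, {"g": list(rng.normal(size=(5, 6)))}),
        ]
        counts = np.array([3.0, 5.0])
        means = np.stack([l.group_means["g"] for l in leaves])
        overall = (counts[:, None] * means).sum(axis=0) / counts.sum()
        resid = (counts[:, None] * (means - overall)).sum(axis=0)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_same_leaf_pair_zero(self):
        d = self._diag(1, {"g": [np.ones(4)] * 2})
        pair, _ = ft.fblss_pair([d], 1, 1, "g")
        assert np.allclose(pair, 0.0)

    def test_identical_group_means_zero(self):
        d1 = self._diag(1, {"g": [np.ones(4)] * 2})
        d2 = self._diag(2, {"g": [np.ones(4)] * 5})
        pair, rel = ft.fblss_pair([d1, d2], 1, 2, "g")
        assert np.allclose(pair, 0.0)
        assert np.all(np.ma.getmaskarray(rel))  # 0/0 everywhere -> masked

    def test_absent_group_rejected(self):
        d = self._diag(1, {"g": [np.ones(4)]})
        with pytest.raises(ValueError, match="absent"):
            ft.fblss_all([d], "h")


class TestReferenceLeaf:
    @staticmethod
    def _leaf(leaf_id, predicted, n_correct, n_total):
        other = "other"
        return ft.LeafDiagnostics(
            leaf_id=leaf_id, members=np.arange(n_total), n=n_total,
            predicted_class=predicted,
            group_counts={predicted: n_correct, other: n_total - n_correct},
            mean=np.zeros(3), group_means={},
            deviance=np.zeros(3), rel_deviance=np.ma.MaskedArray(np.zeros(3)),
            between_group=np.zeros(3),
            rel_between_group=np.ma.MaskedArray(np.zeros(3)),
        )

    def test_highest_purity_wins(self):
        leaves = [self._leaf(1, "c", 95, 100), self._leaf(2, "c", 92, 100)]
        assert ft.select_reference_leaf(leaves, "c") == 1

    def test_purity_tie_prefers_larger_leaf(self):
        leaves = [self._leaf(1, "c", 11, 22), self._leaf(2, "c", 31, 62),
                  self._leaf(3, "c", 2, 63)]
        assert ft.select_reference_leaf(leaves, "c") == 2

    def test_size_ranking_option(self):
        leaves = [self._leaf(1, "c", 10, 10), self._leaf(2, "c", 90, 100)]
        assert ft.select_reference_leaf(leaves, "c") == 1
        assert ft.select_reference_leaf(leaves, "c", ranking="size") == 2

    def test_no_leaf_predicts_class(self):
        leaves = [self._leaf(1, "c", 5, 5)]
        with pytest.raises(ValueError, match="no leaf"):
            ft.select_reference_leaf(leaves, "d")


class TestLeafDiagnosticsPipeline:
    def test_diagnostics_consistent_with_tree(self, fitted_pipeline):
        curves, _, _, feats, tree = fitted_pipeline
        diags = ft.leaf_diagnostics(tree, curves)
        assert {d.leaf_id for d in diags} == {l.leaf_id for l in tree.leaves()}
        assert sum(d.n for d in diags) == curves.n_curves
        for d in diags:
            assert sum(d.group_counts.values()) == d.n
            assert np.all(np.ma.getdata(d.rel_between_group) <= 1.0 + 1e-12)
            assert np.all(d.between_group <= d.deviance + 1e-8)

    def test_diagnostics_invariant_to_constant_shift(self, fitted_pipeline):
        curves, _, _, feats, tree = fitted_pipeline
        shifted = ft.CurveSet(curves.grid, curves.values + 5.0, curves.labels)
        d0 = ft.leaf_diagnostics(tree, curves)
        d1 = ft.leaf_diagnostics(tree, shifted)
        for a, b in zip(d0, d1):
            assert np.allclose(a.deviance, b.deviance)
            assert np.allclose(a.between_group, b.between_group)
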