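import json

import numpy as np
import pytest

from seldi_nodal.oblique_tree import (
    LeafNode,
    SplitNode,
    TreeModel,
    TreeParams,
    best_axis_split,
    best_oblique_split,
    cross_validate,
    fit_tree,
    gini_impurity,
    predict,
    predict_matrix,
    published_tree,
    variable_importance,
)
from seldi_nodal.spectra_io import NODE_NEGATIVE, NODE_POSITIVE, write_tree_model
from seldi_nodal.synthetic_data import (
    default_generator_config,
    generate_feature_matrix,
    table1_params,
)

FAST = TreeParams(n_restarts=5, cv_folds=3, seed=0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _gini_oracle(labels):
    labels = list(labels)
    n = len(labels)
    return 1.0 - sum((labels.count(c) / n) ** 2 for c in set(labels))


def _decrease_oracle(y, left_mask):
    y = list(y)
    left = [v for v, m in zip(y, left_mask) if m]
    right = [v for v, m in zip(y, left_mask) if not m]
    if not left or not right:
        return 0.0
    n = len(y)
    return (_gini_oracle(y) - len(left) / n * _gini_oracle(left)
            - len(right) / n * _gini_oracle(right))


def _axis_oracle(x, y):
    """Enumerate every midpoint threshold; return the best decrease."""
    xs = sorted(set(x))
    best = 0.0
    for a, b in zip(xs, xs[1:]):
        thr = (a + b) / 2
        best = max(best, _decrease_oracle(y, [v <= thr for v in x]))
    return best


def _oblique_2d_oracle(X, y):
    """Exact best linear-partition decrease for 2 features.

    Every achievable partition is realized by a direction normal to some
    pairwise difference of points (plus the axes); enumerate them all and
    scan every threshold.
    """
    X = np.asarray(X, float)
    n = len(X)
    directions = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    for i in range(n):
        for j in range(i + 1, n):
            d = X[i] - X[j]
            if np.allclose(d, 0):
                continue
            directions.append(np.array([-d[1], d[0]]))
            directions.append(d)
    best = 0.0
    for w in directions:
        v = X @ w
        best = max(best, _axis_oracle(v.tolist(), y))
    return best


# ---------------------------------------------------------------------------
# gini
# ---------------------------------------------------------------------------

class TestGini:
    def test_pure_node(self):
        assert gini_impurity([10, 0]) == 0.0

    def test_maximal_two_class(self):
        assert gini_impurity([5, 5]) == 0.5

    def test_66_4_arithmetic(self):
        expected = 1 - (66 / 70) ** 2 - (4 / 70) ** 2
        assert gini_impurity([66, 4]) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0])

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            gini_impurity([-1, 5])

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 3, 12)
            counts = np.bincount(labels, minlength=3)
            assert gini_impurity(counts) == pytest.approx(
                _gini_oracle(labels), rel=1e-12)


# ---------------------------------------------------------------------------
# axis splits
# ---------------------------------------------------------------------------

class TestBestAxisSplit:
    def test_perfect_separation_decrease_equals_parent(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        y = ["a", "a", "a", "b", "b", "b"]
        thr, dec = best_axis_split(X, y, 0)
        assert 3.0 < thr < 10.0
        assert dec == pytest.approx(0.5, rel=1e-12)

    def test_six_point_brute_force(self, rng):
        for _ in range(25):
            x = rng.uniform(0, 10, 6)
            y = rng.choice(["a", "b"], 6).tolist()
            if len(set(y)) < 2:
                continue
            _, dec = best_axis_split(x.reshape(-1, 1), y, 0)
            assert dec == pytest.approx(_axis_oracle(x.tolist(), y),
                                        abs=1e-12)

    def test_label_permutation_invariance(self):
        X = np.array([[1.0], [4.0], [2.0], [9.0], [7.0], [3.0]])
        y1 = ["a", "b", "a", "b", "b", "a"]
        y2 = ["b", "a", "b", "a", "a", "b"]
        t1, d1 = best_axis_split(X, y1, 0)
        t2, d2 = best_axis_split(X, y2, 0)
        assert t1 == t2 and d1 == pytest.approx(d2, rel=1e-12)

    def test_constant_feature(self):
        X = np.ones((6, 1))
        thr, dec = best_axis_split(X, ["a", "b", "a", "b", "a", "b"], 0)
        assert thr is None and dec == 0.0

    def test_tie_breaks_to_smaller_threshold(self):
        # symmetric data: two equally good thresholds
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = ["a", "b", "a", "b"]
        thr, _ = best_axis_split(X, y, 0)
        assert thr == 1.5


# ---------------------------------------------------------------------------
# oblique splits
# ---------------------------------------------------------------------------

class TestBestObliqueSplit:
    def test_diagonal_separable_beats_axis(self):
        # separable only by x1 + x2
        X = np.array([[0.0, 1.0], [1.0, 0.0], [0.2, 0.6], [0.6, 0.2],
                      [1.0, 1.1], [1.1, 1.0], [1.8, 0.4], [0.4, 1.8]])
        y = ["a"] * 4 + ["b"] * 4
        best_axis = max(best_axis_split(X, y, j)[1] for j in range(2))
        coef, thr, dec = best_oblique_split(X, y, params=FAST)
        assert dec > best_axis
        assert dec == pytest.approx(0.5, abs=1e-9)  # perfect split

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_2d_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 9))
        X = rng.uniform(0, 10, (n, 2))
        y = rng.choice(["a", "b"], n).tolist()
        if len(set(y)) < 2:
            y[0] = "a" if y[0] == "b" else "b"
        _, _, dec = best_oblique_split(X, y, params=TreeParams(n_restarts=20))
        oracle = _oblique_2d_oracle(X, y)
        assert dec == pytest.approx(oracle, abs=1e-6)

    def test_dominance_over_axis(self, rng):
        for seed in range(8):
            r = np.random.default_rng(seed)
            X = r.uniform(0, 5, (20, 5))
            y = r.choice(["a", "b"], 20).tolist()
            if len(set(y)) < 2:
                continue
            axis_best = max(best_axis_split(X, y, j)[1] for j in range(5))
            _, _, dec = best_oblique_split(X, y, params=FAST)
            assert dec >= axis_best - 1e-12

    def test_single_feature_reduces_to_axis(self):
        X = np.array([[1.0], [2.0], [5.0], [6.0]])
        y = ["a", "a", "b", "b"]
        thr_axis, dec_axis = best_axis_split(X, y, 0)
        coef, thr, dec = best_oblique_split(X, y, candidate_features=[0])
        assert dec == pytest.approx(dec_axis, rel=1e-12)
        assert coef == {"x0": 1.0}
        assert thr == pytest.approx(thr_axis, rel=1e-12)

    def test_unit_max_magnitude_convention(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.1], [1.8, 0.4],
                      [0.3, 0.2], [1.5, 1.6]])
        y = ["a", "a", "b", "b", "a", "b"]
        coef, _, _ = best_oblique_split(X, y, params=FAST)
        assert max(abs(v) for v in coef.values()) == pytest.approx(1.0)

    def test_pure_node_no_split(self):
        X = np.random.default_rng(0).uniform(0, 1, (6, 2))
        coef, thr, dec = best_oblique_split(X, ["a"] * 6, params=FAST)
        assert coef is None and dec == 0.0


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

class TestFitTree:
    def test_separable_resubstitution_perfect(self, default_config):
        m = generate_feature_matrix(default_config, 20, 20, seed=4)
        model = fit_tree(m, params=TreeParams(prune=False, min_node_size=1,
                                              seed=0))
        preds = predict_matrix(model, m)
        assert preds == m.labels

    def test_fully_grown_zero_resub_error_random_labels(self, rng):
        # no duplicated conflicting vectors -> zero resubstitution error
        X = rng.uniform(0, 1, (30, 3))
        y = rng.choice([NODE_POSITIVE, NODE_NEGATIVE], 30).tolist()
        import pandas as pd
        df = pd.DataFrame(X, columns=["mz_1000", "mz_2000", "mz_3000"])
        model = fit_tree(df, y, params=TreeParams(prune=False, min_node_size=1,
                                                  n_restarts=3, seed=1))
        assert predict_matrix(model, df) == y

    def test_pruned_tree_is_small(self, default_config):
        for seed in range(3):
            m = generate_feature_matrix(default_config, 70, 75, seed=seed)
            model = fit_tree(m, params=TreeParams(seed=0))
            assert model.n_splits <= 5

    def test_determinism(self, tmp_path, default_config):
        m = generate_feature_matrix(default_config, 20, 20, seed=4)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_tree_model(fit_tree(m, params=TreeParams(seed=3)), p1)
        write_tree_model(fit_tree(m, params=TreeParams(seed=3)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_class_single_leaf(self):
        import pandas as pd
        df = pd.DataFrame({"mz_1000": [1.0, 2.0, 3.0]})
        model = fit_tree(df, [NODE_POSITIVE] * 3, params=FAST)
        assert model.n_splits == 0 and model.n_leaves == 1
        assert model.nodes[model.root_id].label == NODE_POSITIVE

    def test_empty_data_errors(self):
        import pandas as pd
        with pytest.raises(ValueError):
            fit_tree(pd.DataFrame({"x": []}), [], params=FAST)


class TestPredict:
    def test_published_tree_positive_mean_vector(self, table1_mean_vectors):
        pos, _ = table1_mean_vectors
        # hand arithmetic on the published splitter
        value = (-0.075 * pos["mz_3104"] - 0.231 * pos["mz_3781"]
                 + 0.157 * pos["mz_5867"] + 0.086 * pos["mz_7970"]
                 + 0.953 * pos["mz_9290"])
        assert value > 1.122  # routes RIGHT, straight to a positive terminal
        label, path = predict(published_tree(), pos)
        assert label == NODE_POSITIVE
        assert path == [1, 3]

    def test_published_tree_negative_mean_vector(self, table1_mean_vectors):
        _, neg = table1_mean_vectors
        v1 = (-0.075 * neg["mz_3104"] - 0.231 * neg["mz_3781"]
              + 0.157 * neg["mz_5867"] + 0.086 * neg["mz_7970"]
              + 0.953 * neg["mz_9290"])
        v2 = 0.410 * neg["mz_3781"] - 0.912 * neg["mz_5867"]
        assert v1 <= 1.122 and v2 > 0.248
        label, path = predict(published_tree(), neg)
        assert label == NODE_NEGATIVE
        assert path == [1, 2, 5]

    def test_boundary_routes_left(self):
        model = TreeModel(nodes={
            1: SplitNode(1, {"mz_5000": 1.0}, threshold=2.0,
                         left_child=2, right_child=3),
            2: LeafNode(2, NODE_NEGATIVE),
            3: LeafNode(3, NODE_POSITIVE),
        }, root_id=1)
        label, _ = predict(model, {"mz_5000": 2.0})  # exactly on threshold
        assert label == NODE_NEGATIVE

    def test_missing_feature_names_mz(self):
        with pytest.raises(KeyError, match="mz_9290"):
            predict(published_tree(), {"mz_3104": 1.0, "mz_3781": 1.0,
                                       "mz_5867": 1.0, "mz_7970": 1.0})


class TestPublishedTree:
    def test_five_features(self):
        assert published_tree().features() == [
            "mz_3104", "mz_3781", "mz_5867", "mz_7970", "mz_9290"]

    def test_three_leaves_two_splits(self):
        model = published_tree()
        assert model.n_leaves == 3 and model.n_splits == 2

    def test_topology_consistency_exhaustive(self, table1_mean_vectors):
        # of the two candidate placements of the second splitter, only
        # "left child of the root" routes both class means correctly
        pos, neg = table1_mean_vectors

        def build(node2_on_left):
            split2 = SplitNode(2, {"mz_3781": 0.410, "mz_5867": -0.912},
                               0.248, left_child=4, right_child=5)
            split1 = SplitNode(1, {"mz_3104": -0.075, "mz_3781": -0.231,
                                   "mz_5867": 0.157, "mz_7970": 0.086,
                                   "mz_9290": 0.953}, 1.122,
                               left_child=2 if node2_on_left else 3,
                               right_child=3 if node2_on_left else 2)
            return TreeModel(nodes={
                1: split1, 2: split2,
                3: LeafNode(3, NODE_POSITIVE),
                4: LeafNode(4, NODE_POSITIVE),
                5: LeafNode(5, NODE_NEGATIVE),
            }, root_id=1)

        consistent = [
            on_left for on_left in (True, False)
            if predict(build(on_left), pos)[0] == NODE_POSITIVE
            and predict(build(on_left), neg)[0] == NODE_NEGATIVE
        ]
        assert consistent == [True]
        # and the shipped tree uses that topology
        assert published_tree().nodes[1].left_child == 2

    def test_bulk_error_below_one_percent(self, default_config):
        # 10,000 samples per class drawn independently in the test
        rng = np.random.default_rng(42)
        n = 10_000
        model = published_tree()
        for label, attr in ((NODE_POSITIVE, "mean_pos"),
                            (NODE_NEGATIVE, "mean_neg")):
            cols = {}
            for p in table1_params():
                mean = getattr(p, attr)
                sd = p.sd_pos if label == NODE_POSITIVE else p.sd_neg
                cols[f"mz_{int(p.mz_center)}"] = np.maximum(
                    rng.normal(mean, sd, n), 0.0)
            import pandas as pd
            preds = predict_matrix(model, pd.DataFrame(cols))
            err = np.mean([p != label for p in preds])
            assert err < 0.01, label


class TestVariableImportance:
    def test_top_score_exactly_100(self, default_config):
        m = generate_feature_matrix(default_config, 30, 30, seed=2)
        model = fit_tree(m, params=FAST)
        scores = variable_importance(model, m)
        assert max(scores.values()) == 100.0

    def test_unused_feature_zero(self, default_config):
        m = generate_feature_matrix(default_config, 30, 30, seed=2)
        model = fit_tree(m, params=FAST)
        used = set(model.features())
        for feat, score in variable_importance(model, m).items():
            if feat not in used:
                assert score == 0.0

    def test_range(self, default_config):
        m = generate_feature_matrix(default_config, 30, 30, seed=5)
        scores = variable_importance(fit_tree(m, params=FAST), m)
        assert all(0.0 <= v <= 100.0 for v in scores.values())


class TestCrossValidate:
    def test_separable_data_perfect(self, rng):
        import pandas as pd
        # wide-margin construction: any reasonable split generalizes
        X = np.concatenate([rng.normal(0.0, 0.1, 30), rng.normal(10.0, 0.1, 30)])
        df = pd.DataFrame({"mz_5000": X, "mz_6000": rng.uniform(0, 1, 60)})
        y = [NODE_POSITIVE] * 30 + [NODE_NEGATIVE] * 30
        report = cross_validate(df, y, params=TreeParams(cv_folds=5,
                                                         n_restarts=5, seed=0))
        assert report.accuracy == 100.0
        assert len(report.fold_reports) == 5

    def test_permuted_labels_near_chance(self, default_config):
        rng = np.random.default_rng(0)
        m = generate_feature_matrix(default_config, 30, 30, seed=7)
        labels = list(m.labels)
        rng.shuffle(labels)
        m.labels = labels
        report = cross_validate(m, params=TreeParams(cv_folds=5, n_restarts=3,
                                                     seed=0))
        # majority-class rate is 50%; allow generous binomial noise
        assert report.accuracy <= 70.0

    def test_deterministic(self, default_config):
        m = generate_feature_matrix(default_config, 20, 20, seed=8)
        params = TreeParams(cv_folds=4, n_restarts=3, seed=5)
        r1 = cross_validate(m, params=params)
        r2 = cross_validate(m, params=params)
        assert r1.as_dict() == r2.as_dict()

    def test_too_many_folds(self, default_config):
        m = generate_feature_matrix(default_config, 4, 30, seed=9)
        with pytest.raises(ValueError, match="cv_folds"):
            cross_validate(m, params=TreeParams(cv_folds=10, seed=0))


class TestModelValidation:
    def test_dangling_child(self):
        nodes = {1: SplitNode(1, {"x": 1.0}, 0.0, 2, 99),
                 2: LeafNode(2, NODE_POSITIVE)}
        with pytest.raises(ValueError, match="dangling"):
            TreeModel(nodes=nodes, root_id=1).validate()

    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            SplitNode(1, {"x": 0.0}, 0.0, 2, 3)

    def test_serialization_preserves_predictions(self, tmp_path,
                                                 default_config, rng):
        from seldi_nodal.spectra_io import read_tree_model

        m = generate_feature_matrix(default_config, 15, 15, seed=10)
        model = fit_tree(m, params=FAST)
        write_tree_model(model, tmp_path / "m.json")
        back = read_tree_model(tmp_path / "m.json")
        assert predict_matrix(back, m) == predict_matrix(model, m)
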