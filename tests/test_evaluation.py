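import itertools

import numpy as np
import pytest

from pwlnet import (
    LabelVector,
    SearchSpace,
    double_cross_validate,
    inner_cv_objective,
    mean_auc,
    per_class_auc,
    tukey_comparison,
)
from pwlnet.simulate import make_subtype_dataset

from conftest import feature_matrix


def auc_by_pair_counting(scores, labels):
    """(concordant + ties/2) / (n_pos * n_neg) over all pos-neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    num = 0.0
    for p, n in itertools.product(pos, neg):
        num += 1.0 if p > n else (0.5 if p == n else 0.0)
    return num / (len(pos) * len(neg))


class StubEstimator:
    """Scores equal to the one-hot truth: perfect separation."""

    def __init__(self, params):
        self.params = params

    def fit(self, X, y):
        self.class_order = list(y.class_order)
        return self

    def predict_proba(self, X):
        # labels are recoverable from sample ids in these fixtures
        raise NotImplementedError


class TestPerClassAUC:
    def test_perfect_scores_give_unit_auc(self):
        y = LabelVector(["a", "a", "b", "b"], class_order=["a", "b"])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        np.testing.assert_allclose(per_class_auc(scores, y), [1.0, 1.0])

    def test_constant_scores_give_half(self):
        y = LabelVector(["a", "a", "b"], class_order=["a", "b"])
        np.testing.assert_allclose(per_class_auc(np.full((3, 2), 0.5), y), [0.5, 0.5])

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.integers(0, 2, size=6)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 4, size=6).astype(float)  # ties likely
            y = LabelVector([str(l) for l in labels], class_order=["0", "1"])
            mat = np.column_stack([-scores, scores])
            got = per_class_auc(mat, y)[1]
            assert got == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_class_without_negatives_is_nan_with_warning(self):
        y = LabelVector(["a", "a", "b"], class_order=["a", "b", "c"])
        out = per_class_auc(np.random.default_rng(0).uniform(size=(3, 3)), y)
        assert np.isnan(out[2]) and not np.isnan(out[0])

    def test_single_class_fold_rejected(self):
        y = LabelVector(["a", "a"], class_order=["a", "b"])
        with pytest.raises(ValueError, match="no class"):
            per_class_auc(np.full((2, 2), 0.5), y)


class TestMeanAUC:
    @pytest.mark.parametrize(
        "mat, expected",
        [
            (np.ones((3, 2)), 1.0),
            (np.array([[1.0, 0.5]]), 0.75),
            (np.array([[1.0, 1.0], [0.0, 0.0]]), 0.5),
        ],
    )
    def test_fold_then_class_average(self, mat, expected):
        assert mean_auc(mat) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_auc(np.empty((0, 0)))


def _tiny_dataset(n_per_class=(15, 15), seed=0):
    return make_subtype_dataset(list(n_per_class), D=8, n_informative_per_class=2,
                                effect_size=2.0, mode="expression", seed=seed)


class _OracleStub:
    """predict_proba returns the one-hot truth carried via a lookup."""

    def __init__(self, lut, n_classes, noise=0.0):
        self.lut, self.C, self.noise = lut, n_classes, noise

    def __call__(self, params):
        return self

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        out = np.full((X.n_samples, self.C), self.noise)
        for i, s in enumerate(X.sample_ids):
            out[i, self.lut[s]] = 1.0
        return out


class TestInnerCV:
    def test_label_oracle_scores_unit_auc(self):
        ds = _tiny_dataset()
        lut = dict(zip(ds.X.sample_ids, ds.y.to_indices()))
        stub = _OracleStub(lut, ds.y.n_classes)
        space = SearchSpace().add_float("x", 0, 1)
        val = inner_cv_objective(ds.X, ds.y, stub, {"x": 0.5}, M=3, seed=0)
        assert val == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        ds = _tiny_dataset()

        class Flat:
            def __init__(self, params): pass
            def fit(self, X, y): return self
            def predict_proba(self, X):
                return np.full((X.n_samples, 2), 0.5)

        assert inner_cv_objective(ds.X, ds.y, Flat, {}, M=3, seed=0) == pytest.approx(0.5)

    def test_training_invocations_counted_per_fold(self):
        ds = _tiny_dataset()
        counter = [0]

        class Count:
            def __init__(self, params): pass
            def fit(self, X, y): return self
            def predict_proba(self, X):
                rng = np.random.default_rng(0)
                return rng.uniform(size=(X.n_samples, 2))

        inner_cv_objective(ds.X, ds.y, Count, {}, M=3, seed=0, counter=counter)
        assert counter[0] == 3


class TestDoubleCV:
    def test_outer_folds_partition_the_samples(self):
        ds = _tiny_dataset((20, 20))
        lut = dict(zip(ds.X.sample_ids, ds.y.to_indices()))
        stub = _OracleStub(lut, 2)
        space = SearchSpace().add_float("x", 0, 1)
        rep = double_cross_validate(ds.X, ds.y, stub, space, K=4, M=2,
                                    L_trials=2, seed=0, sampler="random")
        flat = sum(rep.outer_test_ids, [])
        assert sorted(flat) == sorted(ds.X.sample_ids)
        assert len(set(flat)) == len(flat)
        assert rep.training_run_count == 4 * 2 * 2

    @pytest.mark.parametrize("sampler", ["random", "tpe"])
    def test_dominant_hyperparameter_is_selected(self, sampler):
        ds = _tiny_dataset((20, 20))

        truth = dict(zip(ds.X.sample_ids, ds.y.to_indices()))

        class Quality:
            """AUC driven directly by the 'good' hyperparameter."""

            def __init__(self, params):
                self.good = params["good"]

            def fit(self, X, y):
                return self

            def predict_proba(self, X):
                if self.good == "yes":
                    return np.array([[1 - truth[s], truth[s]] for s in X.sample_ids])
                return np.random.default_rng(0).uniform(size=(X.n_samples, 2))

        space = SearchSpace().add_categorical("good", ["yes", "no"])
        rep = double_cross_validate(ds.X, ds.y, Quality, space, K=3, M=2,
                                    L_trials=8, seed=0, sampler=sampler)
        assert all(p["good"] == "yes" for p in rep.chosen_hyperparams)

    def test_reproducible_for_fixed_seed(self):
        ds = _tiny_dataset((16, 16))
        lut = dict(zip(ds.X.sample_ids, ds.y.to_indices()))
        stub = _OracleStub(lut, 2)
        space = SearchSpace().add_float("x", 0, 1)
        r1 = double_cross_validate(ds.X, ds.y, stub, space, K=3, M=2, L_trials=3, seed=5)
        r2 = double_cross_validate(ds.X, ds.y, stub, space, K=3, M=2, L_trials=3, seed=5)
        assert r1.outer_test_ids == r2.outer_test_ids
        assert r1.chosen_hyperparams == r2.chosen_hyperparams
        np.testing.assert_array_equal(r1.test_auc, r2.test_auc)

    def test_invalid_budget_rejected(self):
        ds = _tiny_dataset()
        space = SearchSpace().add_float("x", 0, 1)
        with pytest.raises(ValueError):
            double_cross_validate(ds.X, ds.y, lambda p: None, space, K=1, M=2, L_trials=1)
        with pytest.raises(ValueError):
            double_cross_validate(ds.X, ds.y, lambda p: None, SearchSpace(), K=2, M=2, L_trials=1)


class TestTukey:
    def test_equal_distributions_not_rejected(self):
        folds = np.array([0.8, 0.85, 0.9, 0.95, 1.0])
        out = tukey_comparison({"m1": folds, "m2": folds.copy()})
        assert not out["reject"].any()
        assert out.loc[0, "mean_diff"] == pytest.approx(0.0)

    def test_separated_groups_rejected_at_fwer_005(self):
        rng = np.random.default_rng(0)
        a = 0.9 + rng.normal(0, 0.001, 10)
        b = 0.5 + rng.normal(0, 0.001, 10)
        out = tukey_comparison({"good": a, "bad": b})
        assert bool(out.loc[0, "reject"])
        assert out.loc[0, "p_adj"] < 0.05

    def test_invariant_under_model_order(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.uniform(0.4, 0.6, 8),
            "b": rng.uniform(0.5, 0.7, 8),
            "c": rng.uniform(0.6, 0.8, 8),
        }
        out1 = tukey_comparison(groups)
        out2 = tukey_comparison(dict(reversed(groups.items())))
        key = lambda df: {
            tuple(sorted((r.model_a, r.model_b))): round(r.p_adj, 6)
            for r in df.itertuples()
        }
        assert key(out1) == key(out2)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tukey_comparison({"a": np.full(5, 0.9), "b": np.full(5, 0.5)})
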