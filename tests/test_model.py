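import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pwlnet import (
    FeatureMatrix,
    LabelVector,
    PWLModel,
    ReallocationNetSpec,
    TrainConfig,
    fit_pwl,
    pointwise_weights,
    predict_logistic,
    predict_pwl,
    reallocated_features,
    reallocation_forward,
)

from conftest import feature_matrix


class TestPredictLogistic:
    @pytest.mark.parametrize(
        "w, x, expected",
        [
            ([0.0, 0.0], [[3.0, -1.0]], 0.5),          # sigma(0)
            ([1.0, -1.0], [[2.0, 2.0]], 0.5),          # cancellation
            ([np.log(3.0)], [[1.0]], 0.75),            # sigma(ln 3) = 3/4
        ],
    )
    def test_closed_form(self, w, x, expected):
        assert predict_logistic(w, np.array(x)) == pytest.approx(expected, abs=1e-12)

    def test_zero_weights_give_half_for_all_samples(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        np.testing.assert_allclose(predict_logistic(np.zeros(4), X), 0.5)

    def test_intercept_interpretation_and_shape_error(self):
        X = np.zeros((3, 2))
        np.testing.assert_allclose(
            predict_logistic([0.0, 0.0, np.log(3.0)], X), 0.75
        )
        with pytest.raises(ValueError, match="3"):
            predict_logistic(np.ones(5), X)


class TestReallocationNetwork:
    def test_depth_below_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ReallocationNetSpec(depth=1)

    def test_eta_shape_is_augmented(self):
        model = PWLModel(ReallocationNetSpec(seed=1), ["a", "b"], [f"g{i}" for i in range(3)])
        X = np.random.default_rng(0).normal(size=(5, 3))
        assert reallocation_forward(model, X).shape == (5, 4)

    def test_eta_deterministic_across_calls(self):
        model = PWLModel(ReallocationNetSpec(seed=5), ["a", "b"], ["g0", "g1"])
        X = np.random.default_rng(1).normal(size=(7, 2))
        np.testing.assert_array_equal(model.eta(X), model.eta(X))

    def test_unit_initialisation_gives_eta_of_ones(self):
        # freshly constructed reallocated model: eta == 1 exactly
        model = PWLModel(ReallocationNetSpec(seed=2), ["a", "b"], ["g0", "g1"])
        X = np.random.default_rng(2).normal(size=(4, 2))
        np.testing.assert_allclose(model.eta(X), 1.0)


class TestPointwiseAlgebra:
    def test_hadamard_product(self):
        model = PWLModel(ReallocationNetSpec(), ["a", "b"], ["g0", "g1", "g2"],
                         intercept=False)
        model.universal_weights = np.array([[1.0, 2.0, 3.0]])
        xi = pointwise_weights(model, np.array([[4.0, 5.0, 6.0]]))
        np.testing.assert_allclose(xi, [[4.0, 10.0, 18.0]])

    def test_unit_eta_returns_w_and_zero_w_annihilates(self):
        model = PWLModel(ReallocationNetSpec(), ["a", "b"], ["g0", "g1"], intercept=False)
        model.universal_weights = np.array([[2.0, -3.0]])
        np.testing.assert_allclose(pointwise_weights(model, np.ones((3, 2))),
                                   np.tile([2.0, -3.0], (3, 1)))
        model.universal_weights = np.zeros((1, 2))
        np.testing.assert_allclose(pointwise_weights(model, np.ones((3, 2))), 0.0)

    def test_reallocated_features_elementwise(self):
        rho = reallocated_features(np.array([[2.0, 2.0]]), np.array([[3.0, -1.0]]),
                                   intercept=False)
        np.testing.assert_allclose(rho, [[6.0, -2.0]])

    def test_unit_eta_identity(self):
        X = np.random.default_rng(3).normal(size=(4, 3))
        rho = reallocated_features(np.ones((4, 4)), X, intercept=True)
        np.testing.assert_allclose(rho[:, :3], X)
        np.testing.assert_allclose(rho[:, 3], 1.0)

    @given(
        X=arrays(float, (6, 3), elements=st.floats(-5, 5)),
        seed=st.integers(0, 10),
    )
    def test_conservation_xi_dot_x_equals_w_dot_rho(self, X, seed):
        """xi . x == w . rho for every sample and class."""
        model = PWLModel(ReallocationNetSpec(seed=seed), ["a", "b", "c"],
                         [f"g{i}" for i in range(3)])
        rng = np.random.default_rng(seed)
        model.universal_weights = rng.normal(size=model.universal_weights.shape)
        for k in model.net.params:  # make eta nontrivial
            model.net.params[k] = rng.normal(size=model.net.params[k].shape)
        pw = model.pointwise(X)
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])
        lhs = np.einsum("ncp,np->nc", pw.xi, Xa)
        rhs = pw.rho @ model.universal_weights.T
        np.testing.assert_allclose(lhs, rhs, rtol=1e-6, atol=1e-9)


class TestPredictPWL:
    def test_softmax_rows_sum_to_one(self):
        model = PWLModel(ReallocationNetSpec(seed=0), ["a", "b", "c"], ["g0", "g1"])
        X = np.random.default_rng(0).normal(size=(6, 2))
        p = predict_pwl(model, X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_reduction_to_logistic_with_unit_eta(self):
        """With eta frozen at 1 the PWL model is exactly Eq-1 logistic."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        w = rng.normal(size=4)
        model = PWLModel(ReallocationNetSpec(seed=0), ["a", "b"], ["g0", "g1", "g2"])
        model.universal_weights = w[None, :]
        np.testing.assert_allclose(
            predict_pwl(model, X)[:, 1], predict_logistic(w, X), atol=1e-9
        )

    def test_sigmoid_and_softmax_heads_agree_on_ranking(self, gaussian_pair):
        X, y = gaussian_pair
        spec = ReallocationNetSpec(depth=2, width=8, seed=0)
        m_sig = fit_pwl(X, y, spec, TrainConfig(epochs=150, head="sigmoid"))
        m_soft = fit_pwl(X, y, spec, TrainConfig(epochs=150, head="softmax"))
        r_sig = np.argsort(m_sig.predict_proba(X)[:, 1])
        r_soft = np.argsort(m_soft.predict_proba(X)[:, 1])
        # identical sample ordering by positive-class probability
        rank_sig = np.empty(len(r_sig)); rank_sig[r_sig] = np.arange(len(r_sig))
        rank_soft = np.empty(len(r_soft)); rank_soft[r_soft] = np.arange(len(r_soft))
        assert np.corrcoef(rank_sig, rank_soft)[0, 1] > 0.99

    def test_feature_name_mismatch_lists_missing(self, gaussian_pair):
        X, y = gaussian_pair
        m = fit_pwl(X, y, ReallocationNetSpec(depth=2, width=4, seed=0),
                    TrainConfig(epochs=10))
        other = FeatureMatrix(X.values, X.sample_ids, ["h0", "h1"])
        with pytest.raises(ValueError, match="g0000"):
            m.predict_proba(other)


class TestFitPWL:
    def test_separable_gaussians_reach_perfect_training_accuracy(self, gaussian_pair):
        X, y = gaussian_pair
        m = fit_pwl(X, y, ReallocationNetSpec(depth=2, width=8, seed=0),
                    TrainConfig(epochs=200))
        assert (np.array(m.predict(X)) == np.array(y.labels)).mean() == 1.0
        assert m.loss_history[-1] < m.loss_history[0]

    def test_identical_seed_gives_bit_identical_parameters(self, gaussian_pair):
        X, y = gaussian_pair
        spec = ReallocationNetSpec(depth=2, width=4, seed=11)
        cfg = TrainConfig(epochs=30)
        m1, m2 = fit_pwl(X, y, spec, cfg), fit_pwl(X, y, spec, cfg)
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])
        np.testing.assert_array_equal(m1.universal_weights, m2.universal_weights)

    def test_non_finite_input_rejected(self, gaussian_pair):
        X, y = gaussian_pair
        bad = X.values.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_pwl(bad, y)

    def test_too_few_samples_rejected(self):
        y = LabelVector(["a", "b", "a"], class_order=["a", "b"])
        with pytest.raises(ValueError, match="at least"):
            fit_pwl(np.zeros((3, 2)), y)

    def test_state_roundtrip_preserves_predictions(self, gaussian_pair):
        X, y = gaussian_pair
        m = fit_pwl(X, y, ReallocationNetSpec(depth=2, width=4, seed=0),
                    TrainConfig(epochs=30))
        m2 = PWLModel.from_state(m.state())
        np.testing.assert_array_equal(m.predict_proba(X), m2.predict_proba(X))
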