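"""TrAdaBoost mechanics: initialization, rates, updates, voting."""

import numpy as np
import pytest

from mitransfer.kmm import KernelConfig, SourceWeightVector
from mitransfer.tradaboost import (
    BoostConfig,
    StrongClassifier,
    beta_source,
    fit,
    init_weights,
    predict,
    update_weights,
    weighted_error,
)


def sw(weights):
    return SourceWeightVector(
        weights=np.asarray(weights, dtype=float), objective=0.0, sigma=1.0,
        config=KernelConfig(),
    )


class FixedHypothesis:
    """Stub weak learner with a constant internal {0,1} prediction map."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict(self, x):
        return np.array([self.mapping(row) for row in np.atleast_2d(x)])


class TestInitWeights:
    def test_uniform_substitution(self):
        np.testing.assert_allclose(
            init_weights(4, 2, "uniform"),
            [0.25, 0.25, 0.25, 0.25, 0.5, 0.5],
        )

    def test_equal_kmm_weights_reproduce_uniform_exactly(self):
        uniform = init_weights(4, 2, "uniform")
        kmm = init_weights(4, 2, "kmm", sw([3.0, 3.0, 3.0, 3.0]))
        np.testing.assert_array_equal(uniform, kmm)

    def test_kmm_normalization(self):
        w = init_weights(4, 2, "kmm", sw([2.0, 1.0, 1.0, 0.0]))
        np.testing.assert_allclose(w[:4], [0.5, 0.25, 0.25, 0.0])
        np.testing.assert_allclose(w[4:], [0.5, 0.5])

    def test_kmm_mode_requires_weights(self):
        with pytest.raises(ValueError, match="requires kmm_weights"):
            init_weights(4, 2, "kmm")


class TestBetaSource:
    def test_single_source_sample_boundary(self):
        assert beta_source(1, 10) == 1.0

    def test_high_precision_value(self):
        expected = 1.0 / (1.0 + np.sqrt(2.0 * np.log(100.0) / 10.0))
        assert abs(beta_source(100, 10) - expected) < 1e-15
        assert abs(beta_source(100, 10) - 0.510281) < 1e-5

    def test_monotonicity(self):
        assert beta_source(1000, 10) < beta_source(100, 10)
        assert beta_source(100, 20) > beta_source(100, 10)


class TestWeightedError:
    def test_perfect_hypothesis(self):
        assert weighted_error([0, 1, 0], [0, 1, 0], np.ones(3)) == 0.0

    def test_uniform_one_of_four_wrong(self):
        assert weighted_error([1, 0, 0, 0], [0, 0, 0, 0], np.ones(4)) == 0.25

    def test_weighted_single_miss(self):
        err = weighted_error(
            [1, 0, 0, 0], [0, 0, 0, 0], np.array([0.7, 0.1, 0.1, 0.1])
        )
        assert err == pytest.approx(0.7)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_error([0], [1], np.zeros(1))


class TestUpdateWeights:
    def test_misclassified_source_halves_at_beta_half(self):
        w = update_weights(np.ones(3), np.array([1.0, 0.0, 0.0]), n=2,
                           beta=0.5, beta_t=0.3)
        np.testing.assert_allclose(w, [0.5, 1.0, 1.0])

    def test_misclassified_target_quadruples_at_beta_t_quarter(self):
        w = update_weights(np.ones(3), np.array([0.0, 0.0, 1.0]), n=2,
                           beta=0.5, beta_t=0.25)
        np.testing.assert_allclose(w, [1.0, 1.0, 4.0])

    def test_all_correct_identity(self, rng):
        w0 = rng.uniform(0.1, 1.0, size=6)
        w1 = update_weights(w0, np.zeros(6), n=3, beta=0.4, beta_t=0.2)
        np.testing.assert_array_equal(w0, w1)

    def test_persistent_miss_is_monotone(self, rng):
        # a source sample misclassified every round has non-increasing weight;
        # a target sample misclassified every round has non-decreasing weight
        w = np.ones(4)
        misses = np.array([1.0, 0.0, 0.0, 1.0])
        for _ in range(10):
            w_next = update_weights(w, misses, n=2, beta=0.6,
                                    beta_t=rng.uniform(0.05, 0.45))
            assert w_next[0] <= w[0]
            assert w_next[3] >= w[3]
            w = w_next


class TestFit:
    @staticmethod
    def transfer_problem(rng, n=80, m=20, shift=1.0):
        xs = np.vstack([
            rng.normal([0.0 + shift, 0.0], 0.8, size=(n // 2, 2)),
            rng.normal([2.0 + shift, 2.0], 0.8, size=(n // 2, 2)),
        ])
        ys = np.repeat([1, 2], n // 2)
        xt = np.vstack([
            rng.normal([0.0, 0.0], 0.8, size=(m // 2, 2)),
            rng.normal([2.0, 2.0], 0.8, size=(m // 2, 2)),
        ])
        yt = np.repeat([1, 2], m // 2)
        return xs, ys, xt, yt

    def test_single_iteration_reduces_to_weak_hypothesis(self, rng):
        xs, ys, xt, yt = self.transfer_problem(rng)
        model = fit(xs, ys, xt, yt, BoostConfig(n_iterations=1, seed=0))
        assert model.n_completed == 1
        internal = model.hypotheses[0].predict(xt)
        np.testing.assert_array_equal(model.predict(xt), model.classes[internal])

    def test_recorded_errors_below_half_and_betas_in_unit_interval(self, rng):
        xs, ys, xt, yt = self.transfer_problem(rng)
        model = fit(xs, ys, xt, yt, BoostConfig(n_iterations=8, seed=1))
        assert all(0.0 <= e < 0.5 for e in model.errors)
        assert all(0.0 < b < 1.0 for b in model.betas)

    def test_deterministic_under_seed(self, rng):
        xs, ys, xt, yt = self.transfer_problem(rng)
        cfg = BoostConfig(n_iterations=5, seed=3)
        a = fit(xs, ys, xt, yt, cfg).predict(xs)
        b = fit(xs, ys, xt, yt, cfg).predict(xs)
        np.testing.assert_array_equal(a, b)

    def test_zero_source_matches_handrolled_adaboost_reference(self, rng):
        from sklearn.svm import SVC

        xt = rng.normal(size=(24, 2))
        yt = (xt[:, 0] + 0.3 * rng.normal(size=24) > 0).astype(int) + 1
        if len(set(yt)) < 2:  # pragma: no cover - rng guard
            yt[0] = 1; yt[1] = 2
        big_n = 3
        model = fit(np.empty((0, 2)), np.empty(0, dtype=int), xt, yt,
                    BoostConfig(n_iterations=big_n, seed=5))

        # reference: the same loop written out by hand on the target only,
        # with the same weak-learner family
        y01 = (yt == 2).astype(int)
        w = np.full(len(yt), 1.0 / len(yt))
        ref_betas = []
        for t in range(big_n):
            learner = SVC(kernel="linear", C=1.0, random_state=5 + t)
            learner.fit(xt, y01, sample_weight=w / w.sum())
            pred = learner.predict(xt)
            eps = float((w * (pred != y01)).sum() / w.sum())
            if eps >= 0.5:
                break
            beta_t = max(eps / (1.0 - eps), 1e-10)
            w = w * beta_t ** (-(pred != y01).astype(float))
            ref_betas.append(beta_t)
        np.testing.assert_allclose(model.betas, ref_betas, atol=1e-12)

    def test_hopeless_weak_learner_degrades_to_capped_single_hypothesis(self):
        # constant-prediction learner has target error exactly 0.5: boosting
        # cannot start, but a usable single-hypothesis model is still
        # returned (with its error capped below 1/2) plus a warning
        class Constant:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, x, y, sample_weight=None):
                return self

            def predict(self, x):
                return np.zeros(len(x), dtype=int)

        xt = np.zeros((10, 1))
        yt = np.repeat([1, 2], 5)
        cfg = BoostConfig(n_iterations=3, weak_learner=Constant(), seed=0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("error")
            with pytest.raises(Warning):
                fit(np.zeros((4, 1)), np.array([1, 2, 1, 2]), xt, yt, cfg)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = fit(np.zeros((4, 1)), np.array([1, 2, 1, 2]), xt, yt, cfg)
        assert model.under_trained and model.n_completed == 1
        assert model.errors[0] == pytest.approx(0.5, abs=1e-5)
        # constant internal-0 prediction maps to the first class label
        np.testing.assert_array_equal(model.predict(xt[:2]), [1, 1])

    def test_weak_learner_without_sample_weight_rejected(self):
        class NoWeights:
            def get_params(self, deep=True):
                return {}

            def fit(self, x, y):
                return self

            def predict(self, x):
                return np.zeros(len(x), dtype=int)

        with pytest.raises(ValueError, match="sample_weight"):
            BoostConfig(weak_learner=NoWeights())

    def test_mismatched_init_length_rejected(self, rng):
        xs, ys, xt, yt = self.transfer_problem(rng)
        with pytest.raises(ValueError, match="init length"):
            fit(xs, ys, xt, yt, BoostConfig(), init=np.ones(3))


class TestPredict:
    @staticmethod
    def model(hypotheses, betas):
        return StrongClassifier(
            hypotheses=hypotheses, betas=betas, n_planned=len(hypotheses),
            classes=np.array([1, 2]), errors=[0.1] * len(hypotheses),
        )

    def test_equal_betas_give_majority_vote(self):
        # 3 hypotheses, vote window = [2, 3]; both voters predict 1 -> class 2
        hyps = [
            FixedHypothesis(lambda r: 0),
            FixedHypothesis(lambda r: 1),
            FixedHypothesis(lambda r: 1),
        ]
        model = self.model(hyps, [0.3, 0.3, 0.3])
        np.testing.assert_array_equal(model.predict(np.zeros((2, 1))), [2, 2])

    def test_hand_computed_weighted_vote(self):
        # 5 completed iterations -> voting window [ceil(5/2), 5] = last three.
        # Voters carry beta (0.1, 0.4, 0.45) -> weights ln(10), ln(2.5),
        # ln(2.222...); votes (1, 0, 0): ln(10) >= half the weight total,
        # so the positive class wins
        hyps = [
            FixedHypothesis(lambda r: 0),   # outside the window
            FixedHypothesis(lambda r: 0),   # outside the window
            FixedHypothesis(lambda r: 1),
            FixedHypothesis(lambda r: 0),
            FixedHypothesis(lambda r: 0),
        ]
        model = StrongClassifier(
            hypotheses=hyps, betas=[0.2, 0.2, 0.1, 0.4, 0.45], n_planned=5,
            classes=np.array([1, 2]), errors=[0.1] * 5,
        )
        votes, threshold = model.decision_scores(np.zeros((1, 1)))
        assert votes[0] == pytest.approx(np.log(10.0))
        assert threshold == pytest.approx(
            0.5 * (np.log(10.0) + np.log(1 / 0.4) + np.log(1 / 0.45))
        )
        assert votes[0] >= threshold
        np.testing.assert_array_equal(model.predict(np.zeros((1, 1))), [2])

    def test_full_window_hand_vote_via_single_pair(self):
        # 2 hypotheses: window = [1, 2] covers both
        hyps = [FixedHypothesis(lambda r: 1), FixedHypothesis(lambda r: 0)]
        model = self.model(hyps, [0.1, 0.4])
        # ln(10) * 1 >= (ln 10 + ln 2.5) / 2  -> positive class
        np.testing.assert_array_equal(model.predict(np.zeros((1, 1))), [2])

    def test_tie_resolves_to_positive(self):
        hyps = [FixedHypothesis(lambda r: 1), FixedHypothesis(lambda r: 0)]
        model = self.model(hyps, [0.25, 0.25])  # equal weights, vote sum == half
        np.testing.assert_array_equal(model.predict(np.zeros((1, 1))), [2])

    def test_empty_model_rejected(self):
        model = self.model([], [])
        with pytest.raises(ValueError, match="no completed"):
            predict(model, np.zeros((1, 1)))
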