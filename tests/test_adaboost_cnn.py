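import numpy as np
import pytest

from ldaboost import (
    BoostedCNNModel,
    CNNConfig,
    LabeledDataset,
    aggregate_probas,
    boosted_cnn_scores,
    fit_single_cnn,
    init_sample_weights,
    train_boosted_cnn,
)
from ldaboost.adaboost_cnn import _samme_r_update

CFG = CNNConfig(batch_size=8)


class StubEstimator:
    """Fixed-output estimator for checking the aggregation rule."""

    def __init__(self, probs):
        self.probs = np.atleast_2d(probs)

    def predict_proba(self, X):
        return np.repeat(self.probs, len(X), axis=0)


class TestSampleWeights:
    def test_uniform_initialization(self):
        assert np.array_equal(init_sample_weights(4), [0.25] * 4)

    @pytest.mark.parametrize("p", [1, 7, 100])
    def test_sum_to_one(self, p):
        assert init_sample_weights(p).sum() == pytest.approx(1.0)

    def test_degenerate_p_rejected(self):
        with pytest.raises(ValueError):
            init_sample_weights(0)

    def test_samme_r_raises_misclassified_weight(self):
        # estimator confident and right on sample 0, wrong on sample 1
        D = init_sample_weights(2)
        probs = np.array([[0.9, 0.1], [0.8, 0.2]])
        y = np.array([0, 1])
        D2 = _samme_r_update(D, probs, y, learning_rate=1.0)
        assert D2.sum() == pytest.approx(1.0, abs=1e-12)
        assert D2[1] > D[1] > D2[0]


class TestAggregation:
    def test_uniform_probability_contributes_zero(self):
        agg = aggregate_probas([np.array([[0.5, 0.5]])])
        assert np.allclose(agg, 0.0, atol=1e-12)

    def test_two_estimator_log_odds_sum(self):
        # hand evaluation: 1/2 ln(0.8/0.2) + 1/2 ln(0.6/0.4) ~ 0.8959
        model = BoostedCNNModel(
            estimators=[StubEstimator([0.2, 0.8]), StubEstimator([0.4, 0.6])],
            learning_rate=0.1,
            sample_weights=init_sample_weights(1),
        )
        X = np.zeros((1, 4))
        agg = aggregate_probas([e.predict_proba(X) for e in model.estimators])
        expected = 0.5 * np.log(0.8 / 0.2) + 0.5 * np.log(0.6 / 0.4)
        assert agg[0, 1] == pytest.approx(expected, abs=1e-9)
        scores, hard = boosted_cnn_scores(model, X)
        assert hard[0] == 1
        assert scores[0] > 0.5

    def test_exact_tie_prefers_non_association(self):
        model = BoostedCNNModel(
            estimators=[StubEstimator([0.5, 0.5])],
            learning_rate=0.1,
            sample_weights=init_sample_weights(1),
        )
        _, hard = boosted_cnn_scores(model, np.zeros((3, 4)))
        assert np.array_equal(hard, [0, 0, 0])

    def test_probability_floor_handles_zero(self):
        agg = aggregate_probas([np.array([[0.0, 1.0]])])
        assert np.isfinite(agg).all()

    def test_empty_estimator_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_probas([])


class TestTraining:
    def test_separates_toy_set(self, toy_separable):
        # oracle: a single directly-fit CNN separates the same data
        single = fit_single_cnn(toy_separable, epochs=60, seed=1, config=CFG)
        p = single.predict_proba(toy_separable.X)
        assert ((p[:, 1] > p[:, 0]).astype(int) == toy_separable.y).all()

        model = train_boosted_cnn(
            toy_separable, Q=3, epochs=60, learning_rate=0.1, seed=1, config=CFG
        )
        _, hard = boosted_cnn_scores(model, toy_separable.X)
        assert np.array_equal(hard, toy_separable.y)

    def test_weights_sum_to_one_every_round(self, toy_separable):
        model = train_boosted_cnn(
            toy_separable, Q=5, epochs=5, learning_rate=0.1, seed=2, config=CFG
        )
        assert np.allclose(model.weight_history, 1.0, atol=1e-9)
        assert model.sample_weights.min() >= 0

    def test_q1_equals_standalone_cnn(self, toy_separable):
        model = train_boosted_cnn(
            toy_separable, Q=1, epochs=20, learning_rate=0.7, seed=5, config=CFG
        )
        single = fit_single_cnn(toy_separable, epochs=20, seed=5, config=CFG)
        scores, hard = boosted_cnn_scores(model, toy_separable.X)
        p = single.predict_proba(toy_separable.X)
        assert np.array_equal(hard, (p[:, 1] > p[:, 0]).astype(int))
        # one round: softmax of the log-odds contributions recovers the
        # CNN's class-1 probability exactly
        assert np.allclose(scores, p[:, 1], atol=1e-9)

    def test_bit_identical_determinism(self, toy_separable):
        kw = dict(Q=3, epochs=5, learning_rate=0.1, seed=9, config=CFG)
        s1, _ = boosted_cnn_scores(
            train_boosted_cnn(toy_separable, **kw), toy_separable.X
        )
        s2, _ = boosted_cnn_scores(
            train_boosted_cnn(toy_separable, **kw), toy_separable.X
        )
        assert np.array_equal(s1, s2)

    def test_single_class_labels_rejected(self, toy_separable):
        bad = LabeledDataset.from_arrays(toy_separable.X, np.ones(8, int))
        with pytest.raises(ValueError, match="both classes"):
            train_boosted_cnn(bad, Q=1, epochs=1, seed=0, config=CFG)

    def test_non_finite_features_rejected(self, toy_separable):
        X = toy_separable.X.copy()
        X[0, 0] = np.nan
        bad = LabeledDataset.from_arrays(X, toy_separable.y)
        with pytest.raises(ValueError, match="finite"):
            train_boosted_cnn(bad, Q=1, epochs=1, seed=0, config=CFG)

    def test_feature_width_mismatch_rejected(self, toy_separable):
        model = train_boosted_cnn(
            toy_separable, Q=1, epochs=1, seed=0, config=CFG
        )
        with pytest.raises(ValueError, match="width"):
            boosted_cnn_scores(model, np.zeros((2, 7)))

    def test_save_load_round_trip(self, toy_separable, tmp_path):
        model = train_boosted_cnn(
            toy_separable, Q=2, epochs=3, seed=4, config=CFG
        )
        model.save(tmp_path / "model")
        loaded = BoostedCNNModel.load(tmp_path / "model")
        s1, h1 = boosted_cnn_scores(model, toy_separable.X)
        s2, h2 = boosted_cnn_scores(loaded, toy_separable.X)
        assert np.array_equal(s1, s2) and np.array_equal(h1, h2)
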