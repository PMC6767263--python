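"""Cost-sensitive classifiers: priors, thresholds, votes, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from fog_forecast.ensemble import (
    BaseLearnerSpec,
    CostSpec,
    TrainedModel,
    adjust_priors,
    train_classifier,
    train_clsf_bagging,
    train_clsf_boost,
    train_individual,
    train_tree_ensembles,
)
from fog_forecast.sample_builder import SampleSet


def separable_set(n=60, dim=5, seed=0, gap=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, dim)), rng.normal(gap, 1, (n, dim))])
    y = np.concatenate([np.zeros(n), np.ones(n)]).astype(np.int8)
    return SampleSet(X=X, y=y, t=np.arange(2 * n, dtype=float))


def noisy_set(n=150, dim=4, seed=1, gap=1.2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, dim)), rng.normal(gap, 1, (n // 3, dim))])
    y = np.concatenate([np.zeros(n), np.ones(n // 3)]).astype(np.int8)
    return SampleSet(X=X, y=y, t=np.arange(len(y), dtype=float))


class TestAdjustPriors:
    def test_unit_costs_leave_priors_unchanged(self):
        np.testing.assert_allclose(
            adjust_priors(np.array([0.9, 0.1]), CostSpec()), [0.9, 0.1]
        )

    def test_direct_renormalization(self):
        out = adjust_priors(np.array([0.8, 0.2]), CostSpec(c_fog=3))
        np.testing.assert_allclose(out, [0.8 / 1.4, 0.6 / 1.4])

    def test_cost_threshold_is_cng_over_sum(self):
        assert CostSpec(c_fog=2).threshold == pytest.approx(1 / 3)
        assert CostSpec().threshold == pytest.approx(0.5)

    def test_degenerate_priors_rejected(self):
        with pytest.raises(ValueError):
            adjust_priors(np.array([1.0, 0.0]), CostSpec())


class TestIndividual:
    @pytest.mark.parametrize("kind", ["svm", "knn", "mlp"])
    def test_separable_data_is_fit_perfectly(self, kind):
        s = separable_set()
        model = train_individual(s, BaseLearnerSpec(kind=kind), seed=0)
        pred = model.predict(s.X)
        np.testing.assert_array_equal(pred, s.y)

    def test_higher_fog_cost_never_lowers_sensitivity(self):
        """Cost enters as a posterior threshold, so on a fixed fitted model
        the set of FoG predictions grows with the FoG cost."""
        s = noisy_set()
        model = train_individual(s, BaseLearnerSpec(kind="svm"), CostSpec(c_fog=1), seed=0)
        preds = {
            c: replace(model, cost=CostSpec(c_fog=c)).predict(s.X) for c in (1, 2, 3)
        }
        assert np.all(preds[1] <= preds[2])
        assert np.all(preds[2] <= preds[3])

    def test_same_seed_same_predictions(self):
        s = noisy_set(seed=4)
        a = train_individual(s, BaseLearnerSpec(kind="mlp"), seed=3)
        b = train_individual(s, BaseLearnerSpec(kind="mlp"), seed=3)
        np.testing.assert_array_equal(a.predict(s.X), b.predict(s.X))

    def test_constant_columns_dropped_with_warning(self):
        s = separable_set()
        s.X[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            model = train_individual(s, BaseLearnerSpec(kind="knn"), seed=0)
        assert model.predict(s.X).shape == s.y.shape

    def test_single_class_train_rejected(self):
        s = separable_set()
        with pytest.raises(ValueError):
            train_individual(s.take(s.y == 0), BaseLearnerSpec(kind="svm"))


class TestClsfBagging:
    def test_majority_vote_counts(self):
        s = separable_set(n=40)
        model = train_clsf_bagging(s, seed=0)
        assert len(model.members) == 3
        np.testing.assert_array_equal(model.predict(s.X), s.y)

    def test_two_member_tie_breaks_toward_fog_under_cost(self):
        class Always:
            def __init__(self, p):
                self.classes_ = np.array([0, 1])
                self.p = p

            def predict_proba(self, X):
                return np.tile([1 - self.p, self.p], (len(X), 1))

        members = [("a", Always(1.0), 1.0), ("b", Always(0.0), 1.0)]
        X = np.zeros((4, 2))
        tie_fog = TrainedModel("bag", CostSpec(c_fog=2), members, vote="majority")
        np.testing.assert_array_equal(tie_fog.predict(X), 1)
        tie_ng = TrainedModel("bag", CostSpec(c_fog=1), members, vote="majority")
        np.testing.assert_array_equal(tie_ng.predict(X), 0)

    def test_unanimous_members_dominate(self):
        class Always:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.tile([0.0, 1.0], (len(X), 1))

        members = [("m", Always(), 1.0)] * 3
        model = TrainedModel("bag", CostSpec(), members, vote="majority")
        np.testing.assert_array_equal(model.predict(np.zeros((3, 2))), 1)

    def test_seed_determinism(self):
        s = noisy_set(seed=5)
        a = train_clsf_bagging(s, seed=7).predict(s.X)
        b = train_clsf_bagging(s, seed=7).predict(s.X)
        np.testing.assert_array_equal(a, b)

    def test_too_few_bags_rejected(self):
        with pytest.raises(ValueError):
            train_clsf_bagging(separable_set(), n_bags=2)


class TestClsfBoost:
    def test_single_round_equals_individual_member(self):
        s = noisy_set(seed=6)
        boost = train_clsf_boost(s, rounds=1, seed=0)
        single = train_individual(s, BaseLearnerSpec(kind="svm"), seed=boost_member_seed(0))
        np.testing.assert_array_equal(boost.predict(s.X), single.predict(s.X))

    def test_training_error_vanishes_on_separable_data(self):
        s = separable_set(n=50, seed=7)
        model = train_clsf_boost(s, rounds=6, seed=1)
        assert np.mean(model.predict(s.X) != s.y) == 0.0

    def test_determinism(self):
        s = noisy_set(seed=8)
        a = train_clsf_boost(s, rounds=3, seed=2).predict(s.X)
        b = train_clsf_boost(s, rounds=3, seed=2).predict(s.X)
        np.testing.assert_array_equal(a, b)


def boost_member_seed(seed):
    """First member seed drawn by train_clsf_boost's generator."""
    return int(np.random.default_rng(seed).integers(2**31))


class TestTreeEnsembles:
    @pytest.mark.parametrize("variant", ["adaboost", "treebagger", "randomforest"])
    def test_separable_data_fit_perfectly(self, variant):
        s = separable_set(n=40, seed=9)
        model = train_tree_ensembles(s, variant, seed=0, n_estimators=30)
        np.testing.assert_array_equal(model.predict(s.X), s.y)

    def test_variants_differ_only_in_feature_subsampling(self):
        s = noisy_set(seed=10)
        tb = train_tree_ensembles(s, "treebagger", seed=0, n_estimators=10)
        rf = train_tree_ensembles(s, "randomforest", seed=0, n_estimators=10)
        assert tb.members[0][1].named_steps["clf"].max_features is None
        assert rf.members[0][1].named_steps["clf"].max_features == "sqrt"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            train_tree_ensembles(separable_set(), "gradientboost")


def test_train_classifier_dispatch_and_unknown_name():
    s = separable_set(n=30, seed=11)
    model = train_classifier("knn", s, seed=0)
    assert model.kind == "knn"
    with pytest.raises(ValueError):
        train_classifier("resnet", s)
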