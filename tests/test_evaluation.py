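"""Metrics arithmetic, split protocols, LOOCV structure, latency."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fog_forecast as ff
from fog_forecast.adasyn import AdasynConfig
from fog_forecast.evaluation import (
    ConfusionCounts,
    confusion_from_predictions,
    evaluate_model,
    latency_profile,
    loocv_patient_independent,
    metrics,
    split_patient_dependent,
)
from fog_forecast.gait_synth import LabelTrack, State
from fog_forecast.sample_builder import SampleSet


class TestMetrics:
    def test_perfect_classifier_scores_100(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
        assert (m.sensitivity, m.specificity, m.f1) == (100.0, 100.0, 100.0)

    def test_direct_arithmetic(self):
        m = metrics(ConfusionCounts(tp=3, fn=1, tn=5, fp=1))
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(83.33, abs=0.01)
        assert m.f1 == pytest.approx(75.0)

    def test_zero_positives_found(self):
        m = metrics(ConfusionCounts(tp=0, fn=4, tn=5, fp=0))
        assert m.sensitivity == 0.0 and m.f1 == 0.0

    def test_undefined_metrics_are_none_not_numbers(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert m.sensitivity is None
        m = metrics(ConfusionCounts(tp=3, fn=1, tn=0, fp=0))
        assert m.specificity is None

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_f1_is_harmonic_mean_of_precision_and_sensitivity(self, tp, fp, tn, fn):
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if tp + fn and tp + fp and tp:
            prec = tp / (tp + fp)
            sens = tp / (tp + fn)
            assert m.f1 == pytest.approx(100 * 2 * prec * sens / (prec + sens))

    def test_confusion_recount_from_raw_pairs(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        c = confusion_from_predictions(y_true, y_pred)
        assert c.tp == sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 1)
        assert c.fn == sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 0)
        assert c.total == 200


def _subject_set(n, subj, t0=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return SampleSet(
        X=rng.normal(size=(n, 4)),
        y=(rng.random(n) < 0.3).astype(np.int8),
        t=t0 + np.arange(n, dtype=float),
        subject=np.full(n, subj),
    )


class TestPatientDependentSplit:
    def test_first_60_percent_train_rest_test(self):
        s = _subject_set(100, "a")
        train, test = split_patient_dependent(s)
        assert len(train) == 60 and len(test) == 40
        assert train.t.max() < test.t.min()

    def test_split_is_per_subject_and_chronological(self):
        s = SampleSet.concatenate([_subject_set(50, "a"), _subject_set(30, "b", t0=0.0)])
        train, test = split_patient_dependent(s)
        for subj, n in (("a", 50), ("b", 30)):
            tr = train.t[train.subject == subj]
            te = test.t[test.subject == subj]
            assert len(tr) == int(n * 0.6)
            assert tr.max() < te.min()

    def test_small_subject_skipped_with_warning(self):
        s = SampleSet.concatenate([_subject_set(50, "a"), _subject_set(5, "b")])
        with pytest.warns(UserWarning, match="skipped"):
            train, _ = split_patient_dependent(s)
        assert set(np.unique(train.subject)) == {"a"}

    def test_synthetic_input_rejected(self):
        s = _subject_set(20, "a")
        s.synthetic[3] = True
        with pytest.raises(ValueError):
            split_patient_dependent(s)


class TestLoocv:
    @staticmethod
    def _three_subjects():
        out = {}
        rng = np.random.default_rng(1)
        for subj in "abc":
            n = 60
            y = np.concatenate([np.zeros(45), np.ones(15)]).astype(np.int8)
            X = rng.normal(size=(n, 4)) + 3.0 * y[:, None]
            out[subj] = SampleSet(
                X=X, y=y, t=np.arange(n, dtype=float), subject=np.full(n, subj)
            )
        return out

    def test_each_subject_tested_exactly_once(self):
        reports, avg = loocv_patient_independent(
            self._three_subjects(), classifier="knn", seed=0
        )
        assert set(reports) == {"a", "b", "c"}
        for r in reports.values():
            assert r.confusion.total == 60
        assert avg.sensitivity is not None

    def test_identical_config_reproduces_reports(self):
        subs = self._three_subjects()
        cfg = dict(classifier="knn", adasyn_cfg=AdasynConfig(beta=0.5, seed=1), seed=0)
        r1, a1 = loocv_patient_independent(subs, **cfg)
        r2, a2 = loocv_patient_independent(subs, **cfg)
        assert a1 == a2
        for s in subs:
            assert r1[s].confusion == r2[s].confusion

    def test_fold_without_fog_noted_and_excluded_from_average(self):
        subs = self._three_subjects()
        subs["c"] = subs["c"].take(np.flatnonzero(subs["c"].y == 0))
        reports, avg = loocv_patient_independent(subs, classifier="knn", seed=0)
        assert reports["c"].metrics.sensitivity is None
        assert any("undefined" in note for note in reports["c"].notes)
        present = [
            r.metrics.sensitivity for r in reports.values()
            if r.metrics.sensitivity is not None
        ]
        assert avg.sensitivity == pytest.approx(float(np.mean(present)))

    def test_two_subjects_minimum(self):
        subs = self._three_subjects()
        with pytest.raises(ValueError):
            loocv_patient_independent({"a": subs["a"]}, classifier="knn")


class TestLatency:
    @staticmethod
    def _truth(rate=64.0, spans=((10.0, 16.0),), total=40.0):
        states = np.zeros(int(total * rate), dtype=np.int8)
        for a, b in spans:
            states[int(a * rate): int(b * rate)] = State.FOG
        return LabelTrack(states)

    def test_hit_at_onset_is_zero_latency_detection(self):
        truth = self._truth()
        times = np.arange(2.0, 40.0, 0.5)
        pred = times == 10.0
        prof = latency_profile(times, pred, truth, 64.0)
        assert prof.latencies == [0.0]
        assert prof.detected_fraction == 1.0 and prof.predicted_fraction == 0.0

    def test_hit_half_second_early_is_prediction(self):
        truth = self._truth()
        times = np.arange(2.0, 40.0, 0.5)
        prof = latency_profile(times, times == 9.5, truth, 64.0)
        assert prof.latencies == [-0.5]
        assert prof.predicted_fraction == 1.0

    def test_three_episode_hand_enumerated_fractions(self):
        """One episode hit 1 s early, one 1.5 s late, one missed:
        predicted 1/3, detected 1/3, identified 2/3."""
        truth = self._truth(spans=((10.0, 14.0), (20.0, 24.0), (30.0, 34.0)))
        times = np.arange(2.0, 40.0, 0.5)
        pred = (times == 9.0) | (times == 21.5)
        prof = latency_profile(times, pred, truth, 64.0)
        assert prof.latencies == [-1.0, 1.5, None]
        assert prof.predicted_fraction == pytest.approx(1 / 3)
        assert prof.detected_fraction == pytest.approx(1 / 3)
        assert prof.identified_fraction == pytest.approx(2 / 3)

    def test_out_of_window_predictions_do_not_count(self):
        truth = self._truth(spans=((20.0, 22.0),))
        times = np.arange(2.0, 40.0, 0.5)
        pred = (times == 10.0) | (times == 32.0)  # far before and after
        prof = latency_profile(times, pred, truth, 64.0)
        assert prof.latencies == [None]

    def test_latencies_are_quantized_to_half_seconds(self):
        # onset off the 0.5 s grid: raw difference rounds to the stride
        rate = 64.0
        states = np.zeros(int(40 * rate), dtype=np.int8)
        states[645: int(16 * rate)] = State.FOG  # onset at 10.078125 s
        truth = LabelTrack(states)
        times = np.arange(2.0, 40.0, 0.5)
        prof = latency_profile(times, times == 10.5, truth, rate)
        assert prof.latencies == [0.5]

    def test_shared_predictions_assigned_to_nearest_onset(self):
        truth = self._truth(spans=((10.0, 11.0), (13.0, 14.0)))
        times = np.arange(2.0, 40.0, 0.5)
        pred = times == 12.0  # inside both search windows, nearer ep 2? no: 10->+2, 13->-1
        prof = latency_profile(times, pred, truth, 64.0)
        assert prof.latencies == [None, -1.0]

    def test_histogram_bins_cover_search_window(self):
        prof = latency_profile(
            np.arange(2.0, 40.0, 0.5),
            np.arange(2.0, 40.0, 0.5) == 9.5,
            self._truth(),
            64.0,
        )
        edges, counts = prof.histogram()
        assert edges[0] == -2.0 and edges[-1] == 4.0
        assert counts.sum() == 1
        assert counts[np.flatnonzero(edges == -0.5)[0]] == 1


def test_evaluate_model_rejects_synthetic_test_samples():
    class Stub:
        def predict(self, X):
            return np.zeros(len(X), dtype=np.int8)

    s = _subject_set(10, "a")
    s.synthetic[0] = True
    with pytest.raises(ValueError):
        evaluate_model(Stub(), s)
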