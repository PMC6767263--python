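"""Evaluation: confusion metrics, split protocols, onset latency.

FoG is the positive class.  Sensitivity = TP/(TP+FN) measures how much
actual freezing is recognised, specificity = TN/(TN+FP) how much normal
gait is left alone, and F1 = 2TP/(2TP+FP+FN) balances the two; all are
reported in percent, and a metric whose denominator is zero is reported
as undefined (``None``) rather than a number.

Two protocols mirror clinical practice:

* patient-dependent — chronological 60/40 split within each subject
  (the chronological ordering prevents temporal leakage through window
  overlap);
* patient-independent — leave-one-subject-out cross-validation, with
  oversampling applied to the pooled training folds only.

Latency analysis works at the episode level: for each true freeze
onset, the latency is the time of the first FoG-classified sample in a
search window from 2 s before the onset to 4 s after (negative latency
= the episode was *predicted*; positive = *detected* after onset).
Because samples advance on the 0.5 s window stride, latencies are
quantised to 0.5 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .adasyn import AdasynConfig, adasyn_oversample
from .ensemble import CostSpec, TrainedModel, train_classifier
from .gait_synth import LabelTrack, State
from .sample_builder import SampleSet

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "LatencyProfile",
    "EvaluationReport",
    "confusion_from_predictions",
    "metrics",
    "split_patient_dependent",
    "loocv_patient_independent",
    "latency_profile",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with FoG as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Percent metrics; ``None`` marks an undefined (0/0) quantity."""

    sensitivity: float | None
    specificity: float | None
    f1: float | None


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        tp=int(np.count_nonzero((y_true == 1) & (y_pred == 1))),
        fp=int(np.count_nonzero((y_true == 0) & (y_pred == 1))),
        tn=int(np.count_nonzero((y_true == 0) & (y_pred == 0))),
        fn=int(np.count_nonzero((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and F1 in percent."""
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    f1 = 100.0 * 2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) else None
    return Metrics(sensitivity=sens, specificity=spec, f1=f1)


@dataclass
class LatencyProfile:
    """Per-episode detection latencies relative to true FoG onsets.

    ``latencies`` holds one entry per true episode: a latency in seconds
    (multiple of the sample stride) or ``None`` for a missed episode.
    Fractions are over all true episodes.
    """

    latencies: list[float | None]
    window: tuple[float, float] = (-2.0, 4.0)

    @property
    def n_episodes(self) -> int:
        return len(self.latencies)

    @property
    def found(self) -> list[float]:
        return [l for l in self.latencies if l is not None]

    @property
    def predicted_fraction(self) -> float:
        return sum(1 for l in self.found if l < 0) / max(self.n_episodes, 1)

    @property
    def detected_fraction(self) -> float:
        return sum(1 for l in self.found if 0 <= l <= self.window[1]) / max(self.n_episodes, 1)

    @property
    def identified_fraction(self) -> float:
        lo, hi = self.window
        return sum(1 for l in self.found if lo <= l <= hi) / max(self.n_episodes, 1)

    @property
    def mean_latency(self) -> float | None:
        return float(np.mean(self.found)) if self.found else None

    @property
    def sd_latency(self) -> float | None:
        return float(np.std(self.found)) if self.found else None

    def histogram(self, step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Counts of episodes per latency bin over the search window."""
        lo, hi = self.window
        edges = np.arange(lo, hi + step, step)
        vals = [l for l in self.found if lo <= l <= hi]
        counts, _ = np.histogram(vals, bins=np.append(edges, hi + step) - step / 2)
        return edges, counts


@dataclass
class EvaluationReport:
    confusion: ConfusionCounts
    metrics: Metrics
    latency: LatencyProfile | None = None
    notes: list[str] = field(default_factory=list)


def evaluate_model(model: TrainedModel, test: SampleSet) -> EvaluationReport:
    if test.synthetic.any():
        raise ValueError("synthetic samples must never appear in a test set")
    pred = model.predict(test.X)
    c = confusion_from_predictions(test.y, pred)
    return EvaluationReport(confusion=c, metrics=metrics(c))


def split_patient_dependent(
    samples: SampleSet, train_frac: float = 0.6, min_samples: int = 10
) -> tuple[SampleSet, SampleSet]:
    """Chronological per-subject split: first 60 % train, rest test.

    Subjects with fewer than ``min_samples`` samples are skipped with a
    warning.  Synthetic samples are rejected outright — oversampling
    belongs after the split, on the training side only.
    """
    if samples.synthetic.any():
        raise ValueError("split must run before oversampling (synthetic samples found)")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    if samples.subject is None:
        subjects = np.zeros(len(samples), dtype=int)
    else:
        subjects = samples.subject
    train_parts, test_parts = [], []
    for subj in np.unique(subjects):
        idx = np.flatnonzero(subjects == subj)
        idx = idx[np.argsort(samples.t[idx], kind="stable")]
        if len(idx) < min_samples:
            warnings.warn(f"subject {subj!r} has fewer than {min_samples} samples; skipped")
            continue
        cut = int(len(idx) * train_frac)
        train_parts.append(samples.take(idx[:cut]))
        test_parts.append(samples.take(idx[cut:]))
    if not train_parts:
        raise ValueError("no subject had enough samples to split")
    return SampleSet.concatenate(train_parts), SampleSet.concatenate(test_parts)


def loocv_patient_independent(
    samples_by_subject: dict[str, SampleSet],
    classifier: str = "clsf_bagging",
    cost: CostSpec = CostSpec(),
    adasyn_cfg: AdasynConfig | None = None,
    seed: int = 0,
    **train_kwargs,
) -> tuple[dict[str, EvaluationReport], Metrics]:
    """Leave-one-subject-out cross-validation.

    For each held-out subject the classifier is trained on the pooled
    samples of all other subjects (with ADASYN applied to that pooled
    training set only) and evaluated on the held-out subject.  Folds
    whose test subject has no FoG get an undefined sensitivity and are
    excluded from the averaged sensitivity with a note.  The average is
    the unweighted mean of per-subject metrics.
    """
    if len(samples_by_subject) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    reports: dict[str, EvaluationReport] = {}
    for subj, test in samples_by_subject.items():
        train = SampleSet.concatenate(
            [s for other, s in samples_by_subject.items() if other != subj]
        )
        if adasyn_cfg is not None and adasyn_cfg.beta > 0:
            train = adasyn_oversample(train, adasyn_cfg)
        model = train_classifier(classifier, train, cost=cost, seed=seed, **train_kwargs)
        report = evaluate_model(model, test)
        if report.metrics.sensitivity is None:
            report.notes.append("no FoG samples in held-out subject; sensitivity undefined")
        reports[subj] = report

    def _mean(vals: list[float | None]) -> float | None:
        present = [v for v in vals if v is not None]
        return float(np.mean(present)) if present else None

    avg = Metrics(
        sensitivity=_mean([r.metrics.sensitivity for r in reports.values()]),
        specificity=_mean([r.metrics.specificity for r in reports.values()]),
        f1=_mean([r.metrics.f1 for r in reports.values()]),
    )
    return reports, avg


def latency_profile(
    pred_times: np.ndarray,
    pred_is_fog: np.ndarray,
    truth: LabelTrack,
    sampling_rate: float,
    window: tuple[float, float] = (-2.0, 4.0),
    stride: float = 0.5,
) -> LatencyProfile:
    """Episode-level latency of FoG predictions against true onsets.

    ``truth`` must be the *original* label track (before pre-FoG
    relabeling), so its episode starts are the clinical onsets.  For
    each true episode, the latency is the time of the first FoG-labeled
    prediction inside ``[onset + window[0], min(onset + window[1],
    episode_end + window[1])]`` minus the onset; episodes with no such
    prediction are missed.  Where search windows of adjacent episodes
    overlap, each prediction counts only toward the nearest onset.

    Because the classifier fires on the window stride, latency is only
    measurable on a ``stride``-spaced grid; the reported latency is the
    raw difference rounded to the nearest multiple of ``stride``.
    """
    pred_times = np.asarray(pred_times, dtype=float)
    pred_is_fog = np.asarray(pred_is_fog).astype(bool)
    episodes = [(a, b) for st, a, b in truth.episodes() if st == State.FOG]
    onsets = np.array([a / sampling_rate for a, _ in episodes])
    ends = np.array([b / sampling_rate for _, b in episodes])
    lo, hi = window

    fog_times = np.sort(pred_times[pred_is_fog])
    latencies: list[float | None] = []
    for i, (t0, t1) in enumerate(zip(onsets, ends)):
        t_min, t_max = t0 + lo, min(t0 + hi, t1 + hi)
        hit = None
        for tp in fog_times:
            if tp < t_min:
                continue
            if tp > t_max:
                break
            # assign each prediction to its nearest onset
            nearest = int(np.argmin(np.abs(onsets - tp)))
            if nearest != i:
                continue
            hit = round((tp - t0) / stride) * stride
            break
        latencies.append(None if hit is None else float(hit))
    return LatencyProfile(latencies=latencies, window=window)
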