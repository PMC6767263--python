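"""Stacked-sample assembly: six successive windows x four channels.

A classification sample at time ``T`` stacks the four features from the
window ending at ``T`` and the five previous window positions (0.5 s
stride, so the windows overlap and the total lookback is 4.5 s), for
each of the four sensor-axis channels: 4 features x 6 windows = 24
values per channel, 96 per sample.

Labeling follows the newest (right-most) window only: the sample is FoG
if at least one FoG-labeled timestamp falls in that window; samples
whose newest window touches excluded data are dropped.  Older windows
may overlap excluded spans — enforcing purity on the whole 4.5 s history
would discard most data around every stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import WindowSpec, featurize_channel
from .gait_synth import CHANNEL_NAMES, SignalRecording
from .preprocess import BinaryLabelTrack, BinaryState, preprocess_recording

__all__ = ["StackedSample", "SampleSet", "build_samples", "samples_from_recording"]

N_STACK_DEFAULT = 6
SAMPLE_DIM = 4 * N_STACK_DEFAULT * len(CHANNEL_NAMES)  # 96


@dataclass(frozen=True)
class StackedSample:
    """A single 96-element sample: 24 values per channel, channels in
    ``CHANNEL_NAMES`` order, windows oldest -> newest, features in
    (freeze index, sample entropy, power, SD) order within a window."""

    values: np.ndarray
    label: int          # 0 = NG, 1 = FOG
    time: float         # end time of the newest window, seconds


@dataclass
class SampleSet:
    """Columnar container for stacked samples.

    ``synthetic`` flags oversampled (ADASYN-generated) rows; they must
    never reach a test set.  ``subject`` optionally carries a subject id
    per row for the split/LOOCV protocols.
    """

    X: np.ndarray
    y: np.ndarray
    t: np.ndarray
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.t = np.asarray(self.t, dtype=float)
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.y), dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.t) != n or len(self.synthetic) != n:
            raise ValueError("X, y, t and synthetic must have matching lengths")
        if self.subject is not None:
            self.subject = np.asarray(self.subject)
            if len(self.subject) != n:
                raise ValueError("subject must match the number of samples")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_fog(self) -> int:
        return int(np.count_nonzero(self.y == 1))

    @property
    def n_ng(self) -> int:
        return int(np.count_nonzero(self.y == 0))

    @property
    def n_majority(self) -> int:
        return max(self.n_fog, self.n_ng)

    @property
    def n_minority(self) -> int:
        return min(self.n_fog, self.n_ng)

    def samples(self) -> list[StackedSample]:
        return [
            StackedSample(values=self.X[i].copy(), label=int(self.y[i]), time=float(self.t[i]))
            for i in range(len(self))
        ]

    @staticmethod
    def concatenate(parts: list["SampleSet"]) -> "SampleSet":
        has_subject = all(p.subject is not None for p in parts)
        return SampleSet(
            X=np.concatenate([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            t=np.concatenate([p.t for p in parts]),
            synthetic=np.concatenate([p.synthetic for p in parts]),
            subject=np.concatenate([p.subject for p in parts]) if has_subject else None,
        )

    def take(self, idx) -> "SampleSet":
        return SampleSet(
            X=self.X[idx],
            y=self.y[idx],
            t=self.t[idx],
            synthetic=self.synthetic[idx],
            subject=None if self.subject is None else self.subject[idx],
        )


def build_samples(
    features: dict[str, tuple[np.ndarray, np.ndarray]],
    labels: BinaryLabelTrack,
    rate: float,
    spec: WindowSpec = WindowSpec(),
    n_windows: int = N_STACK_DEFAULT,
) -> SampleSet:
    """Assemble stacked samples from per-channel feature tables.

    ``features`` maps each channel name to ``(times, F)`` as returned by
    :func:`fog_forecast.features.featurize_channel`; all four channels
    must share the same window grid.  A sample is emitted for every
    window position with at least ``n_windows - 1`` predecessors whose
    newest window contains no excluded timestamp; its label is FoG iff
    the newest window contains at least one FoG timestamp.
    """
    if set(features) != set(CHANNEL_NAMES):
        raise ValueError(f"features must cover exactly the channels {CHANNEL_NAMES}")
    times0 = features[CHANNEL_NAMES[0]][0]
    for c in CHANNEL_NAMES[1:]:
        if not np.array_equal(features[c][0], times0):
            raise ValueError("channel window grids are misaligned")

    length, step = spec.samples(rate)
    n_win = len(times0)
    states = labels.states

    X_rows, y_rows, t_rows = [], [], []
    for w in range(n_windows - 1, n_win):
        a = w * step
        newest = states[a: a + length]
        if np.any(newest == BinaryState.EXCLUDED):
            continue
        label = 1 if np.any(newest == BinaryState.FOG) else 0
        row = np.concatenate(
            [features[c][1][w - n_windows + 1: w + 1].ravel() for c in CHANNEL_NAMES]
        )
        X_rows.append(row)
        y_rows.append(label)
        t_rows.append(times0[w])

    dim = 4 * n_windows * len(CHANNEL_NAMES)
    if not X_rows:
        return SampleSet(X=np.empty((0, dim)), y=np.empty(0, dtype=np.int8), t=np.empty(0))
    return SampleSet(X=np.array(X_rows), y=np.array(y_rows), t=np.array(t_rows))


def samples_from_recording(
    rec: SignalRecording,
    target_rate: float = 64.0,
    pre_fog_seconds: float = 1.0,
    spec: WindowSpec = WindowSpec(),
    n_windows: int = N_STACK_DEFAULT,
) -> tuple[SampleSet, SignalRecording]:
    """Full pipeline from a raw recording to a labeled sample set.

    Returns the samples plus the resampled recording, whose (original,
    pre-relabeling) label track is the onset ground truth for latency
    evaluation.
    """
    rec_rs, binary = preprocess_recording(rec, target_rate, pre_fog_seconds)
    feats = {
        c: featurize_channel(rec_rs.channels[c], target_rate, spec) for c in CHANNEL_NAMES
    }
    samples = build_samples(feats, binary, target_rate, spec, n_windows)
    return samples, rec_rs
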