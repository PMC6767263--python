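"""Resampling and label editing ahead of feature extraction.

The analysis stream is built from a raw recording in three steps:

1. linear resampling of the signal (typically 128 -> 64 Hz; labels are
   carried over by nearest-preceding timestamp, since they are categorical);
2. pre-FoG relabeling: the second of signal immediately preceding every
   freeze onset is itself labeled FoG (unless it was a stop or
   no-activity period), so that classifiers can learn to fire *before*
   the onset;
3. exclusion of long stops (> 1 s) and long no-activity periods (> 2 s),
   collapsing the four-state track to {NG, FOG, EXCLUDED}.

Relabeling must run before exclusion so that it sees the original
stop/no-activity states; the composition is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .gait_synth import CHANNEL_NAMES, LabelTrack, SignalRecording, State

__all__ = [
    "BinaryState",
    "BinaryLabelTrack",
    "resample_linear",
    "relabel_pre_fog",
    "apply_exclusions",
    "preprocess_recording",
]


class BinaryState(IntEnum):
    NG = 0
    FOG = 1
    EXCLUDED = 2


@dataclass
class BinaryLabelTrack:
    """Binary analysis labels aligned to the resampled signal."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        bad = ~np.isin(self.states, [int(s) for s in BinaryState])
        if bad.any():
            raise ValueError("unknown binary state code")

    def __len__(self) -> int:
        return len(self.states)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinaryLabelTrack) and np.array_equal(
            self.states, other.states
        )


def resample_linear(rec: SignalRecording, target_rate: float) -> SignalRecording:
    """Linearly resample all channels to ``target_rate``.

    The output has ``floor(N * target / source)`` samples; channel values
    are linear interpolations at the new sample instants ``k/target``,
    and labels are taken from the nearest preceding original sample.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise ValueError("target_rate must not exceed the recording's rate")
    n_in = len(rec)
    n_out = int(np.floor(n_in * target_rate / rec.sampling_rate))
    t_new = np.arange(n_out) / target_rate
    t_old = np.arange(n_in) / rec.sampling_rate
    channels = {c: np.interp(t_new, t_old, rec.channels[c]) for c in CHANNEL_NAMES}
    idx = np.minimum(np.floor(t_new * rec.sampling_rate).astype(int), n_in - 1)
    labels = LabelTrack(rec.labels.states[idx])
    return SignalRecording(channels=channels, sampling_rate=target_rate, labels=labels)


def relabel_pre_fog(
    labels: LabelTrack, sampling_rate: float, pre_seconds: float = 1.0
) -> LabelTrack:
    """Label the ``pre_seconds`` before each FoG onset as FoG.

    Only normal-gait samples in ``[onset - pre_seconds, onset)`` are
    converted; stop and no-activity samples in that span are left alone.
    Windows are truncated at the start of the recording.  Applied
    per-onset with no merging of close episodes.
    """
    if pre_seconds < 0:
        raise ValueError("pre_seconds must be non-negative")
    out = labels.states.copy()
    span = int(round(pre_seconds * sampling_rate))
    for onset in labels.onsets(State.FOG):
        a = max(onset - span, 0)
        seg = out[a:onset]
        seg[seg == State.NG] = State.FOG
    return LabelTrack(out)


def apply_exclusions(
    labels: LabelTrack,
    sampling_rate: float,
    max_noact: float = 2.0,
    max_stop: float = 1.0,
) -> BinaryLabelTrack:
    """Collapse the four-state track to {NG, FOG, EXCLUDED}.

    No-activity episodes strictly longer than ``max_noact`` seconds and
    stop episodes strictly longer than ``max_stop`` seconds become
    EXCLUDED; shorter stop/no-activity episodes are kept as normal gait.
    """
    out = np.full(len(labels), BinaryState.NG, dtype=np.int8)
    for state, a, b in labels.episodes():
        dur = (b - a) / sampling_rate
        if state == State.FOG:
            out[a:b] = BinaryState.FOG
        elif state == State.STOP:
            out[a:b] = BinaryState.EXCLUDED if dur > max_stop else BinaryState.NG
        elif state == State.NOACT:
            out[a:b] = BinaryState.EXCLUDED if dur > max_noact else BinaryState.NG
    return BinaryLabelTrack(out)


def preprocess_recording(
    rec: SignalRecording,
    target_rate: float = 64.0,
    pre_fog_seconds: float = 1.0,
    max_noact: float = 2.0,
    max_stop: float = 1.0,
) -> tuple[SignalRecording, BinaryLabelTrack]:
    """Full preprocessing chain: resample, relabel, exclude.

    Returns the resampled recording (whose ``labels`` retain the
    *original* four-state episodes, resampled — the ground truth needed
    for onset-latency evaluation) and the binary analysis track.
    """
    rec64 = resample_linear(rec, target_rate)
    relabeled = relabel_pre_fog(rec64.labels, target_rate, pre_fog_seconds)
    binary = apply_exclusions(relabeled, target_rate, max_noact, max_stop)
    return rec64, binary
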