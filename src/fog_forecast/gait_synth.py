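"""Synthetic ankle-accelerometer recordings with ground-truth gait labels.

Real freezing-of-gait (FoG) datasets are rare events embedded in long
stretches of normal walking, punctuated by instructed stops and
off-protocol "no-activity" periods.  This module emulates that structure
with a minimal signal model that keeps the standard spectral features
discriminative:

* normal gait (NG): a locomotion-band sinusoid (fundamental + one
  harmonic) at the stride frequency, left and right ankles in anti-phase;
* FoG: a single freeze-band tone (3-8 Hz) at reduced amplitude — the
  low-amplitude trembling seen during freezes;
* stops / no-activity: noise only;
* everywhere: additive white Gaussian noise.

An optional amplitude-decay ramp over the last ``pre_fog_transition``
seconds of gait before each freeze makes pre-onset windows statistically
distinguishable from steady gait, which is what makes *prediction*
(firing before the onset) learnable at all.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "State",
    "CHANNEL_NAMES",
    "LabelTrack",
    "SignalRecording",
    "SynthConfig",
    "generate_recording",
    "write_recording",
    "read_recording",
    "ParseError",
]


class State(IntEnum):
    """Per-timestamp ground-truth gait state."""

    NG = 0      # normal gait
    FOG = 1     # freezing of gait
    STOP = 2    # instructed stop
    NOACT = 3   # no activity / off-protocol


#: Fixed channel order: sensor (left/right ankle) x axis (vertical/forward).
CHANNEL_NAMES = ("left_vertical", "left_forward", "right_vertical", "right_forward")

_STATE_NAMES = {s: s.name for s in State}
_NAME_STATES = {s.name: s for s in State}


class ParseError(ValueError):
    """Raised when a recording file cannot be parsed."""


@dataclass
class LabelTrack:
    """Aligned sequence of gait states, one per sample.

    ``episodes()`` run-length encodes the track into maximal
    constant-state segments ``(state, start, end)`` with ``end``
    exclusive; by construction the segments partition ``[0, N)`` and
    adjacent segments carry distinct states.
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("label track must be one-dimensional")
        bad = ~np.isin(self.states, [int(s) for s in State])
        if bad.any():
            raise ValueError(f"unknown state code at index {int(np.flatnonzero(bad)[0])}")

    def __len__(self) -> int:
        return len(self.states)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelTrack) and np.array_equal(self.states, other.states)

    def episodes(self) -> list[tuple[int, int, int]]:
        s = self.states
        if len(s) == 0:
            return []
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(s)]))
        return [(int(s[a]), int(a), int(b)) for a, b in zip(starts, ends)]

    def onsets(self, state: int = State.FOG) -> list[int]:
        """Start indices of every episode of ``state``."""
        return [a for st, a, _ in self.episodes() if st == state]


@dataclass
class SignalRecording:
    """Four acceleration channels plus an aligned label track."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    labels: LabelTrack

    def __post_init__(self) -> None:
        if tuple(self.channels) != CHANNEL_NAMES:
            raise ValueError(f"channels must be exactly {CHANNEL_NAMES} in order")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel length mismatch: {lengths}")
        if len(self.labels) != next(iter(lengths.values())):
            raise ValueError("labels and channels must have identical length")
        if self.sampling_rate <= 16.0:
            # Nyquist must cover the 8 Hz upper edge of the freeze band.
            raise ValueError("sampling_rate must exceed 16 Hz")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalRecording):
            return NotImplemented
        return (
            self.sampling_rate == other.sampling_rate
            and self.labels == other.labels
            and all(np.array_equal(self.channels[c], other.channels[c]) for c in CHANNEL_NAMES)
        )


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording generator.

    Amplitudes are in arbitrary acceleration units (think g); rates are
    per minute; durations in seconds.  Defaults reproduce the aggregate
    class imbalance of a typical clinical protocol: roughly 0.3 freeze
    episodes per minute with a 7 s mean duration, i.e. ~3.5 % of samples
    labeled FoG.
    """

    duration: float = 600.0
    sampling_rate: float = 128.0
    gait_freq: float = 1.0
    gait_amplitude: float = 1.0
    fog_freq: float = 5.0
    fog_amplitude: float = 0.5          # fraction of gait_amplitude
    fog_episode_rate: float = 0.3       # episodes / minute
    fog_duration_range: tuple[float, float] = (3.0, 11.0)
    stop_episode_rate: float = 0.5      # episodes / minute
    stop_duration_range: tuple[float, float] = (0.5, 3.0)
    noact_episode_rate: float = 0.1     # episodes / minute
    noact_duration_range: tuple[float, float] = (1.0, 5.0)
    pre_fog_transition: float = 1.0     # seconds of amplitude decay before onset
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        if not (0.5 <= self.gait_freq < 3.0):
            raise ValueError("gait_freq must lie in the locomotion band [0.5, 3) Hz")
        if not (3.0 <= self.fog_freq <= 8.0):
            raise ValueError("fog_freq must lie in the freeze band [3, 8] Hz")
        for name in ("fog_duration_range", "stop_duration_range", "noact_duration_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive with lo <= hi")
            if hi >= self.duration:
                raise ValueError(f"duration must exceed the longest {name} episode")
        if min(self.fog_episode_rate, self.stop_episode_rate, self.noact_episode_rate) < 0:
            raise ValueError("episode rates must be non-negative")
        if self.noise_sd < 0 or self.gait_amplitude < 0 or self.fog_amplitude < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")


def _draw_segments(cfg: SynthConfig, rng: np.random.Generator) -> list[tuple[int, float]]:
    """Draw a (state, duration-seconds) segment sequence covering ``cfg.duration``.

    Special episodes (FoG / stop / no-activity) arrive as a marked Poisson
    process on top of a normal-gait background; gaps between events are NG.
    """
    rates = np.array(
        [cfg.fog_episode_rate, cfg.stop_episode_rate, cfg.noact_episode_rate]
    ) / 60.0  # per second
    kinds = [State.FOG, State.STOP, State.NOACT]
    ranges = [cfg.fog_duration_range, cfg.stop_duration_range, cfg.noact_duration_range]
    total = rates.sum()

    segments: list[tuple[int, float]] = []
    t = 0.0
    while t < cfg.duration:
        if total <= 0:
            segments.append((State.NG, cfg.duration - t))
            break
        gap = rng.exponential(1.0 / total)
        if t + gap >= cfg.duration:
            segments.append((State.NG, cfg.duration - t))
            break
        if gap > 0:
            segments.append((State.NG, gap))
            t += gap
        which = rng.choice(3, p=rates / total)
        lo, hi = ranges[which]
        dur = min(rng.uniform(lo, hi), cfg.duration - t)
        segments.append((kinds[which], dur))
        t += dur
    return segments


def generate_recording(config: SynthConfig) -> SignalRecording:
    """Generate a two-sensor, two-axis recording with ground-truth labels.

    Identical configs (including ``seed``) yield bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate
    n_total = int(round(config.duration * rate))

    segments = _draw_segments(config, rng)
    # convert to sample counts with cumulative rounding so they sum to n_total
    bounds = np.round(np.cumsum([d for _, d in segments]) * rate).astype(int)
    bounds = np.clip(bounds, 0, n_total)
    bounds[-1] = n_total
    starts = np.concatenate(([0], bounds[:-1]))

    labels = np.zeros(n_total, dtype=np.int8)
    for (state, _), a, b in zip(segments, starts, bounds):
        labels[a:b] = state

    t = np.arange(n_total) / rate
    # amplitude envelope of the gait component: 1 during NG, ramping to 0
    # over the pre-FoG transition (gait arrest precedes the trembling),
    # 0 elsewhere (FoG carries its own tone)
    envelope = np.where(labels == State.NG, 1.0, 0.0)
    ramp_n = int(round(config.pre_fog_transition * rate))
    if ramp_n > 0:
        for (state, _), a, b in zip(segments, starts, bounds):
            if state != State.FOG:
                continue
            r0 = max(a - ramp_n, 0)
            k = np.arange(r0, a)
            decay = 1.0 - (k - (a - ramp_n)) / ramp_n  # 1 -> 0 across the ramp
            envelope[r0:a] = np.minimum(envelope[r0:a], decay) * (envelope[r0:a] > 0)

    fog_mask = (labels == State.FOG).astype(float)
    phases = {
        # (gait fundamental phase, forward-axis quarter-cycle offset)
        "left_vertical": 0.0,
        "left_forward": np.pi / 2,
        "right_vertical": np.pi,       # anti-phase: alternating stepping
        "right_forward": np.pi + np.pi / 2,
    }
    axis_scale = {"vertical": 1.0, "forward": 0.7}

    channels: dict[str, np.ndarray] = {}
    for name in CHANNEL_NAMES:
        phi = phases[name]
        scale = axis_scale[name.split("_")[1]]
        gait = config.gait_amplitude * scale * (
            np.sin(2 * np.pi * config.gait_freq * t + phi)
            + 0.5 * np.sin(4 * np.pi * config.gait_freq * t + 2 * phi)
        )
        fog = (
            config.fog_amplitude * config.gait_amplitude * scale
            * np.sin(2 * np.pi * config.fog_freq * t + phi)
        )
        noise = rng.normal(0.0, config.noise_sd, n_total) if config.noise_sd > 0 else 0.0
        channels[name] = envelope * gait + fog_mask * fog + noise

    return SignalRecording(channels=channels, sampling_rate=rate, labels=LabelTrack(labels))


# ---------------------------------------------------------------------------
# Storage: delimited text with a sampling-rate header line.  Column layout:
# time, the four channels, label (state name).  Floats are written with 17
# significant digits so the round trip is exact for IEEE doubles.
# ---------------------------------------------------------------------------

_RATE_PREFIX = "# sampling_rate_hz="


def write_recording(rec: SignalRecording, path) -> None:
    df = pd.DataFrame(
        {"time": np.arange(len(rec)) / rec.sampling_rate}
        | {c: rec.channels[c] for c in CHANNEL_NAMES}
        | {"label": [_STATE_NAMES[State(s)] for s in rec.labels.states]}
    )
    buf = io.StringIO()
    buf.write(f"{_RATE_PREFIX}{rec.sampling_rate!r}\n")
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_recording(path) -> SignalRecording:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_RATE_PREFIX):
            raise ParseError(f"{path}: line 1: expected '{_RATE_PREFIX}<rate>' header")
        try:
            rate = float(first[len(_RATE_PREFIX):])
        except ValueError:
            raise ParseError(f"{path}: line 1: malformed sampling rate") from None
        try:
            df = pd.read_csv(fh, dtype={"label": str}, float_precision="round_trip")
        except Exception as exc:  # pandas raises several parser error types
            raise ParseError(f"{path}: {exc}") from exc

    expected = ["time", *CHANNEL_NAMES, "label"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: line 2: expected columns {expected}, got {list(df.columns)}")
    bad = ~df["label"].isin(_NAME_STATES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        # +3: one header line, one column line, 1-based
        raise ParseError(f"{path}: line {i + 3}: unknown label {df['label'].iloc[i]!r}")
    for c in CHANNEL_NAMES:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            i = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ParseError(f"{path}: line {i + 3}: non-numeric value in field {c!r}")
    labels = LabelTrack(np.array([_NAME_STATES[v] for v in df["label"]], dtype=np.int8))
    channels = {c: df[c].to_numpy(dtype=float) for c in CHANNEL_NAMES}
    return SignalRecording(channels=channels, sampling_rate=rate, labels=labels)
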