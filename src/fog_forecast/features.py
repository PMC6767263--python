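"""Windowed features: freeze index, sample entropy, band power, SD.

Features are computed on 2 s sliding windows with 75 % overlap (0.5 s
step).  Spectral features use a single un-windowed (rectangular)
periodogram of the de-meaned segment; with 2 s windows the frequency
resolution is 0.5 Hz, which exactly resolves the band edges.  Band
membership is by bin-center frequency with the locomotion band
half-open, ``[0.5, 3)`` Hz, and the freeze band closed, ``[3, 8]`` Hz,
so the two bands tile the total-power band ``[0.5, 8]`` exactly.

The periodogram is scaled so that a unit-amplitude on-bin sinusoid
contributes 0.5 signal-units^2 (its variance) to its band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "freeze_index",
    "sample_entropy",
    "band_power",
    "std_dev",
    "featurize_channel",
]

#: Feature order within each window block of a stacked sample.
FEATURE_NAMES = ("freeze_index", "sample_entropy", "power", "std_dev")

FREEZE_BAND = (3.0, 8.0)
LOCOMOTION_BAND = (0.5, 3.0)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.  Default: 2 s windows, 75 % overlap."""

    length: float = 2.0
    overlap: float = 0.75

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must lie in [0, 1)")
        if self.length <= 0:
            raise ValueError("window length must be positive")

    @property
    def step(self) -> float:
        return self.length * (1 - self.overlap)

    def samples(self, rate: float) -> tuple[int, int]:
        """(window length, step) in samples; both must be integral."""
        n = self.length * rate
        s = self.step * rate
        if abs(n - round(n)) > 1e-9 or abs(s - round(s)) > 1e-9:
            raise ValueError("window length and step must be whole samples at this rate")
        return int(round(n)), int(round(s))


def _periodogram(window: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular periodogram of the de-meaned window.

    Returns (bin frequencies, per-bin power).  Power is normalised so a
    unit-amplitude sinusoid on a bin centre carries 0.5 units^2.
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    x = x - x.mean()
    spec = np.fft.rfft(x)
    power = (np.abs(spec) ** 2) * (2.0 / n**2)
    power[0] /= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, power


def _band_sum(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float,
              closed_hi: bool) -> float:
    if closed_hi:
        mask = (freqs >= lo) & (freqs <= hi)
    else:
        mask = (freqs >= lo) & (freqs < hi)
    return float(power[mask].sum())


def _check_window(window: np.ndarray, rate: float) -> None:
    if len(window) < 2 * rate:
        raise ValueError("window must cover at least 2 s (0.5 Hz resolution)")


def freeze_index(window: np.ndarray, rate: float, cap: float = 100.0) -> float:
    """Ratio of freeze-band (3-8 Hz) to locomotion-band ([0.5, 3) Hz) power.

    Elevated during FoG trembling.  When the locomotion power is
    negligible (machine-epsilon scale) the ratio is undefined and the
    configured ``cap`` is returned, keeping the feature bounded.
    """
    _check_window(window, rate)
    freqs, power = _periodogram(window, rate)
    p_freeze = _band_sum(freqs, power, *FREEZE_BAND, closed_hi=True)
    p_loco = _band_sum(freqs, power, *LOCOMOTION_BAND, closed_hi=False)
    eps = np.finfo(float).eps * len(window) * max(float(power.sum()), 1.0)
    if p_loco <= eps:
        return cap
    return min(p_freeze / p_loco, cap)


def band_power(window: np.ndarray, rate: float, lo: float = 0.5, hi: float = 8.0) -> float:
    """Total periodogram power over the closed band ``[lo, hi]`` Hz."""
    if lo >= hi:
        raise ValueError("band must satisfy lo < hi")
    _check_window(window, rate)
    freqs, power = _periodogram(window, rate)
    return _band_sum(freqs, power, lo, hi, closed_hi=True)


def sample_entropy(
    window: np.ndarray,
    m: int = 2,
    r: float | None = None,
    fallback: float | None = None,
) -> float:
    """Sample entropy (SampEn) of the window, in nats.

    SampEn = -ln(A/B), where B counts pairs of length-``m`` templates
    within Chebyshev distance ``r`` of each other (self-matches
    excluded) and A counts the same for length ``m+1``; both counts run
    over the first ``N - m`` templates so every length-``m`` template has
    a length-``m+1`` continuation.  Low values mean regular, repetitive
    signal; white noise scores high.

    ``r`` defaults to 0.2 x the window's population SD (the standard
    physiological-signal convention).  When A or B is zero the estimate
    is undefined; the returned ``fallback`` defaults to
    ``ln(number of possible template pairs)``, a finite upper bound.
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("window must have more than m + 1 samples")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r < 0 or (r == 0 and np.ptp(x) > 0):
        raise ValueError("tolerance r must be positive for a non-constant signal")

    n_templates = n - m
    tm1 = sliding_window_view(x, m + 1)              # (n_templates, m+1)
    tm = tm1[:, :m]                                   # length-m prefixes
    # pairwise Chebyshev distances (i < j), N <= a few hundred in practice
    d_m = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    d_m1 = np.maximum(d_m, np.abs(tm1[:, -1, None] - tm1[None, :, -1]))
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if a == 0 or b == 0:
        if fallback is not None:
            return fallback
        return math.log(n_templates * (n_templates - 1) / 2)
    return -math.log(a / b)


def std_dev(window: np.ndarray) -> float:
    """Population standard deviation of the window."""
    x = np.asarray(window, dtype=float)
    if len(x) == 0:
        raise ValueError("window must be non-empty")
    return float(np.std(x))


def featurize_channel(
    channel: np.ndarray,
    rate: float,
    spec: WindowSpec = WindowSpec(),
    freeze_cap: float = 100.0,
    m: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute all four features on every window position of a channel.

    Returns ``(times, F)`` where ``times[i]`` is the end time of window
    ``i`` in seconds and ``F`` has shape ``(n_windows, 4)`` with columns
    in ``FEATURE_NAMES`` order.  Window ``i`` covers samples
    ``[i*step, i*step + length)``; the number of windows is
    ``floor((N - length) / step) + 1``.
    """
    x = np.asarray(channel, dtype=float)
    length, step = spec.samples(rate)
    if len(x) < length:
        raise ValueError("channel shorter than one window")
    n_windows = (len(x) - length) // step + 1
    times = (np.arange(n_windows) * step + length) / rate
    feats = np.empty((n_windows, 4))
    for i in range(n_windows):
        w = x[i * step: i * step + length]
        feats[i, 0] = freeze_index(w, rate, cap=freeze_cap)
        feats[i, 1] = sample_entropy(w, m=m)
        feats[i, 2] = band_power(w, rate)
        feats[i, 3] = std_dev(w)
    return times, feats
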