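"""Shared fixtures: synthetic recordings and pooled sample sets.

All signal data are generated at test time from seeded configs; the
heavier pooled sets are session-scoped so the classifier tests reuse
them.
"""

import warnings

import numpy as np
import pytest
from hypothesis import settings

import fog_forecast as ff

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_pooled(seed: int, n_rec: int, duration: float, **synth_kw) -> ff.SampleSet:
    """Concatenate several short recordings into one time-ordered,
    single-subject sample set (times offset so chronology is global)."""
    sets, ts = [], []
    offset = 0.0
    for i in range(n_rec):
        cfg = ff.SynthConfig(
            duration=duration, seed=int((seed * 1000 + i) % 2**31), **synth_kw
        )
        samples, _ = ff.samples_from_recording(ff.generate_recording(cfg))
        ts.append(samples.t + offset)
        offset += duration
        sets.append(samples)
    pooled = ff.SampleSet.concatenate(sets)
    pooled.t = np.concatenate(ts)
    pooled.subject = np.full(len(pooled), "s0")
    return pooled


#: Generator settings for the "well-separated" regime: strong freeze-band
#: tone, low noise, no stops, long episodes frequent enough to populate
#: short recordings.
EASY_SYNTH = dict(
    fog_episode_rate=2.0,
    fog_amplitude=1.0,
    fog_duration_range=(6.0, 12.0),
    stop_episode_rate=0.0,
    noact_episode_rate=0.0,
    noise_sd=0.02,
)

#: Moderate regime for the monotonicity gates: default separability and
#: noise so sensitivity is not saturated and imbalance handling matters.
MODERATE_SYNTH = dict(fog_episode_rate=2.0, fog_amplitude=0.5, noise_sd=0.1)


@pytest.fixture(scope="session")
def easy_pooled() -> ff.SampleSet:
    return make_pooled(7, n_rec=8, duration=60.0, **EASY_SYNTH)


@pytest.fixture(scope="session")
def small_recording() -> ff.SignalRecording:
    cfg = ff.SynthConfig(duration=60.0, fog_episode_rate=2.0, seed=11)
    return ff.generate_recording(cfg)


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield
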