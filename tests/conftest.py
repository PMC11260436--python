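import dataclasses

import numpy as np
import pytest

from tapkin import (
    DisplacementSignal,
    FilterConfig,
    TapSignalParams,
    lowpass,
    simulate_cohort,
    simulate_signal,
)


def make_sinusoid(
    freq_hz: float = 3.0,
    half_amplitude: float = 18.0,
    offset: float = 23.0,
    duration_s: float = 10.0,
    frame_rate: float = 30.0,
    phase: float | None = None,
) -> DisplacementSignal:
    t = np.arange(0.0, duration_s, 1.0 / frame_rate)
    if phase is None:
        # valley exactly on frame 2: extrema land on the sample grid, so the
        # discretized trace carries the closed-form amplitudes and durations
        phase = -np.pi / 2 - 2 * np.pi * freq_hz * (2.0 / frame_rate)
    values = offset + half_amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return DisplacementSignal(frame_rate=frame_rate, values=values, filtered=False)


@pytest.fixture
def sinusoid_signal() -> DisplacementSignal:
    """Noiseless 3 Hz tapping-like sinusoid, 36 deg peak-to-valley, 10 s at 30 FPS."""
    return make_sinusoid()


@pytest.fixture
def filtered_sinusoid(sinusoid_signal) -> DisplacementSignal:
    return lowpass(sinusoid_signal, FilterConfig())


@pytest.fixture
def clean_params() -> TapSignalParams:
    """A deterministic generator configuration: no randomness, no decay."""
    return TapSignalParams(
        n_taps=30,
        mean_peak_to_valley=36.0,
        amplitude_cv=0.0,
        mean_cycle_duration=0.4,
        cycle_duration_cv=0.0,
        decay_ratio=1.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def clean_signal(clean_params) -> DisplacementSignal:
    return simulate_signal(clean_params)


@pytest.fixture(scope="session")
def small_cohort():
    """Shrunken-spread 4-class cohort shared across model tests."""
    return simulate_cohort(n_per_class=30, feature_noise_scale=0.25, seed=7)


def preset_params(score: int, **overrides) -> TapSignalParams:
    from tapkin import SEVERITY_PRESETS

    return dataclasses.replace(SEVERITY_PRESETS[score].params, **overrides)
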