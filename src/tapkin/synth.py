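"""Synthetic finger-tapping signals, landmark streams, and labeled cohorts.

The generator builds quasi-periodic opening/closing angle traces: each tap is
a half-cosine rise to its peak followed by a half-cosine fall back to a fixed
baseline, with per-tap amplitude and duration drawn around configurable means
and a deterministic linear amplitude trend that realizes a target first-half
over second-half amplitude ratio (the sequence-effect "decay").  Severity
presets 0-3 parameterize the generator at published per-score feature means
so downstream feature extraction and classification are testable without any
video data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AngleRangeError, ConfigurationError, InvalidParameterError
from .features import CSV_HEADER, FEATURE_NAMES, pipeline_features
from .kinematics import FilterConfig
from .pose_io import INDEX_TIP, N_LANDMARKS, THUMB_TIP, WRIST, DisplacementSignal, LandmarkSequence

BASELINE_DEG = 5.0  # fully-closed angle; keeps the trace positive under noise
PAD_AMP_FRAC = 0.6  # lead-in/out partial opening, fraction of mean amplitude
PAD_DUR_FRAC = 0.35  # lead-in/out duration, fraction of mean cycle duration


@dataclass(frozen=True)
class TapSignalParams:
    """Knobs for one synthetic tapping trial."""

    n_taps: int = 30
    mean_peak_to_valley: float = 36.0
    amplitude_cv: float = 0.1
    mean_cycle_duration: float = 0.4
    cycle_duration_cv: float = 0.1
    opening_fraction: float = 0.45
    decay_ratio: float = 1.0
    noise_sd: float = 0.0
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taps < 2:
            raise InvalidParameterError(f"n_taps must be >= 2, got {self.n_taps}")
        for name in ("mean_peak_to_valley", "mean_cycle_duration", "frame_rate", "decay_ratio"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("amplitude_cv", "cycle_duration_cv", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0 < self.opening_fraction < 1:
            raise InvalidParameterError(
                f"opening_fraction must be in (0,1), got {self.opening_fraction}"
            )
        if BASELINE_DEG + self.mean_peak_to_valley >= 175.0:
            raise InvalidParameterError("mean_peak_to_valley too large for the angle range")


@dataclass(frozen=True)
class SeverityPreset:
    """Generator parameters keyed to an ordinal clinical severity score."""

    score: int
    params: TapSignalParams
    # Between-subject spread of the per-trial targets, used by simulate_cohort.
    amplitude_sd: float = 0.0
    cycle_duration_sd: float = 0.0
    amplitude_cv_sd: float = 0.0
    cycle_duration_cv_sd: float = 0.0
    decay_sd: float = 0.0


def _preset(score, amp, amp_sd, dur, dur_sd, cv_amp, cv_amp_sd, cv_dur, cv_dur_sd,
            decay, decay_sd) -> SeverityPreset:
    return SeverityPreset(
        score=score,
        params=TapSignalParams(
            n_taps=40,
            mean_peak_to_valley=amp,
            amplitude_cv=cv_amp,
            mean_cycle_duration=dur,
            cycle_duration_cv=cv_dur,
            decay_ratio=decay,
            noise_sd=0.5,
        ),
        amplitude_sd=amp_sd,
        cycle_duration_sd=dur_sd,
        amplitude_cv_sd=cv_amp_sd,
        cycle_duration_cv_sd=cv_dur_sd,
        decay_sd=decay_sd,
    )


# Per-score targets: published group means (and between-subject SDs) of mean
# amplitude [deg], mean cycle duration [s], within-trial amplitude CV, cycle
# duration CV, and amplitude decay.
SEVERITY_PRESETS: dict[int, SeverityPreset] = {
    0: _preset(0, 36.81, 18.96, 0.44, 0.17, 0.17, 0.10, 0.12, 0.09, 1.02, 0.10),
    1: _preset(1, 32.86, 12.95, 0.33, 0.12, 0.15, 0.10, 0.08, 0.02, 1.13, 0.16),
    2: _preset(2, 31.04, 26.87, 0.37, 0.16, 0.21, 0.10, 0.14, 0.09, 1.23, 0.32),
    3: _preset(3, 26.87, 12.00, 0.37, 0.16, 0.28, 0.12, 0.24, 0.16, 1.20, 0.34),
}


def _amplitude_trend(n: int, decay_ratio: float) -> np.ndarray:
    """Unit-mean linear trend g_k with first-half/second-half mean ratio = decay_ratio.

    g_k = 1 + s*(k - (n-1)/2); the centered index has zero mean so the overall
    mean stays 1, and s is solved from the two half-means.
    """
    k = np.arange(n) - (n - 1) / 2.0
    half = n // 2
    m1 = k[:half].mean()
    m2 = k[half:].mean()
    r = decay_ratio
    s = (r - 1.0) / (m1 - r * m2)
    g = 1.0 + s * k
    return g


def draw_cycles(params: TapSignalParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-tap (durations, amplitudes) realizing the requested targets.

    The deterministic decay trend contributes to the realized amplitude CV, so
    the random multiplicative spread is shrunk to the residual
    ``sqrt(max(0, amplitude_cv^2 - trend_cv^2))`` and the total realized CV
    matches ``amplitude_cv`` in expectation.
    """
    n = params.n_taps
    g = _amplitude_trend(n, params.decay_ratio)
    trend_cv = float(np.std(g, ddof=1))  # mean(g) == 1
    resid_cv = float(np.sqrt(max(0.0, params.amplitude_cv**2 - trend_cv**2)))
    amp = params.mean_peak_to_valley * g * (1.0 + resid_cv * rng.standard_normal(n))
    amp = np.clip(amp, 1.0, 170.0 - BASELINE_DEG)
    dur = params.mean_cycle_duration * (
        1.0 + params.cycle_duration_cv * rng.standard_normal(n)
    )
    dur = np.clip(dur, 0.1 * params.mean_cycle_duration, None)
    return dur, amp


def _render(params: TapSignalParams, dur: np.ndarray, amp: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Sample the piecewise half-cosine trace on the frame grid."""
    pad_amp = PAD_AMP_FRAC * params.mean_peak_to_valley
    pad_dur = PAD_DUR_FRAC * params.mean_cycle_duration
    starts = pad_dur + np.concatenate([[0.0], np.cumsum(dur)])  # cycle boundaries
    total = starts[-1] + pad_dur
    t = np.arange(0.0, total, 1.0 / params.frame_rate)
    x = np.full(t.size, BASELINE_DEG)

    lead = t < pad_dur
    x[lead] = BASELINE_DEG + pad_amp * 0.5 * (1 + np.cos(np.pi * t[lead] / pad_dur))
    tail = t >= starts[-1]
    x[tail] = BASELINE_DEG + pad_amp * 0.5 * (
        1 - np.cos(np.pi * np.clip((t[tail] - starts[-1]) / pad_dur, 0, 1))
    )

    body = (~lead) & (~tail)
    tb = t[body]
    cyc = np.clip(np.searchsorted(starts, tb, side="right") - 1, 0, len(dur) - 1)
    tau = tb - starts[cyc]
    t_open = params.opening_fraction * dur[cyc]
    t_close = dur[cyc] - t_open
    opening = tau < t_open
    phase = np.where(
        opening,
        0.5 * (1 - np.cos(np.pi * np.clip(tau / t_open, 0, 1))),
        0.5 * (1 + np.cos(np.pi * np.clip((tau - t_open) / t_close, 0, 1))),
    )
    x[body] = BASELINE_DEG + amp[cyc] * phase

    if params.noise_sd > 0:
        x = x + params.noise_sd * rng.standard_normal(x.size)
    return np.clip(x, 0.0, 179.0)


def simulate_signal(params: TapSignalParams) -> DisplacementSignal:
    """Generate one synthetic tapping trial; reproducible under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    dur, amp = draw_cycles(params, rng)
    values = _render(params, dur, amp, rng)
    return DisplacementSignal(
        frame_rate=params.frame_rate, values=values, filtered=False, provenance="synth"
    )


def signal_to_landmarks(signal: DisplacementSignal) -> LandmarkSequence:
    """Embed an angle trace into a 21-landmark stream (inverse of angle extraction).

    The wrist sits at the origin, the index base-to-tip vector is fixed, and
    the thumb tip is rotated in the xy-plane so the angle between the two
    base-to-tip vectors equals the signal at every frame.  The 18 remaining
    landmarks are constant plausible offsets; they are unused downstream.
    """
    angles = signal.values
    if (angles < 0).any() or (angles >= 180).any():
        raise AngleRangeError("signal angles must lie in [0, 180) degrees")
    n = len(signal)
    coords = np.zeros((n, N_LANDMARKS, 3))
    # static skeleton: crude open-hand pose in normalized-image-like units
    rng = np.random.default_rng(12345)
    static = 0.05 + 0.25 * rng.random((N_LANDMARKS, 3))
    static[:, 2] = 0.0
    coords[:] = static
    coords[:, WRIST, :] = 0.0
    index_vec = np.array([0.0, -0.3, 0.0])  # pointing "up" in image coordinates
    coords[:, INDEX_TIP, :] = index_vec
    theta = np.radians(angles)
    # rotate the index vector by -theta about z
    coords[:, THUMB_TIP, 0] = index_vec[0] * np.cos(theta) + index_vec[1] * np.sin(theta)
    coords[:, THUMB_TIP, 1] = -index_vec[0] * np.sin(theta) + index_vec[1] * np.cos(theta)
    coords[:, THUMB_TIP, 2] = 0.0
    return LandmarkSequence(frame_rate=signal.frame_rate, coords=coords)


def simulate_cohort(
    n_per_class: int,
    presets: dict[int, SeverityPreset] | None = None,
    feature_noise_scale: float = 1.0,
    seed: int = 0,
    scores: tuple[int, ...] = (0, 1, 2, 3),
    filter_config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Simulate a labeled cohort and run the full feature pipeline on it.

    Each subject draws trial-level targets (amplitude, cycle duration, CVs,
    decay) around its severity preset with between-subject SDs scaled by
    ``feature_noise_scale``, simulates a trial, and is featurized through the
    filter/segment/extract pipeline.  Age is drawn around 63 +/- 8 years, sex
    is balanced Bernoulli, and ``is_control`` flags score-0 rows.
    """
    if n_per_class < 2:
        raise InvalidParameterError(f"n_per_class must be >= 2, got {n_per_class}")
    presets = presets if presets is not None else SEVERITY_PRESETS
    missing = [s for s in scores if s not in presets]
    if missing:
        raise ConfigurationError(f"no preset for requested score(s) {missing}")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for score in scores:
        preset = presets[score]
        base = preset.params
        for i in range(n_per_class):
            s = feature_noise_scale
            params = replace(
                base,
                mean_peak_to_valley=float(np.clip(
                    rng.normal(base.mean_peak_to_valley, s * preset.amplitude_sd), 8.0, 160.0)),
                mean_cycle_duration=float(np.clip(
                    rng.normal(base.mean_cycle_duration, s * preset.cycle_duration_sd), 0.15, 2.0)),
                amplitude_cv=float(np.clip(
                    rng.normal(base.amplitude_cv, s * preset.amplitude_cv_sd), 0.0, 0.8)),
                cycle_duration_cv=float(np.clip(
                    rng.normal(base.cycle_duration_cv, s * preset.cycle_duration_cv_sd), 0.0, 0.8)),
                decay_ratio=float(np.clip(
                    rng.normal(base.decay_ratio, s * preset.decay_sd), 0.6, 2.5)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            fv = pipeline_features(simulate_signal(params), filter_config)
            row = {k: v for k, v in fv.as_dict().items() if k in FEATURE_NAMES}
            row["age"] = float(np.clip(rng.normal(63.0, 8.0), 40.0, 85.0))
            row["sex"] = int(rng.integers(0, 2))
            row["score"] = int(score)
            row["is_control"] = bool(score == 0)
            rows.append(row)
    return pd.DataFrame(rows, columns=CSV_HEADER)
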