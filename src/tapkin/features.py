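"""The 13 per-trial kinematic features computed from a segmented angle trace.

Per tap ``k`` with events (valley ``v_k``, peak ``p_k``, valley ``v_{k+1}``):

* amplitude ``A_k``       = angle(p_k) - angle(v_k)           (opening excursion)
* closing amplitude       = angle(p_k) - angle(v_{k+1})
* opening duration        = t(p_k) - t(v_k)
* closing duration        = t(v_{k+1}) - t(p_k)
* cycle duration ``D_k``  = t(v_{k+1}) - t(v_k)
* speed                   = A_k / D_k
* opening / closing speed = excursion over the corresponding sub-movement time

Trial-level summaries: mean and CV (sample SD over mean) of amplitude and of
each speed, mean/CV/range of cycle duration, tapping rate (taps over the
first-to-last-valley span), and amplitude decay (mean amplitude of the first
half of taps over the second half, split by tap index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InsufficientTapsError,
    SegmentationIntegrityError,
    TapkinError,
    UsageError,
)
from .kinematics import CycleSegmentation, FilterConfig, compute_angle_signal, lowpass, segment_cycles
from .pose_io import DisplacementSignal, fill_gaps, read_displacement, read_landmarks

logger = logging.getLogger(__name__)

FEATURE_NAMES: list[str] = [
    "mean_amplitude",
    "cv_amplitude",
    "mean_speed",
    "cv_speed",
    "mean_opening_speed",
    "cv_opening_speed",
    "mean_closing_speed",
    "cv_closing_speed",
    "mean_cycle_duration",
    "cv_cycle_duration",
    "range_cycle_duration",
    "rate",
    "amplitude_decay",
]

COVARIATE_NAMES: list[str] = ["age", "sex"]
LABEL_NAMES: list[str] = ["score", "is_control"]
CSV_HEADER: list[str] = FEATURE_NAMES + COVARIATE_NAMES + LABEL_NAMES

MIN_TAPS = 4


@dataclass
class FeatureVector:
    mean_amplitude: float
    cv_amplitude: float
    mean_speed: float
    cv_speed: float
    mean_opening_speed: float
    cv_opening_speed: float
    mean_closing_speed: float
    cv_closing_speed: float
    mean_cycle_duration: float
    cv_cycle_duration: float
    range_cycle_duration: float
    rate: float
    amplitude_decay: float
    age: float | None = None
    sex: int | None = None
    score: int | None = None
    is_control: bool | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _cv(x: np.ndarray) -> float:
    """Sample (n-1) standard deviation over mean."""
    return float(np.std(x, ddof=1) / np.mean(x))


def extract_features(signal: DisplacementSignal, seg: CycleSegmentation) -> FeatureVector:
    """Compute the 13 kinematic features from a segmented trial."""
    n = seg.n_taps
    if n < MIN_TAPS:
        raise InsufficientTapsError(f"need >= {MIN_TAPS} taps, got {n}")
    t = seg.taps
    x = signal.values
    dt = 1.0 / signal.frame_rate

    v0, p, v1 = t[:, 0], t[:, 1], t[:, 2]
    amp = x[p] - x[v0]
    closing_amp = x[p] - x[v1]
    if (amp <= 0).any() or (closing_amp <= 0).any():
        raise SegmentationIntegrityError("non-positive tap amplitude; segmentation is inconsistent")
    opening_dur = (p - v0) * dt
    closing_dur = (v1 - p) * dt
    cycle_dur = (v1 - v0) * dt

    speed = amp / cycle_dur
    opening_speed = amp / opening_dur
    closing_speed = closing_amp / closing_dur

    half = n // 2
    decay = float(np.mean(amp[:half]) / np.mean(amp[half:]))
    span = (seg.valley_indices[-1] - seg.valley_indices[0]) * dt
    return FeatureVector(
        mean_amplitude=float(np.mean(amp)),
        cv_amplitude=_cv(amp),
        mean_speed=float(np.mean(speed)),
        cv_speed=_cv(speed),
        mean_opening_speed=float(np.mean(opening_speed)),
        cv_opening_speed=_cv(opening_speed),
        mean_closing_speed=float(np.mean(closing_speed)),
        cv_closing_speed=_cv(closing_speed),
        mean_cycle_duration=float(np.mean(cycle_dur)),
        cv_cycle_duration=_cv(cycle_dur),
        range_cycle_duration=float(np.max(cycle_dur) - np.min(cycle_dur)),
        rate=float(n / span),
        amplitude_decay=decay,
    )


def pipeline_features(
    signal: DisplacementSignal,
    filter_config: FilterConfig = FilterConfig(),
    min_prominence_frac: float = 0.1,
    min_separation: float = 0.1,
) -> FeatureVector:
    """Filter, segment, and featurize a raw displacement signal."""
    filtered = signal if signal.filtered else lowpass(signal, filter_config)
    seg = segment_cycles(filtered, min_prominence_frac, min_separation)
    return extract_features(filtered, seg)


def batch_extract(
    inputs: list[str | Path],
    frame_rate: float | None = None,
    filter_config: FilterConfig = FilterConfig(),
    min_prominence_frac: float = 0.1,
    min_separation: float = 0.1,
    max_gap: float = 0.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Featurize a batch of landmark or displacement files.

    Landmark files (``.json`` or wide CSVs) are gap-filled and converted to
    angle signals; two-column CSVs are read as displacement signals directly.
    Per-file failures are logged and collected, not fatal to the batch.

    Returns the feature table (one row per successful input, indexed by file
    name) and a list of ``{"path", "error"}`` records for the failures.
    """
    if not inputs:
        raise UsageError("batch_extract requires at least one input file")
    rows: list[dict] = []
    index: list[str] = []
    failures: list[dict] = []
    for item in inputs:
        path = Path(item)
        try:
            signal = _load_signal(path, frame_rate, max_gap)
            fv = pipeline_features(signal, filter_config, min_prominence_frac, min_separation)
            rows.append({k: v for k, v in fv.as_dict().items() if k in FEATURE_NAMES})
            index.append(path.name)
        except (TapkinError, OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            failures.append({"path": str(path), "error": str(exc)})
    table = pd.DataFrame(rows, index=index, columns=FEATURE_NAMES)
    return table, failures


def _load_signal(path: Path, frame_rate: float | None, max_gap: float) -> DisplacementSignal:
    if path.suffix.lower() == ".json":
        seq = read_landmarks(path, frame_rate=frame_rate)
    else:
        header = pd.read_csv(path, nrows=0).columns
        if list(header) == ["time_s", "angle_deg"]:
            return read_displacement(path)
        seq = read_landmarks(path, frame_rate=frame_rate)
    segments = fill_gaps(seq, max_gap=max_gap)
    if len(segments) > 1:
        logger.warning("%s split into %d segments by long gaps; using longest", path, len(segments))
    seq = max(segments, key=len)
    return compute_angle_signal(seq)
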