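"""Angle extraction, low-pass filtering, and tapping-cycle segmentation.

The opening angle is the angle between the two vectors joining the hand base
(wrist) to the thumb tip and to the index tip.  The raw per-frame angle trace
is low-pass filtered (default 7 Hz cut-off, zero phase) and segmented into
alternating valleys (fingers closed) and peaks (fingers fully open); each
complete tap is a valley-peak-valley triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    EmptySignalError,
    InsufficientMovementError,
)
from .pose_io import INDEX_TIP, THUMB_TIP, WRIST, DisplacementSignal, LandmarkSequence

DEFAULT_CUTOFF_HZ = 7.0
DEFAULT_ORDER = 4
DEFAULT_MIN_PROMINENCE_FRAC = 0.1
DEFAULT_MIN_SEPARATION_S = 0.1


@dataclass(frozen=True)
class FilterConfig:
    """Low-pass filter settings: Butterworth, applied forward-backward."""

    cutoff: float = DEFAULT_CUTOFF_HZ
    order: int = DEFAULT_ORDER
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ConfigurationError(f"order must be >= 1, got {self.order}")


@dataclass
class CycleSegmentation:
    """Alternating valley/peak indices and per-tap (valley, peak, valley) triplets."""

    valley_indices: np.ndarray
    peak_indices: np.ndarray
    taps: np.ndarray = field(default=None)  # type: ignore[assignment]  # (n_taps, 3)

    def __post_init__(self) -> None:
        self.valley_indices = np.asarray(self.valley_indices, dtype=int)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.taps is None:
            self.taps = np.column_stack(
                [self.valley_indices[:-1], self.peak_indices, self.valley_indices[1:]]
            )
        self.taps = np.asarray(self.taps, dtype=int)

    @property
    def n_taps(self) -> int:
        return self.taps.shape[0]


def compute_angle_signal(seq: LandmarkSequence) -> DisplacementSignal:
    """Per-frame thumb-index opening angle in degrees.

    For each frame, with ``b`` the wrist, ``t`` the thumb tip and ``i`` the
    index tip, the angle is ``arccos((t-b)·(i-b) / (|t-b| |i-b|))`` with the
    cosine clamped to [-1, 1].  Works for 2-D and 3-D coordinates and is
    invariant to rigid transforms and uniform scaling.
    """
    if not seq.mask.all():
        raise EmptySignalError("sequence has masked frames; run fill_gaps first")
    base = seq.coords[:, WRIST, :]
    v1 = seq.coords[:, THUMB_TIP, :] - base
    v2 = seq.coords[:, INDEX_TIP, :] - base
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    bad = np.flatnonzero((n1 == 0) | (n2 == 0))
    if bad.size:
        raise DegenerateGeometryError(
            f"fingertip coincides with hand base at frame {int(bad[0])}"
        )
    cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    return DisplacementSignal(frame_rate=seq.frame_rate, values=angles, filtered=False)


def lowpass(signal: DisplacementSignal, cfg: FilterConfig = FilterConfig()) -> DisplacementSignal:
    """Zero-phase Butterworth low-pass; length preserved, DC gain exactly 1."""
    nyquist = signal.frame_rate / 2.0
    if cfg.cutoff >= nyquist:
        raise ConfigurationError(
            f"cutoff {cfg.cutoff} Hz must be below Nyquist {nyquist} Hz"
        )
    if len(signal) <= 3 * cfg.order:
        raise EmptySignalError(f"signal too short to filter (need > {3 * cfg.order} samples)")
    sos = sps.butter(cfg.order, cfg.cutoff, btype="low", fs=signal.frame_rate, output="sos")
    if cfg.zero_phase:
        filtered = sps.sosfiltfilt(sos, signal.values)
    else:
        filtered = sps.sosfilt(sos, signal.values)
    return DisplacementSignal(
        frame_rate=signal.frame_rate,
        values=filtered,
        filtered=True,
        provenance=signal.provenance,
    )


def _enforce_alternation(values: np.ndarray, peaks: np.ndarray, valleys: np.ndarray):
    """Merge candidate extrema into a strictly alternating valley/peak train.

    Between consecutive peaks the single lowest valley survives; between
    consecutive valleys the single highest peak survives.
    """
    events = [(int(i), +1) for i in peaks] + [(int(i), -1) for i in valleys]
    events.sort()
    out: list[tuple[int, int]] = []
    for idx, kind in events:
        if out and out[-1][1] == kind:
            prev, _ = out[-1]
            better = (values[idx] > values[prev]) if kind == +1 else (values[idx] < values[prev])
            if better:
                out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    return out


def segment_cycles(
    signal: DisplacementSignal,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
) -> CycleSegmentation:
    """Detect alternating peaks and valleys; return complete taps only.

    Prominence threshold is ``min_prominence_frac`` times the robust signal
    range (95th minus 5th percentile); ``min_separation`` is the minimum time
    between same-kind extrema.  Partial leading/trailing cycles are dropped:
    the event train is trimmed to start and end on a valley.
    """
    if not signal.filtered:
        raise ConfigurationError("segment_cycles requires a filtered signal; run lowpass first")
    x = signal.values
    lo, hi = np.percentile(x, [5, 95])
    rng = hi - lo
    if rng <= 0:
        raise InsufficientMovementError("signal has no dynamic range")
    prominence = min_prominence_frac * rng
    distance = max(1, int(round(min_separation * signal.frame_rate)))
    peaks, _ = sps.find_peaks(x, prominence=prominence, distance=distance)
    valleys, _ = sps.find_peaks(-x, prominence=prominence, distance=distance)
    if peaks.size == 0 or valleys.size < 2:
        raise InsufficientMovementError(
            f"found {peaks.size} peaks / {valleys.size} valleys; need >= 2 complete taps"
        )
    events = _enforce_alternation(x, peaks, valleys)
    # trim to valley ... valley
    while events and events[0][1] != -1:
        events.pop(0)
    while events and events[-1][1] != -1:
        events.pop()
    v_idx = np.array([i for i, k in events if k == -1], dtype=int)
    p_idx = np.array([i for i, k in events if k == +1], dtype=int)
    if p_idx.size < 2 or v_idx.size != p_idx.size + 1:
        raise InsufficientMovementError(
            f"only {p_idx.size} complete taps found; need >= 2"
        )
    return CycleSegmentation(valley_indices=v_idx, peak_indices=p_idx)
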