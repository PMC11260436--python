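"""Hand-landmark and displacement-signal containers and file I/O.

Landmark streams follow the 21-point MediaPipe hand convention: index 0 is
the wrist (hand base), indices 1-4 the thumb, 5-8 the index finger and so on
tip-last per finger.  Coordinates may be 2-D or 3-D, in normalized-image or
metric units; downstream angle computation is scale- and unit-invariant.

File dialects
-------------
Landmark CSV: header ``frame,x0,y0,z0,...,x20,y20,z20``; one row per frame;
missing frames may be encoded either as absent frame indices or as rows of
NaNs.  Landmark JSON: list of ``{"frame": i, "landmarks": [[x, y, z], ...]}``.
Displacement CSV: header ``time_s,angle_deg``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptySignalError, OrderingError, SchemaError

N_LANDMARKS = 21
WRIST = 0
THUMB_TIP = 4
INDEX_TIP = 8

DEFAULT_MAX_GAP_S = 0.5


@dataclass
class LandmarkSequence:
    """Per-frame 21-landmark hand coordinates at a fixed frame rate.

    Parameters
    ----------
    frame_rate : float
        Sampling rate in Hz; must be positive.
    coords : ndarray of shape (n_frames, 21, ndim)
        Landmark coordinates, ``ndim`` 2 or 3.  Masked frames may hold NaNs.
    mask : ndarray of bool, shape (n_frames,)
        True where the hand was detected (frame present).
    """

    frame_rate: float
    coords: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.frame_rate <= 0:
            raise SchemaError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.coords.ndim != 3 or self.coords.shape[1] != N_LANDMARKS:
            raise SchemaError(
                f"coords must have shape (n_frames, {N_LANDMARKS}, ndim), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[2] not in (2, 3):
            raise SchemaError(f"landmarks must be 2-D or 3-D, got {self.coords.shape[2]}-D")
        if self.mask is None:
            self.mask = ~np.isnan(self.coords).any(axis=(1, 2))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.coords.shape[0],):
            raise SchemaError("mask length must equal number of frames")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dim(self) -> int:
        return self.coords.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate


@dataclass
class DisplacementSignal:
    """Uniformly sampled thumb-index opening angle trace in degrees."""

    frame_rate: float
    values: np.ndarray
    filtered: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise SchemaError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise EmptySignalError("signal needs at least 2 samples")
        if not np.isfinite(self.values).all():
            raise SchemaError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate


def _csv_header() -> list[str]:
    cols = ["frame"]
    for i in range(N_LANDMARKS):
        cols += [f"x{i}", f"y{i}", f"z{i}"]
    return cols


def write_landmarks(seq: LandmarkSequence, path: str | Path, format: str | None = None) -> None:
    """Write a landmark sequence as CSV or JSON (inferred from suffix)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    coords = seq.coords
    if coords.shape[2] == 2:  # pad z with zeros for the on-disk dialect
        coords = np.concatenate([coords, np.zeros_like(coords[:, :, :1])], axis=2)
    if fmt == "csv":
        flat = coords.reshape(len(seq), -1)
        flat = np.where(seq.mask[:, None], flat, np.nan)
        df = pd.DataFrame(flat, columns=_csv_header()[1:])
        df.insert(0, "frame", np.arange(len(seq)))
        df.to_csv(path, index=False)
    elif fmt == "json":
        records = []
        for i in range(len(seq)):
            if not seq.mask[i]:
                continue
            records.append({"frame": int(i), "landmarks": coords[i].tolist()})
        payload = {"frame_rate": seq.frame_rate, "frames": records, "n_frames": len(seq)}
        path.write_text(json.dumps(payload))
    else:
        raise SchemaError(f"unknown landmark format {fmt!r}")


def read_landmarks(
    path: str | Path, format: str | None = None, frame_rate: float | None = None
) -> LandmarkSequence:
    """Read a landmark sequence; frames missing from the file become masked.

    ``frame_rate`` is required for CSV (the dialect has no header metadata);
    JSON carries its own and ``frame_rate`` overrides it if given.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        if frame_rate is None:
            raise SchemaError("frame_rate is required when reading landmark CSV")
        df = pd.read_csv(path)
        expected = _csv_header()
        if list(df.columns) != expected:
            n_coord_cols = len(df.columns) - 1
            if n_coord_cols % 3 == 0 and n_coord_cols // 3 != N_LANDMARKS:
                raise SchemaError(
                    f"expected {N_LANDMARKS} landmarks per frame, got {n_coord_cols // 3}"
                )
            raise SchemaError(f"landmark CSV header mismatch in {path}")
        frames = df["frame"].to_numpy()
        if not (np.diff(frames) > 0).all():
            raise OrderingError(f"frame indices not strictly increasing in {path}")
        n_frames = int(frames[-1]) + 1
        coords = np.full((n_frames, N_LANDMARKS, 3), np.nan)
        coords[frames.astype(int)] = df[expected[1:]].to_numpy().reshape(-1, N_LANDMARKS, 3)
        return LandmarkSequence(frame_rate=frame_rate, coords=coords)
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        fr = frame_rate if frame_rate is not None else payload.get("frame_rate")
        if fr is None:
            raise SchemaError("frame_rate absent from JSON and not supplied")
        records = payload["frames"]
        idx = np.array([r["frame"] for r in records], dtype=int)
        if idx.size and not (np.diff(idx) > 0).all():
            raise OrderingError(f"frame indices not strictly increasing in {path}")
        n_frames = int(payload.get("n_frames", (idx[-1] + 1) if idx.size else 0))
        coords = np.full((n_frames, N_LANDMARKS, 3), np.nan)
        for r in records:
            lm = np.asarray(r["landmarks"], dtype=float)
            if lm.shape != (N_LANDMARKS, 3):
                raise SchemaError(
                    f"expected {N_LANDMARKS} landmarks, got {lm.shape[0]} at frame {r['frame']}"
                )
            coords[r["frame"]] = lm
        return LandmarkSequence(frame_rate=float(fr), coords=coords)
    raise SchemaError(f"unknown landmark format {fmt!r}")


def write_displacement(signal: DisplacementSignal, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": signal.times, "angle_deg": signal.values})
    df.to_csv(path, index=False)


def read_displacement(path: str | Path) -> DisplacementSignal:
    """Read a ``time_s,angle_deg`` CSV; frame rate inferred from the time grid."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "angle_deg"]:
        raise SchemaError(f"displacement CSV must have columns time_s,angle_deg, got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise EmptySignalError("displacement signal needs at least 2 samples")
    dt = np.diff(t)
    if not (dt > 0).all():
        raise OrderingError("time_s not strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SchemaError("displacement signal must be uniformly sampled")
    return DisplacementSignal(frame_rate=1.0 / dt[0], values=df["angle_deg"].to_numpy(),
                              provenance=str(path))


def fill_gaps(seq: LandmarkSequence, max_gap: float = DEFAULT_MAX_GAP_S) -> list[LandmarkSequence]:
    """Interpolate short detection gaps; split the sequence at long ones.

    Gaps of masked frames lasting at most ``max_gap`` seconds are filled by
    per-coordinate linear interpolation between the flanking detected frames.
    Longer gaps (and masked runs touching either end) split the sequence;
    each returned segment is fully unmasked and analyzable on its own.
    """
    if not seq.mask.any():
        raise EmptySignalError("all frames masked; nothing to interpolate")
    max_gap_frames = int(round(max_gap * seq.frame_rate))
    present = np.flatnonzero(seq.mask)
    coords = seq.coords.copy()

    # Fill short interior gaps in place.
    split_after: set[int] = set()
    for a, b in zip(present[:-1], present[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        if gap <= max_gap_frames:
            w = np.linspace(0.0, 1.0, gap + 2)[1:-1]
            coords[a + 1 : b] = (1 - w)[:, None, None] * coords[a] + w[:, None, None] * coords[b]
        else:
            split_after.add(int(a))

    segments: list[LandmarkSequence] = []
    start = int(present[0])
    boundaries = sorted(split_after) + [int(present[-1])]
    for end in boundaries:
        if end >= start:
            seg = coords[start : end + 1]
            segments.append(LandmarkSequence(seq.frame_rate, seg, np.ones(len(seg), bool)))
        if end in split_after:
            nxt = present[present > end]
            start = int(nxt[0]) if nxt.size else end + 1
    return segments
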