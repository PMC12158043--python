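"""Core data types and file I/O for VR gaze scoring.

The scorer works on four kinds of objects: time-stamped 3D gaze traces
(:class:`GazeTrace`), planar rectangular areas of interest whose pose may
change over time (:class:`AOITrajectory`), per-stimulus analysis windows
(:class:`StimulusWindow`), and the per-stimulus result
(:class:`FixationScore`).  All times are absolute experiment-clock seconds;
all positions are world units in the virtual scene's frame.

File formats are deliberately plain: gaze traces are CSV with columns
``t,x,y,z,valid``; AOI trajectories and stimulus windows live together in
one JSON document; scores and manual-rater annotations are CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABSENT",
    "GazeTrace",
    "AOIPose",
    "AOITrajectory",
    "StimulusWindow",
    "FixationScore",
    "RaterTable",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_aoi_json",
    "write_aoi_json",
    "write_scores_csv",
    "read_scores_csv",
    "read_annotations_csv",
    "write_annotations_csv",
]

#: Sentinel for a TOFF that does not exist (gaze never entered the AOI).
#: Represented as NaN in arrays/CSV but exported under a readable name so
#: callers never confuse "no first fixation" with a time of 0.
ABSENT = float("nan")

_AXIS_TOL = 1e-9


def _is_absent(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class GazeTrace:
    """An ordered series of 3D gaze samples with per-sample validity.

    Parameters
    ----------
    t : array of float
        Sample timestamps, seconds, strictly increasing.
    p : array of shape (n, 3)
        World-space gaze point per sample.  Must be finite for valid
        samples; invalid samples typically carry a stale or zero position
        from the acquisition stack and are ignored by the scorer.
    valid : boolean array
        True where the eye tracker reported a usable gaze estimate.
    rate_hz : float
        Nominal sampling rate in Hz.
    """

    t: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    rate_hz: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "valid", valid)
        if t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        n = t.size
        if p.shape != (n, 3):
            raise ValueError(f"p must have shape ({n}, 3), got {p.shape}")
        if valid.shape != (n,):
            raise ValueError("valid must match t in length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(t)):
            raise ValueError("timestamps must be finite")
        if n > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at sample {bad}")
        if np.any(valid & ~np.all(np.isfinite(p), axis=1)):
            raise ValueError("valid samples must have finite positions")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Span from first to last timestamp, seconds (0 if < 2 samples)."""
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0


@dataclass(frozen=True)
class AOIPose:
    """Pose of a planar rectangular AOI at one instant.

    The rectangle lies in the plane spanned by the orthonormal in-plane
    axes ``axis_u`` / ``axis_v`` through ``center``, with half-extents
    ``half_w`` along u and ``half_h`` along v (world units).
    """

    t: float
    center: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    half_w: float
    half_h: float

    def __post_init__(self):
        for name in ("center", "axis_u", "axis_v"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        if abs(np.linalg.norm(self.axis_u) - 1.0) > 1e-6:
            raise ValueError("axis_u must be unit length")
        if abs(np.linalg.norm(self.axis_v) - 1.0) > 1e-6:
            raise ValueError("axis_v must be unit length")
        if abs(float(self.axis_u @ self.axis_v)) > 1e-6:
            raise ValueError("axis_u and axis_v must be orthogonal")
        if self.half_w <= 0 or self.half_h <= 0:
            raise ValueError("half extents must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axis_u, self.axis_v)


@dataclass(frozen=True)
class AOITrajectory:
    """A static or moving AOI described by pose keyframes.

    ``kind='static'`` requires exactly one keyframe whose pose holds for
    all time; ``kind='dynamic'`` requires >= 1 keyframes with strictly
    increasing times, between which pose is interpolated.
    """

    aoi_id: str
    keyframes: tuple[AOIPose, ...]
    kind: Literal["static", "dynamic"]

    def __post_init__(self):
        object.__setattr__(self, "keyframes", tuple(self.keyframes))
        if len(self.keyframes) < 1:
            raise ValueError(f"AOI {self.aoi_id!r}: needs at least one keyframe")
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"AOI {self.aoi_id!r}: kind must be static or dynamic")
        if self.kind == "static" and len(self.keyframes) != 1:
            raise ValueError(f"AOI {self.aoi_id!r}: static AOI must have exactly 1 keyframe")
        times = [k.t for k in self.keyframes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"AOI {self.aoi_id!r}: keyframe times must be strictly increasing")


@dataclass(frozen=True)
class StimulusWindow:
    """The analysis interval of one stimulus and the AOI it is scored against."""

    stimulus_id: str
    aoi_id: str
    t_start: float
    t_end: float

    def __post_init__(self):
        if not (self.t_end > self.t_start):
            raise ValueError(f"stimulus {self.stimulus_id!r}: t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FixationScore:
    """Scoring result for one stimulus.

    ``toff`` is the absolute time of first AOI entry (NaN when gaze never
    entered the AOI); ``tfd`` is the summed duration of all retained
    inside-AOI intervals.  A stimulus rejected by the dropout QC carries
    ``qc='rejected_dropout'`` and no metrics (toff NaN, tfd NaN, no
    intervals).
    """

    stimulus_id: str
    intervals: tuple[tuple[float, float], ...]
    toff: float
    tfd: float
    qc: Literal["accepted", "rejected_dropout"]
    t_start: float = float("nan")
    t_end: float = float("nan")

    def __post_init__(self):
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if self.qc not in ("accepted", "rejected_dropout"):
            raise ValueError("qc must be 'accepted' or 'rejected_dropout'")
        for (a, b) in ivs:
            if not b > a:
                raise ValueError("each interval must have t_exit > t_enter")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("intervals must be ordered and disjoint")
        if self.qc == "accepted":
            total = sum(b - a for a, b in ivs)
            if abs(total - self.tfd) > 1e-9:
                raise ValueError("tfd inconsistent with intervals")
            if ivs:
                if abs(self.toff - ivs[0][0]) > 1e-12:
                    raise ValueError("toff must equal first interval start")
            elif not _is_absent(self.toff):
                raise ValueError("toff must be absent when no intervals")
            if math.isfinite(self.t_start) and math.isfinite(self.t_end):
                span = self.t_end - self.t_start
                if self.tfd < -1e-12 or self.tfd > span + 1e-9:
                    raise ValueError("tfd outside [0, window duration]")
                for (a, b) in ivs:
                    if a < self.t_start - 1e-9 or b > self.t_end + 1e-9:
                        raise ValueError("interval outside the stimulus window")

    @property
    def has_fixation(self) -> bool:
        return len(self.intervals) > 0

    @property
    def toff_relative(self) -> float:
        """First-entry time relative to window start (NaN when absent)."""
        if _is_absent(self.toff) or not math.isfinite(self.t_start):
            return ABSENT
        return self.toff - self.t_start


@dataclass
class RaterTable:
    """A stimuli-by-raters matrix of one metric, input to agreement stats.

    Cells may be NaN (rejected stimulus, never-fixated TOFF, missing
    annotation).  Agreement statistics use listwise deletion: a stimulus
    row enters the computation only if every rater scored it.
    """

    metric: Literal["TOFF", "TFD"]
    values: np.ndarray
    rater_ids: list[str]
    stimulus_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (stimuli x raters)")
        n, k = self.values.shape
        if len(self.stimulus_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lists must match matrix shape")

    def complete_rows(self) -> np.ndarray:
        """Rows with no missing cell, as an (m, k) array."""
        mask = np.all(np.isfinite(self.values), axis=1)
        return self.values[mask]

    @property
    def n_complete(self) -> int:
        return int(np.all(np.isfinite(self.values), axis=1).sum())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gaze_csv(path: str | Path, rate_hz: float) -> GazeTrace:
    """Read a gaze trace from CSV with header ``t,x,y,z,valid``.

    Rows with ``valid=0`` are retained with the valid flag set false.
    Non-monotone timestamps raise ``ValueError`` naming the first
    offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    required = ["t", "x", "y", "z", "valid"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(bad[0]) + 2  # +1 for 0-based, +1 for the header line offset
            raise ValueError(f"{path}: non-monotone timestamp at data row {row}")
    p = df[["x", "y", "z"]].to_numpy(dtype=float)
    valid = df["valid"].to_numpy().astype(bool)
    return GazeTrace(t=t, p=p, valid=valid, rate_hz=rate_hz)


def write_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    """Write a gaze trace as ``t,x,y,z,valid`` CSV (full float precision)."""
    df = pd.DataFrame(
        {
            "t": trace.t,
            "x": trace.p[:, 0],
            "y": trace.p[:, 1],
            "z": trace.p[:, 2],
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def _pose_from_dict(d: dict) -> AOIPose:
    return AOIPose(
        t=float(d["t"]),
        center=np.asarray(d["center"], dtype=float),
        axis_u=np.asarray(d["axis_u"], dtype=float),
        axis_v=np.asarray(d["axis_v"], dtype=float),
        half_w=float(d["half_w"]),
        half_h=float(d["half_h"]),
    )


def read_aoi_json(path: str | Path) -> tuple[list[AOITrajectory], list[StimulusWindow]]:
    """Read AOI trajectories and stimulus windows from one JSON document.

    Schema::

        {"aois":    [{"id", "kind", "keyframes": [{"t", "center", "axis_u",
                                                   "axis_v", "half_w", "half_h"}]}],
         "windows": [{"stimulus_id", "aoi_id", "t_start", "t_end"}]}

    Every type invariant is checked on load; a window referencing an
    unknown AOI is a hard error.
    """
    with open(path) as fh:
        doc = json.load(fh)
    trajectories = []
    for entry in doc.get("aois", []):
        trajectories.append(
            AOITrajectory(
                aoi_id=str(entry["id"]),
                keyframes=tuple(_pose_from_dict(k) for k in entry["keyframes"]),
                kind=entry["kind"],
            )
        )
    known = {tr.aoi_id for tr in trajectories}
    windows = []
    for entry in doc.get("windows", []):
        w = StimulusWindow(
            stimulus_id=str(entry["stimulus_id"]),
            aoi_id=str(entry["aoi_id"]),
            t_start=float(entry["t_start"]),
            t_end=float(entry["t_end"]),
        )
        if w.aoi_id not in known:
            raise ValueError(
                f"{path}: window {w.stimulus_id!r} references unknown AOI {w.aoi_id!r}"
            )
        windows.append(w)
    return trajectories, windows


def write_aoi_json(
    trajectories: Iterable[AOITrajectory],
    windows: Iterable[StimulusWindow],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write AOIs and windows in the schema ``read_aoi_json`` expects."""
    doc = {
        "aois": [
            {
                "id": tr.aoi_id,
                "kind": tr.kind,
                "keyframes": [
                    {
                        "t": k.t,
                        "center": k.center.tolist(),
                        "axis_u": k.axis_u.tolist(),
                        "axis_v": k.axis_v.tolist(),
                        "half_w": k.half_w,
                        "half_h": k.half_h,
                    }
                    for k in tr.keyframes
                ],
            }
            for tr in trajectories
        ],
        "windows": [
            {
                "stimulus_id": w.stimulus_id,
                "aoi_id": w.aoi_id,
                "t_start": w.t_start,
                "t_end": w.t_end,
            }
            for w in windows
        ],
    }
    if metadata:
        doc["metadata"] = metadata
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_scores_csv(scores: Sequence[FixationScore], path: str | Path) -> None:
    """Write one row per stimulus with millisecond time precision.

    Columns: ``stimulus_id,qc,toff,toff_relative,tfd,n_intervals``.
    Absent TOFF (and all metrics of a QC-rejected stimulus) are written as
    empty fields, never as 0.
    """

    def fmt(x: float) -> str:
        return "" if _is_absent(x) else f"{x:.3f}"

    rows = []
    for s in scores:
        rejected = s.qc != "accepted"
        rows.append(
            {
                "stimulus_id": s.stimulus_id,
                "qc": s.qc,
                "toff": "" if rejected else fmt(s.toff),
                "toff_relative": "" if rejected else fmt(s.toff_relative),
                "tfd": "" if rejected else fmt(s.tfd),
                "n_intervals": "" if rejected else len(s.intervals),
            }
        )
    pd.DataFrame(
        rows, columns=["stimulus_id", "qc", "toff", "toff_relative", "tfd", "n_intervals"]
    ).to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    """Read a scores CSV back as a DataFrame (empty metric fields -> NaN)."""
    return pd.read_csv(path, dtype={"stimulus_id": str})


def read_annotations_csv(path: str | Path) -> pd.DataFrame:
    """Read a manual-rater annotation table.

    Expected columns: ``stimulus_id,rater_id,toff,tfd`` — one row per
    (stimulus, rater); empty metric cells mean the rater recorded no
    fixation / could not score that stimulus.
    """
    df = pd.read_csv(path, dtype={"stimulus_id": str, "rater_id": str})
    required = ["stimulus_id", "rater_id", "toff", "tfd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def write_annotations_csv(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False, float_format="%.3f")
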