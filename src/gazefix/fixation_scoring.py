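"""Fixation metrics from the binary scoring vector.

The scorer turns the per-sample in/out vector into enter/exit intervals,
debounces them (inside and outside intervals shorter than ``min_interval``
— 100 ms by default — are removed), and reduces the surviving intervals to
the two temporal metrics:

TOFF — time of first fixation, the absolute time gaze first enters the AOI;
TFD  — total fixation duration, the summed length of all inside intervals.

Pruning runs in two passes.  By default short *gaps* between fixations are
merged first and short *fixations* deleted second (``gaps_first``), so two
brief AOI touches separated by a flicker-length gap survive as one
fixation, the way a human scorer treats continuous dwell.  The opposite
order is available as ``intervals_first``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import preprocess
from .aoi_geometry import HitParams, score_vector
from .gaze_model import ABSENT, AOITrajectory, FixationScore, GazeTrace, StimulusWindow
from .preprocess import PreprocessConfig

__all__ = [
    "ScoringConfig",
    "intervals_from_scores",
    "prune_intervals",
    "compute_toff",
    "compute_tfd",
    "score_stimulus",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class ScoringConfig:
    """Debouncing parameters.

    min_interval
        Minimum duration, seconds, below which inside and outside
        intervals are removed (default 0.100).  Zero disables pruning.
    prune_order
        ``gaps_first`` (default) merges sub-threshold gaps before deleting
        sub-threshold fixations; ``intervals_first`` does the reverse.
    """

    min_interval: float = 0.100
    prune_order: Literal["gaps_first", "intervals_first"] = "gaps_first"

    def __post_init__(self):
        if self.min_interval < 0:
            raise ValueError("min_interval must be >= 0")
        if self.prune_order not in ("gaps_first", "intervals_first"):
            raise ValueError("prune_order must be 'gaps_first' or 'intervals_first'")


def intervals_from_scores(
    scores: Sequence[int] | np.ndarray, times: Sequence[float] | np.ndarray
) -> list[Interval]:
    """Maximal runs of 1s as (t_enter, t_exit) intervals.

    t_enter is the timestamp of the run's first sample.  t_exit is the
    timestamp of the first sample *after* the run; when the run reaches the
    end of the trace, the exit is the last timestamp plus one median sample
    period (the dwell is still ongoing at the final sample).
    """
    s = np.asarray(scores)
    t = np.asarray(times, dtype=float)
    if s.shape != t.shape:
        raise ValueError(f"scores ({s.shape}) and times ({t.shape}) lengths differ")
    n = s.size
    if n == 0:
        return []
    period = float(np.median(np.diff(t))) if n > 1 else 0.0
    padded = np.concatenate(([0], (s != 0).astype(int), [0]))
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # index of first sample after the run
    out: list[Interval] = []
    for i, j in zip(starts, ends):
        t_enter = float(t[i])
        t_exit = float(t[j]) if j < n else float(t[-1]) + period
        out.append((t_enter, t_exit))
    return out


def prune_intervals(
    intervals: Sequence[Interval],
    window: StimulusWindow | None = None,
    cfg: ScoringConfig = ScoringConfig(),
) -> list[Interval]:
    """Remove inside/outside intervals shorter than ``cfg.min_interval``.

    Two passes.  Gap pass: every gap between *consecutive* fixations
    shorter than the threshold is closed by merging its neighbours (the
    lead-in before the first fixation and the tail after the last are not
    gaps between fixations and are never merged away).  Interval pass:
    any fixation still shorter than the threshold is deleted.  The passes
    run in the order selected by ``cfg.prune_order`` and repeat until
    neither applies, so the output is a fixpoint: every fixation and every
    internal gap is >= the threshold.
    """
    m = cfg.min_interval
    ivs = [(float(a), float(b)) for a, b in intervals]
    for (a, b) in ivs:
        if not b > a:
            raise ValueError("intervals must have t_exit > t_enter")
    for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError("intervals must be ordered and disjoint")
    if m == 0:
        return ivs

    def merge_gaps(xs: list[Interval]) -> list[Interval]:
        out: list[Interval] = []
        for iv in xs:
            if out and iv[0] - out[-1][1] < m:
                out[-1] = (out[-1][0], iv[1])
            else:
                out.append(iv)
        return out

    def drop_short(xs: list[Interval]) -> list[Interval]:
        return [iv for iv in xs if iv[1] - iv[0] >= m]

    passes = (merge_gaps, drop_short) if cfg.prune_order == "gaps_first" else (
        drop_short,
        merge_gaps,
    )
    while True:
        new = ivs
        for p in passes:
            new = p(new)
        if new == ivs:
            return ivs
        ivs = new


def compute_toff(intervals: Sequence[Interval]) -> float:
    """Absolute time of first AOI entry; NaN (absent) when no fixation."""
    return float(intervals[0][0]) if intervals else ABSENT


def compute_tfd(intervals: Sequence[Interval]) -> float:
    """Summed duration of all inside-AOI intervals (0 for none)."""
    return float(sum(b - a for a, b in intervals))


def score_stimulus(
    trace: GazeTrace,
    traj: AOITrajectory,
    window: StimulusWindow,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    hit_cfg: HitParams = HitParams(),
    score_cfg: ScoringConfig = ScoringConfig(),
) -> FixationScore:
    """Run the full pipeline for one stimulus.

    downsample -> dropout QC -> median filter -> trim -> score vector ->
    intervals -> prune -> TOFF/TFD.  A stimulus whose window contains a
    tracking loss longer than ``pre_cfg.dropout_max`` is returned with
    ``qc='rejected_dropout'`` and no metrics.  Deterministic: identical
    inputs give identical scores.
    """
    ds = preprocess.downsample(trace, pre_cfg.target_rate_hz)
    # restrict to the window plus a margin wide enough that the median
    # filter sees the same neighbourhood it would on the full trace
    margin = max(1.0, 2.0 * pre_cfg.median_order / pre_cfg.target_rate_hz)
    near = (ds.t >= window.t_start - margin) & (ds.t <= window.t_end + margin)
    ds = GazeTrace(t=ds.t[near], p=ds.p[near], valid=ds.valid[near], rate_hz=ds.rate_hz)
    _, qc = preprocess.detect_dropouts(ds, window, pre_cfg.dropout_max)
    if qc == "rejected_dropout":
        return FixationScore(
            stimulus_id=window.stimulus_id,
            intervals=(),
            toff=ABSENT,
            tfd=ABSENT,
            qc="rejected_dropout",
            t_start=window.t_start,
            t_end=window.t_end,
        )
    filt = preprocess.median_filter(ds, pre_cfg.median_order)
    trimmed = preprocess.trim_to_window(filt, window)
    scores = score_vector(trimmed, traj, window, hit_cfg)
    raw = intervals_from_scores(scores, trimmed.t)
    # an end-of-trace exit may overshoot t_end by one sample period
    raw = [(a, min(b, window.t_end)) for a, b in raw if min(b, window.t_end) > a]
    pruned = prune_intervals(raw, window, score_cfg)
    return FixationScore(
        stimulus_id=window.stimulus_id,
        intervals=tuple(pruned),
        toff=compute_toff(pruned),
        tfd=compute_tfd(pruned),
        qc="accepted",
        t_start=window.t_start,
        t_end=window.t_end,
    )
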