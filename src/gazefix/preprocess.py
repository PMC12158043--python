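"""Signal conditioning ahead of AOI scoring.

The pipeline stages, in the order the scorer applies them:

1. decimate the raw trace to the analysis rate (200 Hz -> 50 Hz by default),
2. dropout QC — reject a stimulus whose window contains a tracking loss
   longer than ``dropout_max`` (100 ms by default),
3. median-filter each coordinate to suppress high-frequency, low-amplitude
   tremor,
4. trim the trace to the stimulus window.

Decimation is pure sample selection (no anti-alias filter): smoothing is
applied after decimation by the median filter, and position traces are not
band-limited signals where aliasing of tremor noise would matter at the
scale of 100 ms fixation intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_model import GazeTrace, StimulusWindow

__all__ = [
    "PreprocessConfig",
    "DropoutReport",
    "downsample",
    "detect_dropouts",
    "median_filter",
    "trim_to_window",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for the conditioning stages.

    target_rate_hz
        Analysis rate; must divide the source rate exactly (default 50).
    median_order
        Sliding-window length of the median filter in samples (default 10).
    dropout_max
        Longest tolerated tracking loss inside a window, seconds
        (default 0.100).
    """

    target_rate_hz: float = 50.0
    median_order: int = 10
    dropout_max: float = 0.100

    def __post_init__(self):
        if self.target_rate_hz <= 0:
            raise ValueError("target_rate_hz must be positive")
        if self.median_order < 1:
            raise ValueError("median_order must be >= 1")
        if self.dropout_max <= 0:
            raise ValueError("dropout_max must be positive")


@dataclass(frozen=True)
class DropoutReport:
    """Tracking-loss gaps found within a stimulus window."""

    gaps: tuple[tuple[float, float], ...]
    longest_gap: float

    def __post_init__(self):
        object.__setattr__(self, "gaps", tuple((float(a), float(b)) for a, b in self.gaps))
        for (_, b0), (a1, _) in zip(self.gaps, self.gaps[1:]):
            if a1 < b0:
                raise ValueError("gaps must be ordered and disjoint")


def downsample(trace: GazeTrace, target_rate_hz: float) -> GazeTrace:
    """Decimate by keeping every (source/target)-th sample, starting at the first.

    The source rate must be an integer multiple of the target rate.
    Timestamps are carried over from the kept samples; a kept sample is
    valid only if it was valid in the source.
    """
    ratio = trace.rate_hz / target_rate_hz
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        raise ValueError(
            f"source rate {trace.rate_hz} Hz is not an integer multiple of "
            f"target rate {target_rate_hz} Hz"
        )
    if step == 1:
        return GazeTrace(t=trace.t, p=trace.p, valid=trace.valid, rate_hz=target_rate_hz)
    sel = slice(0, None, step)
    return GazeTrace(
        t=trace.t[sel], p=trace.p[sel], valid=trace.valid[sel], rate_hz=target_rate_hz
    )


def detect_dropouts(
    trace: GazeTrace, window: StimulusWindow, dropout_max: float = 0.100
) -> tuple[DropoutReport, str]:
    """Find tracking-loss gaps within ``window`` and decide the QC flag.

    A gap is a maximal run of invalid samples, or an inter-sample spacing
    wider than 2/rate (missing rows), clipped to the window.  The stimulus
    is ``rejected_dropout`` iff the longest gap exceeds ``dropout_max``.

    A run of k invalid samples at rate r counts as k/r seconds of lost
    tracking (its span from the first invalid timestamp to the next valid
    one); missing rows count as the unsampled stretch they leave.
    """
    t, valid = trace.t, trace.valid
    period = 1.0 / trace.rate_hz
    in_win = (t >= window.t_start - period) & (t <= window.t_end + period)
    idx = np.nonzero(in_win)[0]
    gaps: list[tuple[float, float]] = []

    if idx.size == 0:
        # no samples at all near the window: the whole window is one gap
        gaps.append((window.t_start, window.t_end))
    else:
        tw, vw = t[idx], valid[idx]
        # sampling gaps (missing rows)
        if tw.size > 1:
            dt = np.diff(tw)
            for i in np.nonzero(dt > 2.0 * period)[0]:
                gaps.append((float(tw[i]) + period, float(tw[i + 1])))
        # leading/trailing coverage gaps relative to the window
        if tw[0] > window.t_start + 2.0 * period:
            gaps.append((window.t_start, float(tw[0])))
        if tw[-1] < window.t_end - 2.0 * period:
            gaps.append((float(tw[-1]), window.t_end))
        # runs of valid == False; a run of k samples counts as k/rate of
        # lost tracking (from its first invalid timestamp to the next
        # valid one)
        i = 0
        n = tw.size
        while i < n:
            if not vw[i]:
                j = i
                while j + 1 < n and not vw[j + 1]:
                    j += 1
                a = float(tw[i])
                b = float(tw[j + 1]) if j + 1 < n else window.t_end
                gaps.append((a, b))
                i = j + 1
            else:
                i += 1

    # clip to window, drop empties, merge overlaps
    clipped = []
    for a, b in gaps:
        a, b = max(a, window.t_start), min(b, window.t_end)
        if b > a:
            clipped.append((a, b))
    clipped.sort()
    merged: list[list[float]] = []
    for a, b in clipped:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    gaps_t = tuple((a, b) for a, b in merged)
    longest = max((b - a for a, b in gaps_t), default=0.0)
    report = DropoutReport(gaps=gaps_t, longest_gap=longest)
    # 1 ns guard so a gap of exactly dropout_max is not rejected by float
    # rounding in the time subtraction
    qc = "rejected_dropout" if longest > dropout_max + 1e-9 else "accepted"
    return report, qc


def _running_median(x: np.ndarray, order: int) -> np.ndarray:
    """Sliding median with window length ``order``.

    The window at index i spans ``[i - order//2, i + (order-1)//2]`` — for
    even order the window is past-biased, the convention of the MATLAB-style
    1-D median filter.  Even order: the median is the mean of the two middle
    order statistics.  Edges use shrinking windows (no padding), so the
    filter never injects values from outside the observed range.
    """
    n = x.size
    if order <= 1 or n == 0:
        return x.copy()
    half_lo = order // 2
    half_hi = (order - 1) // 2
    out = np.empty_like(x, dtype=float)
    interior_lo = half_lo
    interior_hi = n - half_hi  # first index whose window would overrun
    if interior_hi > interior_lo:
        sw = np.lib.stride_tricks.sliding_window_view(x, order)
        out[interior_lo:interior_hi] = np.median(sw, axis=1)
    for i in list(range(min(interior_lo, n))) + list(range(max(interior_hi, interior_lo, 0), n)):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        out[i] = np.median(x[lo:hi])
    return out


def median_filter(trace: GazeTrace, order: int = 10) -> GazeTrace:
    """Apply a 1-D running median of length ``order`` to each coordinate.

    Timestamps and validity flags are untouched.  Order 1 is the identity.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    p = np.column_stack([_running_median(trace.p[:, j], order) for j in range(3)])
    return GazeTrace(t=trace.t, p=p, valid=trace.valid, rate_hz=trace.rate_hz)


def trim_to_window(trace: GazeTrace, window: StimulusWindow) -> GazeTrace:
    """Keep samples with ``t_start <= t < t_end`` (half-open)."""
    mask = (trace.t >= window.t_start) & (trace.t < window.t_end)
    return GazeTrace(
        t=trace.t[mask], p=trace.p[mask], valid=trace.valid[mask], rate_hz=trace.rate_hz
    )
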