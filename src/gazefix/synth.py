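"""Synthetic VR eye-tracking sessions with known ground truth.

Emulates the study design the scorer was built for: 36 stimuli per
session — 18 static billboards shown for 10 s, and 18 "bus billboards"
that approach linearly for 30 s, stand at a bus stop for 8 s, then depart;
the dynamic analysis window opens 2 s before the bus stops and lasts 10 s.
Gaze is sampled at 200 Hz from a per-stimulus fixation schedule that
alternates on-AOI dwell with off-AOI gaze, plus isotropic Gaussian noise
and blink dropouts (runs of invalid samples).

Billboard world sizes are chosen so the angular extents at the nominal
viewing distance match the study's stimuli (static 20° x 16°; bus billboard
12.5° x 22.5° while stationary).  The generator records its ground-truth
schedule per stimulus, so scoring accuracy can be measured without any
recorded data, and can simulate manual raters as noisy observers of the
true enter/exit times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixation_scoring import ScoringConfig, compute_tfd, compute_toff, prune_intervals
from .gaze_model import (
    AOIPose,
    AOITrajectory,
    GazeTrace,
    StimulusWindow,
)

__all__ = ["SessionConfig", "GroundTruth", "Session", "generate_session", "simulate_raters"]

#: Nominal viewing distance from the participant to a billboard (world units,
#: 1 unit = 1 m).  Angular sizes below are converted to world extents at
#: this distance.
VIEW_DISTANCE = 10.0

STATIC_ANG_W, STATIC_ANG_H = 20.0, 16.0  # degrees
BUS_ANG_W, BUS_ANG_H = 12.5, 22.5  # degrees, mid-range of the stationary bus


def _angular_to_half_extent(deg: float, dist: float) -> float:
    return dist * math.tan(math.radians(deg) / 2.0)


@dataclass(frozen=True)
class SessionConfig:
    """Study-design parameters of a simulated session.

    Defaults reproduce the acquisition and stimulus timing of the study
    the scorer targets: 18 static + 18 dynamic stimuli, 10 s analysis
    windows, 200 Hz eye tracker, a 30 s bus approach with an 8 s stop and
    the window opening 2 s before the stop.  ``noise_sd`` is the isotropic
    gaze noise in world units (0.1 m at a 10 m viewing distance is roughly
    0.6° of visual angle, a typical VR eye-tracker accuracy); blinks occur
    at ``blink_rate`` per minute and last uniformly within ``blink_dur``.
    """

    n_static: int = 18
    n_dynamic: int = 18
    window_s: float = 10.0
    rate_hz: float = 200.0
    noise_sd: float = 0.1
    blink_rate: float = 4.0
    blink_dur: tuple[float, float] = (0.05, 0.08)
    bus_approach_s: float = 30.0
    bus_stop_s: float = 8.0
    pre_stop_s: float = 2.0
    gap_s: float = 2.0
    dwell_range_s: tuple[float, float] = (1.0, 2.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_static < 0 or self.n_dynamic < 0:
            raise ValueError("stimulus counts must be >= 0")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not self.pre_stop_s < self.window_s:
            raise ValueError("pre_stop_s must be shorter than the window")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Intended fixation schedule of one stimulus."""

    stimulus_id: str
    intervals: tuple[tuple[float, float], ...]
    toff: float
    tfd: float


@dataclass
class Session:
    """Everything a simulated session produces."""

    trace: GazeTrace
    trajectories: list[AOITrajectory]
    windows: list[StimulusWindow]
    truth: list[GroundTruth]
    config: SessionConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": [g.stimulus_id for g in self.truth],
                "toff": [g.toff for g in self.truth],
                "tfd": [g.tfd for g in self.truth],
                "n_intervals": [len(g.intervals) for g in self.truth],
            }
        )


#: Schedule quantum: the 50 Hz analysis-grid period, seconds.  Dwell
#: boundaries are drawn on this grid so the decimated trace represents the
#: schedule exactly.
GRID = 0.02

#: Off-AOI gaze positions, in units of the AOI half-width along axis_u.
#: Before landing on the AOI, gaze hovers just outside its edge (parafoveal
#: approach); after leaving, it departs to a distant scene point.
HOVER_OFFSET = 1.5
FAR_OFFSET = -4.0

_MIN_GAP_TICKS = 15  # 0.3 s: minimum off-AOI stretch between dwells
_HOVER_TICKS = 8  # tail of each pre-dwell gap spent hovering near the AOI


def _fixation_schedule(
    rng: np.random.Generator, t0: float, t1: float, min_dwell: float = 1.0, max_dwell: float = 2.8
) -> list[tuple[float, float]]:
    """Draw 1–3 on-AOI dwell intervals covering part of [t0, t1).

    Dwell durations are uniform on [min_dwell, max_dwell]; dwells are
    separated (and preceded) by off-AOI stretches of at least 0.3 s, and
    the stretch after the last dwell is either empty or at least 0.3 s.
    All boundaries land on the 50 Hz analysis grid so the sampled trace
    carries the schedule without quantization error.
    """
    total = int(round((t1 - t0) / GRID))
    k = int(rng.integers(1, 4))
    dur = [int(round(float(rng.uniform(min_dwell, max_dwell)) / GRID)) for _ in range(k)]
    slack = total - sum(dur) - _MIN_GAP_TICKS * k
    if slack < 0:  # window too short for k dwells: fall back to one
        k, dur = 1, [min(dur[0], total - _MIN_GAP_TICKS)]
        slack = total - dur[0] - _MIN_GAP_TICKS
    # distribute the slack over the k gaps (before each dwell) and the tail
    parts = rng.multinomial(slack, np.ones(k + 1) / (k + 1))
    if 0 < parts[-1] < _MIN_GAP_TICKS:  # tail must be empty or >= 0.3 s
        parts[0] += parts[-1]
        parts[-1] = 0
    out = []
    tick = 0
    for i in range(k):
        tick += _MIN_GAP_TICKS + int(parts[i])
        a = tick
        tick += dur[i]
        out.append((round(t0 + a * GRID, 9), round(t0 + tick * GRID, 9)))
    return out


def _make_static_aoi(
    rng: np.random.Generator, aoi_id: str
) -> AOITrajectory:
    # billboards scattered around the scene at the nominal viewing distance
    az = float(rng.uniform(-60, 60))
    center = np.array(
        [VIEW_DISTANCE * math.sin(math.radians(az)),
         float(rng.uniform(1.0, 3.0)),
         VIEW_DISTANCE * math.cos(math.radians(az))]
    )
    u = np.array([math.cos(math.radians(az)), 0.0, -math.sin(math.radians(az))])
    v = np.array([0.0, 1.0, 0.0])
    pose = AOIPose(
        t=0.0,
        center=center,
        axis_u=u,
        axis_v=v,
        half_w=_angular_to_half_extent(STATIC_ANG_W, VIEW_DISTANCE),
        half_h=_angular_to_half_extent(STATIC_ANG_H, VIEW_DISTANCE),
    )
    return AOITrajectory(aoi_id=aoi_id, keyframes=(pose,), kind="static")


def _make_bus_aoi(
    cfg: SessionConfig, aoi_id: str, t_appear: float
) -> tuple[AOITrajectory, float]:
    """Bus billboard: linear approach, stop, linear departure.

    Returns the trajectory and the stop time (start of the stationary
    phase).  The AOI's world size is constant; its angular size grows as
    it approaches, as in the real scene.
    """
    half_w = _angular_to_half_extent(BUS_ANG_W, VIEW_DISTANCE)
    half_h = _angular_to_half_extent(BUS_ANG_H, VIEW_DISTANCE)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    far = np.array([-80.0, 2.0, VIEW_DISTANCE])
    stop = np.array([0.0, 2.0, VIEW_DISTANCE])
    gone = np.array([80.0, 2.0, VIEW_DISTANCE])
    t_stop = t_appear + cfg.bus_approach_s
    t_depart = t_stop + cfg.bus_stop_s
    t_gone = t_depart + cfg.bus_approach_s

    def pose(t: float, c: np.ndarray) -> AOIPose:
        return AOIPose(t=t, center=c, axis_u=u, axis_v=v, half_w=half_w, half_h=half_h)

    traj = AOITrajectory(
        aoi_id=aoi_id,
        keyframes=(
            pose(t_appear, far),
            pose(t_stop, stop),
            pose(t_depart, stop),
            pose(t_gone, gone),
        ),
        kind="dynamic",
    )
    return traj, t_stop


def generate_session(cfg: SessionConfig) -> Session:
    """Build one fully seeded session: trace + AOIs + windows + ground truth.

    Static stimuli are laid out first, then dynamic ones; stimuli are
    separated by ``gap_s`` of free viewing.  During each stimulus window
    the scheduled gaze target alternates between the AOI center (on
    segments) and a point well outside the AOI (off segments); between
    windows gaze wanders off-AOI.  Gaussian noise of ``noise_sd`` world
    units is added to every sample and blinks are inserted as runs of
    invalid samples at ``blink_rate`` per minute.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.rate_hz

    trajectories: list[AOITrajectory] = []
    windows: list[StimulusWindow] = []
    truths: list[GroundTruth] = []
    # (window, on-intervals, AOI center sampler) per stimulus
    plan: list[tuple[StimulusWindow, list[tuple[float, float]], AOITrajectory]] = []

    t_cursor = cfg.gap_s
    for i in range(cfg.n_static):
        sid, aid = f"static_{i:02d}", f"aoi_static_{i:02d}"
        traj = _make_static_aoi(rng, aid)
        w = StimulusWindow(stimulus_id=sid, aoi_id=aid, t_start=t_cursor, t_end=t_cursor + cfg.window_s)
        trajectories.append(traj)
        windows.append(w)
        plan.append((w, _fixation_schedule(rng, w.t_start, w.t_end, *cfg.dwell_range_s), traj))
        t_cursor = w.t_end + cfg.gap_s

    for i in range(cfg.n_dynamic):
        sid, aid = f"bus_{i:02d}", f"aoi_bus_{i:02d}"
        traj, t_stop = _make_bus_aoi(cfg, aid, t_cursor)
        w_start = t_stop - cfg.pre_stop_s
        w = StimulusWindow(stimulus_id=sid, aoi_id=aid, t_start=w_start, t_end=w_start + cfg.window_s)
        trajectories.append(traj)
        windows.append(w)
        plan.append((w, _fixation_schedule(rng, w.t_start, w.t_end, *cfg.dwell_range_s), traj))
        t_cursor = traj.keyframes[-1].t + cfg.gap_s

    t_total = t_cursor
    n = int(round(t_total / dt))
    # timestamps rounded to exact decimals so the decimated 50 Hz grid
    # carries the schedule boundaries without representation error
    t = np.round(np.arange(n) * dt, 9)
    # between stimuli gaze wanders along a path far from every billboard
    p = np.column_stack(
        [5.0 * np.sin(0.1 * t), -30.0 + 0.5 * np.cos(0.07 * t), -5.0 * np.ones(n)]
    )

    from .aoi_geometry import pose_at  # local import to avoid cycle at module load

    hover_s = _HOVER_TICKS * GRID
    for w, on_ivs, traj in plan:
        # label every off-AOI stretch of the window: gaze departs to a
        # distant scene point after leaving the AOI and hovers just outside
        # its edge for the moments before landing on it
        segments: list[tuple[float, float, str]] = []
        prev = w.t_start
        for a, b in on_ivs:
            segments.append((prev, round(a - hover_s, 9), "far"))
            segments.append((round(a - hover_s, 9), a, "hover"))
            segments.append((a, b, "on"))
            prev = b
        segments.append((prev, w.t_end, "far"))

        idx = np.nonzero((t >= w.t_start) & (t < w.t_end))[0]
        for j in idx:
            tj = float(t[j])
            kind = next(kind for a, b, kind in segments if a <= tj < b)
            pose = pose_at(traj, tj)
            if kind == "on":
                target = pose.center
            elif kind == "hover":
                target = pose.center + pose.axis_u * (HOVER_OFFSET * pose.half_w)
            else:
                target = pose.center + pose.axis_u * (FAR_OFFSET * pose.half_w)
            if cfg.noise_sd > 0:
                nu, nv = rng.normal(0.0, cfg.noise_sd, size=2)
                # gaze points are scene-surface intersections, so estimation
                # noise displaces them within the AOI plane
                target = target + nu * pose.axis_u + nv * pose.axis_v
            p[j] = target

        ivs = tuple((a, b) for a, b in on_ivs)
        truths.append(
            GroundTruth(
                stimulus_id=w.stimulus_id,
                intervals=ivs,
                toff=compute_toff(list(ivs)),
                tfd=compute_tfd(list(ivs)),
            )
        )

    valid = np.ones(n, dtype=bool)
    if cfg.blink_rate > 0:
        n_blinks = rng.poisson(cfg.blink_rate * t_total / 60.0)
        for _ in range(n_blinks):
            start = float(rng.uniform(0, t_total))
            dur = float(rng.uniform(*cfg.blink_dur))
            valid[(t >= start) & (t < start + dur)] = False

    trace = GazeTrace(t=t, p=p, valid=valid, rate_hz=cfg.rate_hz)
    return Session(trace=trace, trajectories=trajectories, windows=windows, truth=truths, config=cfg)


def simulate_raters(
    truth: list[GroundTruth],
    jitter_sd: float,
    miss_prob: float,
    n_raters: int,
    seed: int,
    min_interval: float = 0.100,
) -> pd.DataFrame:
    """Simulate manual raters as noisy observers of the true enter/exit times.

    Each rater perturbs every true enter and exit time with independent
    N(0, jitter_sd^2) error, drops short intervals with probability
    ``miss_prob``, re-applies the 100 ms debouncing rules, and reports
    TOFF/TFD recomputed from the perturbed intervals.  Returns an
    annotation table with columns ``stimulus_id,rater_id,toff,tfd``.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not (0 <= miss_prob < 1):
        raise ValueError("miss_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cfg = ScoringConfig(min_interval=min_interval)
    rows = []
    for r in range(n_raters):
        rid = f"rater_{r + 1}"
        for gt in truth:
            ivs = []
            for (a, b) in gt.intervals:
                if miss_prob > 0 and (b - a) < 3 * min_interval and rng.random() < miss_prob:
                    continue
                ja = a + rng.normal(0, jitter_sd) if jitter_sd > 0 else a
                jb = b + rng.normal(0, jitter_sd) if jitter_sd > 0 else b
                if jb > ja:
                    ivs.append((ja, jb))
            ivs.sort()
            # enforce disjointness after jitter before re-pruning
            clean: list[tuple[float, float]] = []
            for a, b in ivs:
                if clean and a < clean[-1][1]:
                    clean[-1] = (clean[-1][0], max(clean[-1][1], b))
                else:
                    clean.append((a, b))
            pruned = prune_intervals(clean, None, cfg)
            rows.append(
                {
                    "stimulus_id": gt.stimulus_id,
                    "rater_id": rid,
                    "toff": compute_toff(pruned),
                    "tfd": compute_tfd(pruned),
                }
            )
    return pd.DataFrame(rows, columns=["stimulus_id", "rater_id", "toff", "tfd"])
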