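"""Time-resolved AOI pose evaluation and point-in-AOI hit testing.

Gaze is a world-space point (the acquisition stack exports a computed 3D
gaze position, not a ray), so the containment test is point-in-slab: a
point is inside the AOI when its offset from the rectangle center is within
``plane_tolerance`` along the plane normal and within the half-extents
along the two in-plane axes.  ``plane_tolerance`` absorbs the depth error
of the gaze estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_model import AOIPose, AOITrajectory, GazeTrace, StimulusWindow

__all__ = ["HitParams", "pose_at", "contains", "score_vector"]


@dataclass(frozen=True)
class HitParams:
    """Containment-test tunables.

    plane_tolerance
        Half-thickness of the slab around the AOI plane, world units
        (default 0.05).
    closed_bounds
        Whether a point exactly on the boundary counts as inside
        (default True).
    """

    plane_tolerance: float = 0.05
    closed_bounds: bool = True

    def __post_init__(self):
        if self.plane_tolerance < 0:
            raise ValueError("plane_tolerance must be >= 0")


def pose_at(traj: AOITrajectory, t: float) -> AOIPose:
    """Evaluate the AOI pose at time ``t``.

    Static AOIs return their sole pose for any ``t``.  Dynamic AOIs
    interpolate component-wise linearly (center and half-extents) between
    the bracketing keyframes; the in-plane axes are interpolated linearly
    and then re-orthonormalized by Gram–Schmidt with ``axis_u`` first.
    ``t`` outside the keyframe span of a dynamic AOI is a hard error.
    """
    if traj.kind == "static":
        return traj.keyframes[0]
    kfs = traj.keyframes
    if t < kfs[0].t or t > kfs[-1].t:
        raise ValueError(
            f"AOI {traj.aoi_id!r}: t={t} outside keyframe span "
            f"[{kfs[0].t}, {kfs[-1].t}]"
        )
    times = np.array([k.t for k in kfs])
    j = int(np.searchsorted(times, t, side="right"))
    if j == 0:
        return kfs[0]
    if j == len(kfs):
        return kfs[-1]
    a, b = kfs[j - 1], kfs[j]
    w = (t - a.t) / (b.t - a.t)
    u = (1 - w) * a.axis_u + w * b.axis_u
    v = (1 - w) * a.axis_v + w * b.axis_v
    u = u / np.linalg.norm(u)
    v = v - (v @ u) * u
    v = v / np.linalg.norm(v)
    return AOIPose(
        t=t,
        center=(1 - w) * a.center + w * b.center,
        axis_u=u,
        axis_v=v,
        half_w=(1 - w) * a.half_w + w * b.half_w,
        half_h=(1 - w) * a.half_h + w * b.half_h,
    )


def contains(pose: AOIPose, p: np.ndarray, params: HitParams = HitParams()) -> bool:
    """True when point ``p`` lies inside the AOI slab rectangle."""
    d = np.asarray(p, dtype=float) - pose.center
    dn = abs(float(d @ pose.normal))
    du = abs(float(d @ pose.axis_u))
    dv = abs(float(d @ pose.axis_v))
    if params.closed_bounds:
        return dn <= params.plane_tolerance and du <= pose.half_w and dv <= pose.half_h
    return dn < params.plane_tolerance and du < pose.half_w and dv < pose.half_h


def score_vector(
    trace: GazeTrace,
    traj: AOITrajectory,
    window: StimulusWindow,
    params: HitParams = HitParams(),
) -> np.ndarray:
    """Binary in/out score per sample of a window-trimmed trace.

    A sample scores 1 iff it is valid and its gaze point is inside the AOI
    at that sample's time; invalid samples score 0.
    """
    n = len(trace)
    scores = np.zeros(n, dtype=np.int8)
    for i in range(n):
        if trace.valid[i] and contains(pose_at(traj, float(trace.t[i])), trace.p[i], params):
            scores[i] = 1
    return scores
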