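"""The textbook TOFF/TFD example, scored by the full pipeline.

A static billboard's analysis window opens at 90.000 s.  Gaze enters the
AOI 0.5 s later and dwells three times (2, 1.5 and 3 s), so the time of
first fixation is 90.500 s and the total fixation duration 6.500 s.
"""

import numpy as np

from gazefix import AOIPose, AOITrajectory, GazeTrace, StimulusWindow, score_stimulus
from gazefix.synth import FAR_OFFSET, HOVER_OFFSET

pose = AOIPose(
    t=0.0,
    center=np.array([0.0, 2.0, 10.0]),
    axis_u=np.array([1.0, 0.0, 0.0]),
    axis_v=np.array([0.0, 1.0, 0.0]),
    half_w=1.763,  # 20 degrees wide at 10 m
    half_h=1.406,  # 16 degrees tall
)
aoi = AOITrajectory(aoi_id="board", keyframes=(pose,), kind="static")
window = StimulusWindow(stimulus_id="demo", aoi_id="board", t_start=90.0, t_end=100.0)

# render a 200 Hz gaze trace following the dwell schedule: near the AOI edge
# before each landing, on the center during dwells, far away between them
dwells = [(90.5, 92.5), (93.0, 94.5), (95.0, 98.0)]
t = np.round(89.0 + np.arange(int(12.0 * 200)) / 200.0, 9)
p = np.tile(pose.center + FAR_OFFSET * pose.half_w * pose.axis_u, (t.size, 1))
for a, b in dwells:
    p[(t >= a - 0.16) & (t < a)] = pose.center + HOVER_OFFSET * pose.half_w * pose.axis_u
    p[(t >= a) & (t < b)] = pose.center
trace = GazeTrace(t=t, p=p, valid=np.ones(t.size, bool), rate_hz=200.0)

score = score_stimulus(trace, aoi, window)
print(f"qc:   {score.qc}")
print(f"TOFF: {score.toff:.3f} s  (absolute; {score.toff_relative:.3f} s after onset)")
print(f"TFD:  {score.tfd:.3f} s over {len(score.intervals)} fixation intervals")
for i, (a, b) in enumerate(score.intervals, 1):
    print(f"  fixation {i}: {a:.3f} -> {b:.3f} s  ({b - a:.3f} s)")
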