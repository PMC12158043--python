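# Methods

## Problem and pipeline

`gazefix` automates a measurement that is otherwise done by human video
annotation: given a 3D gaze trace recorded in a VR headset and the pose of a
rectangular area of interest (AOI) in the scene — static, or moving like a
bus-mounted billboard — determine, per stimulus, the **time of first
fixation** (TOFF, the absolute time gaze first enters the AOI) and the
**total fixation duration** (TFD, the summed time gaze spends inside it)
within a fixed analysis window.

The scoring pipeline for one stimulus is:

1. **Decimation.** The raw trace (nominally 200 Hz) is reduced to the
   analysis rate (default 50 Hz) by keeping every *k*-th sample, *k* =
   source/target.  No anti-alias filter is applied: decimation by selection
   preserves the raw positions, and the median filter that follows supplies
   the smoothing; position traces are not interpreted spectrally anywhere in
   the pipeline.
2. **Dropout QC.** A stimulus whose window contains more than 100 ms of
   lost tracking is rejected outright and reported with missing metrics
   (never zeros).  A run of *k* invalid samples counts as *k*/rate seconds
   of loss; a hole in the timestamps counts as the unsampled stretch it
   leaves.  QC is assessed on the decimated trace, before filtering, so the
   filter never smooths across a disqualifying gap.
3. **Median filter.** Each coordinate is passed through a 10th-order
   (10-sample, i.e. 200 ms at 50 Hz) one-dimensional running median to
   remove sample-level spikes and high-frequency tremor.  For even orders
   the window is past-biased, `[i − n/2, i + n/2 − 1]`, and the median is
   the mean of the two middle order statistics — the conventions of the
   classic MATLAB-style `medfilt1`.  Edge windows shrink rather than
   zero-pad; zero padding would drag gaze positions toward the world origin.
4. **Window trim.** Samples with `t_start ≤ t < t_end` are kept
   (half-open, so abutting windows never share a sample).
5. **Binary scoring.** Each sample scores 1 iff it is valid and its gaze
   point lies inside the AOI at that instant.  The AOI test is
   point-in-slab: with the pose's in-plane axes *u*, *v* and normal *n*,
   a point at offset *d* from the center is inside iff |d·n| ≤
   `plane_tolerance` (default 0.05 world units), |d·u| ≤ half-width and
   |d·v| ≤ half-height.  Boundaries are closed by default.  Gaze is a world
   point, not a ray: the acquisition stack exports the computed 3D gaze
   position (the intersection of the gaze ray with scene geometry), so when
   the participant looks at the billboard the exported point lies on its
   plane and the slab tolerance only absorbs numeric depth error.
6. **Intervals.** Enter/exit times come from the differences of the binary
   scoring vector: a maximal run of ones becomes an interval from its first
   sample's timestamp to the timestamp of the first sample after the run
   (or last timestamp + one period if the run reaches the end of the trace,
   clipped to the window end).
7. **Debouncing.** Inside and outside intervals shorter than 100 ms are
   removed.  Two passes, by default gaps first: every sub-threshold gap
   between consecutive fixations is closed by merging its neighbours, then
   every fixation still shorter than the threshold is deleted, repeated to
   a fixpoint.  Merging first means two brief AOI touches separated by a
   flicker-length gap survive as one fixation — the way a human scorer
   treats continuous dwell.  The opposite order is available
   (`prune_order="intervals_first"`).  The lead-in before the first
   fixation and the tail after the last are not gaps between fixations and
   are never merged away.
8. **Metrics.** TOFF = the first interval's enter time (absolute seconds;
   a relative value is derived in the output CSV); TFD = the summed
   interval durations.  A stimulus whose gaze never enters the AOI has
   TFD = 0 and an explicitly absent TOFF (NaN / empty CSV field) — never 0,
   which would corrupt agreement statistics downstream.

### Dynamic AOIs

A moving AOI is a sequence of pose keyframes.  Pose at an arbitrary time
interpolates center and half-extents linearly between the bracketing
keyframes; the in-plane axes are interpolated linearly and re-orthonormalized
by Gram–Schmidt (u first).  The scorer is motion-model-agnostic: any motion
can be approximated by densifying keyframes.  Querying a dynamic AOI outside
its keyframe span is an error rather than an extrapolation.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `target_rate_hz` | 50 | Hz | analysis rate; must divide the source rate |
| `median_order` | 10 | samples | median filter window (200 ms at 50 Hz) |
| `dropout_max` | 0.100 | s | longest tolerated tracking loss per window |
| `min_interval` | 0.100 | s | debouncing threshold for dwells and gaps |
| `plane_tolerance` | 0.05 | world units | slab half-thickness of the AOI test |
| `closed_bounds` | true | — | point on the AOI edge counts as inside |

The temporal defaults (50 Hz, order 10, 100 ms, 100 ms) are the published
operating point of the pipeline this package implements; the containment
defaults are this package's own, since the containment test itself is not
specified anywhere upstream.

## Agreement statistics

Validation against human raters uses the intraclass correlation in its
two-way random-effects, absolute-agreement, single-measures form, ICC(2,1)
(= McGraw–Wong ICC(A,1)).  For an n×k table decomposed into row, column and
residual mean squares MSR, MSC, MSE:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

The 95% confidence interval is the exact F-based interval of McGraw & Wong
(1996) with the Satterthwaite denominator degrees of freedom — the same
formulas SPSS implements; the implementation is cross-checked in the test
suite against an explicit double-loop ANOVA oracle and against pingouin's
ICC(A,1).  Interpretation bands follow Koo & Li (2016): > 0.9 excellent,
[0.75, 0.9] good, [0.5, 0.75) moderate, < 0.5 poor.

Rater tables put the automatic scorer in the first column and each human
rater in one column.  Rows with any missing cell — a QC-rejected stimulus,
an absent TOFF, a missing annotation — are dropped listwise and the count is
logged; how human raters would score a never-fixated stimulus is undefined,
so imputing is deliberately avoided.  Per-rater Pearson correlations use
pairwise-complete rows (≥ 3 per pair, nonzero variance required).

Note that ICC on *absolute* TOFF over a long session is dominated by the
between-stimulus spread of onset times and is therefore optimistic compared
with ICC on window-relative TOFF; the output CSV carries both columns so
either analysis can be run.

## The synthetic-session generator

No recorded sessions are distributed, so the generator emulates the study
design the scorer targets and provides exact ground truth:

* **Stimuli.** 18 static billboards (20° × 16° of visual angle at the
  nominal 10 m viewing distance, i.e. ~3.5 × 2.8 m) shown for 10 s, and 18
  bus billboards (12.5° × 22.5°, the mid-range of the moving stimulus) that
  approach linearly for 30 s, stand 8 s at a bus stop, and depart; the
  dynamic analysis window opens 2 s before the stop and lasts 10 s.
  Stimuli are separated by 2 s of free viewing.
* **Fixation schedule.** Per window, 1–3 on-AOI dwells of 1.0–2.8 s
  (uniform), separated and preceded by off-AOI stretches of ≥ 0.3 s; the
  stretch after the last dwell is empty or ≥ 0.3 s.  All boundaries lie on
  the 50 Hz analysis grid (20 ms ticks, timestamps rounded to exact
  decimals), so the decimated trace represents the schedule without
  quantization error and the recorded ground truth is exact.
* **Gaze rendering.** 200 Hz.  During a dwell the gaze target is the AOI
  center (moving with it for dynamic AOIs).  Off-AOI gaze follows an
  approach/depart model: for the ~0.16 s before landing on the AOI, gaze
  hovers just outside its edge (1.5 half-widths from center — parafoveal
  approach); after leaving, it departs to a distant scene point (4
  half-widths on the opposite side); between stimuli it wanders far from
  every billboard.  Gaze-estimation noise (default SD 0.1 world units ≈
  0.57° at 10 m, a typical VR eye-tracker accuracy) is applied **in the AOI
  plane**: exported gaze points are scene-surface intersections, so angular
  error displaces them across the surface rather than isotropically in 3D.
  Blinks are inserted as runs of invalid samples (default 4/min,
  50–80 ms, i.e. below the dropout threshold).
* **Why recovery is exact.**  An even-order running median shifts a step
  edge: at each dwell boundary exactly one filter window straddles the edge
  5/5, and its output is the midpoint of the on- and off-levels.  Whether
  that midpoint lies inside the AOI decides a one-sample shift.  With the
  approach/depart geometry the pre-entry midpoint (center + 0.75
  half-widths) is inside and the post-exit midpoint (center − 2
  half-widths) is outside, so both the enter and the exit land on the true
  grid sample and the noiseless pipeline reproduces ground truth bit-for-bit.
  This is a property of the generator's gaze model, not of the scorer; with
  other off-AOI geometries the scorer is still accurate to one sample
  period per edge.
* **Simulated raters.** Human annotators are modelled as noisy observers
  of the true enter/exit times: each time gets independent N(0, σ²) jitter,
  short intervals can be missed with a configurable probability, the 100 ms
  debouncing rules are re-applied, and TOFF/TFD are recomputed.  σ and the
  miss probability are free simulation parameters, not estimates of any
  particular rater pool.

What the generator does **not** emulate: saccade kinematics (main-sequence
dynamics, curved trajectories), smooth-pursuit gain < 1 on the moving bus,
head movement, calibration drift, or gaze landing anywhere interesting
between AOIs.  Passing the recovery and agreement tests therefore shows the
pipeline implements its definition correctly and is robust to plausible
noise/blink levels — not that it is robust to every artifact of real
recordings.

## Numerical choices

* Times are float seconds on the experiment clock; generated timestamps are
  rounded to 9 decimals so grid arithmetic is exact.
* The dropout threshold comparison uses a 1 ns guard so a gap of exactly
  100 ms is not rejected through float subtraction error.
* `min_interval = 0` disables debouncing entirely (identity).
* Zero-variance agreement tables raise "ICC undefined" rather than
  returning a conventional value.
* Degenerate inputs: an empty trimmed trace yields TFD 0 / absent TOFF;
  a static AOI answers any query time; sliding median windows shrink at the
  trace edges.

## Test and acceptance problem sizes

The test suite validates on single synthetic sessions (36 stimuli each,
seeds 1–5 for the recovery property), 1,000 randomized interval lists for
the debouncing contract, and 200-row tables for the null behaviour of the
ICC.  These sizes make every documented property decisive at desk scale
while keeping the full suite under a minute of compute for the statistical
parts; the session-level tests dominate the runtime.

## Known limitations

* The scorer assumes gaze positions are already expressed in the same world
  frame as the AOI poses; no coordinate-frame reconciliation is attempted.
* Point-in-slab containment cannot represent gaze rays that hit the AOI
  obliquely from a depth-erroneous gaze point far off the plane; raising
  `plane_tolerance` trades that off against false hits near the plane.
* Blink removal is expected to have happened upstream in the acquisition
  stack; the pipeline only *detects* residual invalid runs, it does not
  interpolate across them.
* ICC confidence intervals assume the two-way random-effects model;
  severely non-normal metric distributions (e.g. TFD piled at 0) will make
  the nominal 95% coverage approximate.
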