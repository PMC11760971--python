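# Methods

This note documents the models, numerical choices and known limitations of
`tagtrax`: the trajectory post-processing chain, the three behavioral
traits, the two-group statistical procedure, and the synthetic-data
generator used to validate all of it.

## Processing chain

Input is a per-frame, per-landmark table of pixel positions with tracker
confidences (the three-row-header CSV dialect of DeepLabCut-class pose
estimators; an HDF5 container with the same schema is also read).  The
chain is fixed in this order:

confidence cutoff → centroid → metric calibration → gap interpolation →
low-pass filter → speed → speed gate.

**Confidence cutoff (0.6).**  Observations with likelihood strictly below
the cutoff are masked; a likelihood exactly equal to the cutoff is kept
(the cutoff is the *minimum confidence included*).  Masking is idempotent
and monotone in the cutoff.

**Centroid and the all-landmarks rule.**  The animal's position is the
arithmetic mean of the four body landmarks (antenna tips, when present,
are excluded).  By default a frame is valid only when *all* body landmarks
survive the cutoff (`min_valid_landmarks = 4`).  This is deliberate: the
landmarks sit ±10 mm from the body centre, so a centroid averaged over a
varying subset jumps by roughly a third of the dropped landmark's offset
(~4 mm) whenever the tracker loses a point.  At a realistic ~2% per-landmark
dropout rate such jumps add metres of spurious path per 20-minute trial
and an order-of-magnitude bias in average speed.  Treating partial frames
as gaps and bridging them by interpolation removes the bias at the cost of
a few percent of frames.  Subset centroids remain available
(`min_valid_landmarks = 2`).

**Calibration.**  `x_mm = (x_px − origin_x)·scale_x` per axis (anisotropic
scales are supported because x and y calibration factors are measured
independently).  The default scale, 0.145 mm/px, corresponds to a
185 mm arena filling the width of a cropped 720p frame.  Points outside
the arena rectangle are clamped to the boundary; excursions beyond 5 mm
are logged as calibration warnings.

**Gap interpolation (≤ 15 frames).**  Invalid runs up to 0.5 s flanked by
valid frames are filled linearly.  Longer gaps are left invalid and split
the trajectory into segments that are filtered independently, so filter
transients never bridge a real discontinuity.

**Zero-phase Butterworth (order 2, 6 Hz).**  Each coordinate of each
contiguous segment is filtered forward and backward (`filtfilt`, reflected
padding of length 3·(2·order+1), shortened for brief segments; segments of
≤ 3·order frames pass through unfiltered).  Zero-phase filtering is the
gait-analysis convention: a causal pass would delay the track by several
frames and shift every bout boundary.  The price is that the effective
amplitude response is the *square* of the single-pass Butterworth
magnitude — 0.5 at the corner frequency rather than 1/√2 — which the test
suite verifies against the analytic response.  A causal single-pass mode
is available behind the `zero_phase` flag.

**Speed and gate.**  Speed for interval *i* is the Euclidean displacement
between frames *i* and *i+1* times the frame rate; an interval is valid
only when both endpoint frames are.  Intervals faster than 230 mm/s (the
species' maximum recorded moving speed) mark the *later* frame invalid, in
a single pass over the precomputed speeds — removal is not cascaded, and
exactly 230 mm/s is kept (strict inequality).  Speeds are recomputed after
gating so downstream metrics see gated validity.

## Behavioral traits

* **Average speed** — summed valid inter-frame displacement divided by the
  number of valid intervals, times the frame rate (mm/s).  Dividing by
  valid rather than total intervals avoids deflating the speed of
  individuals with more masked frames; the literal total-interval
  denominator is available via `avg_speed_denominator="total"`.
* **Walks** — maximal runs of consecutive valid intervals with speed
  strictly above 10 mm/s, lasting at least 1.0 s (duration counted in
  intervals: 30 intervals at 30 fps is exactly 1 s).  A single
  sub-threshold or invalid interval ends a run; there is no dip tolerance.
* **Exploration** — the number of distinct cells of a 3 × 6 grid (18
  equal cells, the shape that best matches the 185:80 arena aspect ratio;
  the grid shape is configurable) visited by valid centroid positions.
  Cell assignment is `floor`-based with far-edge points assigned to the
  last row/column; positions are clipped to the arena first because
  filtering can leave sub-millimetre excursions past a wall.

## Statistical comparison

Per trait: OLS of the (possibly transformed) trait on the tag factor
(treatment coding, untagged = reference) plus the experimental block
factor, both fixed.  The tag effect is tested with a Type II *F*-test
(1 numerator df) — computed as the nested-model *F* against the block-only
model, which is identical to Type II for a 1-df factor without
interactions and is cross-checked against the independent ANOVA routine in
the test suite.  Residual normality is checked with Shapiro–Wilk; when it
rejects at α = 0.05 the trait is re-fit along the ladder identity → √x →
log x → x³, keeping the first rung whose residuals pass (the last rung,
flagged, if none does).  The cube rung is the literal third power; a
cube-root alternative exists because the wording of such choices is often
ambiguous.  Zeros under the log rung receive a half-count offset
(0 → 0.5), loudly logged.  Blocks containing only one group would
confound tag with block, so the block factor is then dropped with a
warning.  No multiple-testing correction is applied across the three
traits (a Holm option would be trivial to add; the original protocol used
none).  Presets `rfid` (√x for all traits) and `marker` (identity /
log / x³) reproduce fixed per-study transformation choices.

Monte-Carlo calibration of the full procedure (transformation selection
followed by the *F*-test) on simulated null studies gives per-trait type-I
error close to the nominal 0.05; the walk count, a small discrete
variable, runs very slightly liberal (~0.055–0.065 in our replicates),
which is the familiar behaviour of normal-theory tests on skewed counts
at n = 30.

## Synthetic-data generator

The generator produces what the chain consumes: pixel-space pose tables
with confidences, plus noise-free ground truth.

**Behavioral model.**  Alternating pauses and walk bouts with exponential
durations (means 240 s and 8 s); bout speed is gamma across bouts
(shape 4, mean 25 mm/s) and constant within a bout apart from short
(≤ 8-frame) acceleration ramps at the edges.  During bouts the animal
performs a correlated random walk: heading diffusion of 0.4 rad/√s
realised as an AR(1) angular-velocity process with 0.3 s correlation time,
steering capped at 0.15 rad/frame.  Near walls (within 15 mm) the heading
is blended toward the nearest wall tangent with strength proportional to
the thigmotaxis weight (0.7), and a time-to-impact controller steers along
whichever wall would be hit first, so corners are turned smoothly; a
specular reflection with clamping (1 mm margin) remains as a failsafe.
Pacing is modelled two ways, mirroring the back-and-forth edge shuttling
seen in tagged animals: spontaneous smooth 180° turns (rate 0.1 s⁻¹) and a
per-trial home range (40–90 mm) that triggers a turn when the bout strays
beyond it; most bouts also set off roughly opposite to the previous bout's
ending direction.  The tag effect multiplies walk-initiation rate and bout
speed by √effect each, so `effect` is the expected multiplier of average
speed.

Null-group defaults were calibrated once so simulated untagged individuals
fall in the range observed for real untagged animals (~0.8 mm/s average
speed, ~4 walks per 20-min trial).  Simulated exploration (~10 zones) runs
higher than real untagged animals (~6–7): simulated pacing is less
spatially persistent than real shelter-seeking, a known gap between the
generator and real data.

**Identifiability by design.**  Two generator properties exist so that
ground truth is *recoverable* by the mandated processing chain rather than
ambiguous under it:

* paths are smooth in time (correlated turning, rate-limited steering,
  edge ramps), so the 6 Hz zero-phase filter is nearly transparent to the
  true path — white per-frame heading noise would put most path energy
  above the filter band and make exact recovery impossible by
  construction;
* bout durations avoid [0.8, 1.2) s and bout speeds avoid [10, 13) mm/s
  (draws in these guard bands are resampled), so the ±1–2-frame
  threshold-crossing shifts that smoothing introduces at bout edges cannot
  flip a bout's ground-truth label.

Ground truth (bouts, average speed, zones) is computed from the realised
noise-free path with the same metric definitions the pipeline uses, so
truncated or wall-reflected bouts are labelled consistently.

**Observation noise.**  Landmarks sit at fixed body-frame offsets (summing
to zero, so their mean is exactly the centroid) rotated by the heading and
converted to pixels through the arena calibration.  Each landmark
coordinate receives Gaussian jitter with 1 px marginal sd and an AR(1)
correlation time of 1 s — pose-estimator error on near-identical frames is
strongly autocorrelated; modelling it as white would overstate
frame-to-frame flicker several-fold.  Each landmark independently drops
out with probability 0.02 per frame, receiving a likelihood below the
confidence cutoff (others draw uniformly above it).

**Tolerance conditioning.**  Speed-recovery is asserted relatively (0.5%)
on trials containing at least one true walk; a trial with no walk carries
only a few millimetres of sub-threshold creep, where a relative bound is
ill-conditioned, so such trials are held to an absolute 0.005 mm/s
tolerance instead (the usual rtol-plus-atol reasoning).

**What passing tests do and do not show.**  With zero noise the full chain
recovers walk and zone counts exactly and average speed to <0.5% across
seeded trials; with default noise, walk counts stay within ±1 and zone
counts within ±1 in ~100% of trials.  Average speed, however, carries an
irreducible positive bias under tracking noise: the summed-|displacement|
statistic rectifies residual velocity noise (~0.2–0.3 mm/s after
filtering) over the ~97% of the trial the animal is stationary, inflating
it by tens of percent against a ~0.8 mm/s true signal.  No temporally
honest jitter model with a 1 px marginal sd avoids this.  The bias is
common to both tag groups, so group *comparisons* are unaffected — but
absolute average speeds from this pipeline (and from any pipeline with the
same chain, on real data) should be read as noise-floor-inflated, and the
validation suite reports the measured bias rather than hiding it.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 50 noise-free and 200
noisy trials for recovery; 1000 random series for walk-detector oracle
equivalence; 100 random fixtures for linear-model oracle equivalence; 500
replicate null studies (15/15, 4 blocks) for type-I calibration; and 200
replicate studies per arm for the effect-pattern checks (effect 5 at
15/15/4 blocks; effect 1.25 at 10/10/2 blocks).  These sizes keep the full
validation around ten minutes on one CPU while leaving Monte-Carlo noise
well inside the asserted tolerances.
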