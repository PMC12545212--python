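# Methods

## Scope and data model

The package analyses markerless kinematics of crawling octopus arms from
two inputs a depth-mapping camera provides: per-frame 2D positions of
tracked points (sub-pixel, from a digitizing tool) and orthographic range
images ("depth maps", mm per pixel, with invalid pixels where no surface
was resolved).  Tracked points carry one of three roles: *key* points mark
material positions along an arm, *guide* points add constraints for the
curve fit, and *reference* points follow static background features used to
remove camera/vehicle motion.  Frames are 0-based and all intervals are
half-open `[on, off)`; arms are labelled L1..L4, R1..R4 with pair 1 dorsal
and pair 4 ventral.

## Trajectory cleaning

The correction chain mirrors standard practice for depth-derived point
tracks and runs in a fixed order:

1. **Depth lookup.**  z is the median of the valid pixels in an 11 x 11
   window centred at the rounded (half-to-even) pixel position; x and y are
   the sub-pixel track position times the pixel pitch.  An observation is
   dropped when less than half of the window carries valid depth — a median
   needs a majority of real pixels.
2. **5-frame median** on z to knock out single-frame range errors.
3. **Background removal.**  The per-frame offset is the component-wise
   median over reference points of (current minus first-valid position),
   subtracted from every trajectory.  The median (rather than mean) makes
   one misbehaving reference harmless.  Frames with no valid reference
   carry the last offset forward and are logged.  The operation is exactly
   idempotent, and a pure per-frame translation of the whole scene is
   removed to machine precision.
4. **Outlier rejection** against a 50-frame moving-median z baseline:
   a sample is removed when its deviation exceeds the larger of 5 mm and
   one standard deviation of all baseline deviations of that trajectory
   (computed per trajectory, not per window, so the rule is reproducible).
   An option extends the rule to all three axes.
5. **20-frame moving average** per axis, then invalid runs strictly shorter
   than 100 frames are filled with an interpolating cubic spline through up
   to 8 valid samples on each side.  Shape-preserving interpolants (PCHIP)
   were rejected because they do not reproduce smooth polynomial motion;
   the not-a-knot cubic reproduces cubic trajectories exactly.  Gaps at the
   sequence edges are never extrapolated.

All window filters are centred and shrink at the sequence edges — no
padding, no fabricated samples.  Every filter is checked bit-for-bit
against an independent brute-force implementation.

A caveat worth knowing: the outlier rule assumes the arm moves slowly
relative to the 50-frame (0.83 s at 60 fps) baseline window.  For strides
much faster than ~5 s per cycle the genuine motion itself exceeds the
threshold and real samples are removed.  Deep-sea crawling (cycle durations
of tens of seconds) is comfortably inside the valid regime.

## Arm curves, curvature, strain

Each frame's arm is a **simple interpolating spline** through the ordered
valid points, parameterized by chord length and reparameterized to arc
length by composite Simpson quadrature on a dense grid (32 samples per
segment).  Curvature is computed analytically from the spline derivatives,
kappa = |r' x r''| / |r'|^3, which is parameterization-invariant, at
regularly spaced arc-length stations (default 100).

Spline degree: curvature is a second derivative, and a cubic interpolant
through sparse tracked points carries O(h^2) oscillatory second-derivative
error — on a 200 mm arc sampled at 8 points that error reaches 1.6% of the
true curvature at the 5% arc-length station regardless of parameterization.
Sparse fits (>= 6 points) therefore default to an interpolating quintic,
which reduces the same error to 0.04%.  Refits from dense samples use a
cubic: at that knot density its interpolation error is negligible and a
higher order would only amplify residual noise.  Smoothing is never applied
along the arm; all smoothing is temporal and explicit.

**Temporal stabilisation** samples every frame's curve at shared
per-segment arc-length fractions, applies a centred 7-frame moving average
across frames to each sampled coordinate, and refits.  Tracked points sit
at segment boundaries, so their material identity survives the refit.
Frames whose valid point set differs from the modal one are treated as
missing rather than silently changing segment identity.

**Strain** of segment i is 100 * (L_i(t)/L_i(t0) - 1) with L measured along
the fit between consecutive tracked points.  The reference configuration t0
is the curve at substrate release — the natural origin of an arm cycle,
where time axes of the fields are also anchored.  This choice is a
convention (release frame vs first frame vs rest length) and is exposed as
the `release_frame` argument of `build_field`.

**Fields.**  `build_field` resamples curvature onto stations at equal
fractions of each frame's arc length and maps per-segment strain
piecewise-constant onto the stations of the release-frame curve; the s axis
is labelled in mm of the reference curve, optionally shifted so s = 0 sits
at the foot (substrate attachment) point, and t = 0 at release.  By
construction the strain field's t = 0 row is identically zero.

## Gait analysis

A stride is one contact onset of an arm to its next onset; the duty cycle
is the contact fraction in percent.  Contact states are ternary
(contact / air / unknown).  Strides that touch unknown frames are excluded
by default (a grey region makes both onset and cycle length uncertain); a
`max_unknown_frames` option tolerates short unknown runs.  A contact run
starting at frame 0 is left-censored and dropped.  Summaries per arm pair
report median, IQR and Tukey whiskers (Q1 - 1.5 IQR, Q3 + 1.5 IQR).

The arms-in-contact series counts contact states per frame (unknowns count
as non-contact and are reported separately; all-unknown frames are
excluded).  The trend is a cubic regression B-spline (20 basis functions)
with a ridge penalty whose weight is selected by generalized
cross-validation over a fixed grid, fitted via statsmodels' GAM machinery;
the 95% band is the normal approximation from the coefficient covariance.
Constant series short-circuit to a flat, zero-width band.

The bilateral-support fraction counts, among determinable frames, those
with at least one left and one right arm in contact.  A frame is
determinable when the known states decide the answer: bilateral when both
sides have a known contact; not bilateral when all arms of either side are
known to be in the air; excluded otherwise.

The touch-down order matrix counts consecutive onset pairs (entry (b, a):
arm b's onset immediately after arm a's).  Onsets require a known air state
in the previous frame; simultaneous onsets are ordered L1..L4, R1..R4 and
every consecutive pair is counted, which makes the count deterministic.

## Aggregation and morphometrics

To pool strides across arms and individuals, the arm-distance axis is
normalized to the individual's head width and the time axis to the median
arm cycle of that arm pair; curvature and strain values are untouched.
Pooled samples fall into a rectangular (s', t') grid (default 20 x 20 over
the observed range) with per-bin arithmetic means and the count of distinct
sequences contributing — means rather than medians, as the binned map is a
first-moment summary and the choice is configurable upstream.

Morphometric measurements are Euclidean distances between picked 3D points,
summarised as mean ± sample (n-1) standard deviation over at least three
repeats from different perspectives.  The calibration report compares
measured to known distances on a dot grid: per-pair error
|measured - known| / known * 100, passing when the mean is strictly below
2% — the instrument-validation statistic.

## The synthetic generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions of every recovery test.

An arm stride is a planar (torsion-free) curve built by integrating
prescribed curvature and stretch profiles over the material coordinate:
kappa(sigma, t) = kappa_peak * exp(-(sigma - s_foot)^2 / 2w^2) * h(t), a
Gaussian bump centred at the foot, and strain concentrated as a
raised-cosine bump over the third of the arm immediately proximal to the
foot, both under a raised-cosine time envelope h(t) over one cycle.  The
envelope is zero at frame 0, the substrate-release frame, so the truth
strain is identically zero at the reference time.  Defaults: 200 mm arm,
13 key points (spacing ~16.7 mm — at least two points per standard
deviation of the curvature bump, so the tracking density resolves the
bend), foot at 45% of arm length, kappa_peak 0.02 mm^-1 (a 50 mm bend
radius, a strong curl), bump s.d. 30 mm, strain peak 15%, 10 s cycle at
60 fps.  A `constant` envelope variant yields stationary shapes (e.g.
circular arcs) for closed-form checks.

Observation simulation adds i.i.d. Gaussian noise per point and axis plus a
per-frame drift vector shared by all points — including three generated,
world-stationary reference points — emulating vehicle and instrument sway.
Depth stacks are rendered orthographically: each point paints a disc of its
depth (nearest surface wins), everything else is invalid, depths are
quantized to 0.01 mm so stacks survive the 16-bit on-disk round trip
bit-exactly, and the returned 2D tracks carry sub-pixel positions as a real
digitizer would.  Gaits are deterministic square waves with per-arm period,
duty and phase, plus i.i.d. masking to the unknown state.  All stochastic
operations are pure functions of (inputs, seed).

What the generator does *not* emulate: arm torsion, tapering and
self-occlusion, sucker-scale structure, correlated tracker failures,
non-Gaussian depth artefacts (e.g. specular dropouts), and terrain-driven
irregularity of real gaits.  Passing recovery tests therefore demonstrate
the correctness of the measurement chain, not robustness to every failure
mode of field data.

## Recovery performance and a known limit

With noise-free observations the full chain (simulate → render depth →
preprocess → reconstruct) recovers the curvature field to ~0.14% and the
strain field to ~0.32% of their peaks (RMSE over the interior 90% of arc
length, all frames).

At 1 mm/axis observation noise the recovery floor is set by information,
not implementation: the stated filter chain reduces white point noise to at
best 1/sqrt(20) = 0.22 mm (the 7-frame average on the interpolation removes
little more, because the 20-frame average leaves noise correlated across
±10 frames), and a second derivative over ~16.7 mm point spacing amplifies
0.22 mm to roughly 2-3 x 10^-3 mm^-1 — 12-17% of the 0.02 mm^-1 peak, for
any interpolant (an ideal three-point second difference already gives
sqrt(6) * 0.22 / 16.7^2 ≈ 10%).  Strain referenced to a single release
frame additionally inherits that frame's segment-length noise as a
persistent offset.  Measured: ~18% (curvature) and ~20% (strain) of peak at
this noise level.  Sub-10% recovery at 1 mm noise would need wider point
spacing (which undersamples the bend), longer temporal averaging, or a
smoothing rather than interpolating spline — all deliberate departures from
the processing chain this package implements.

## Problem sizes

Default validation runs use one 600-frame stride per seed (10 s at 60 fps,
13 points plus 3 references, ~850 x 330 px depth frames at 0.25 mm/px),
ten seeds for the noisy end-to-end check, 10-minute gaits at 60 fps for
stride statistics, and 1000 random inputs for the filter-oracle checks.
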