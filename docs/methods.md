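# Methods

## Problem and measurement model

An engineered cardiac microbundle is suspended between two elastomeric
cantilever pillars. During a twitch the tissue pulls the pillar tips
toward each other; treating each pillar as a linear cantilever, the tip
force is `F = k·δ` where `δ` is the tip deflection from rest and `k` the
pillar stiffness. When `k` has not been measured it is derived from beam
theory for a point load applied at distance `a` along a cantilever of
length `L`:

    k = 6 E I / (a² (3L − a)),      I = w t³/12 (rectangular) or π D⁴/64 (circular)

which reduces to the classical tip-load stiffness `3EI/L³` at `a = L`.
Unit policy: lengths in μm, forces in μN, stiffness in μN/μm; the elastic
modulus is accepted in kPa and converted internally (1 kPa = 10⁻³
μN/μm²). Stress is force divided by the tissue cross section (automatic
width × user depth) and reported in kPa (1 μN/μm² = 1 MPa).

**Deflection convention.** `δ` is the mean of the two pillars'
deflections from their own rest positions. The alternative — the change
in inter-pillar distance — is the sum of the two deflections and
reports forces exactly 2× higher for a symmetric contraction. The
package outputs the per-pillar-mean convention and exposes the other for
auditing; a unit test pins the factor at exactly 2.

## Pipeline

**Segmentation.** The first frame is thresholded with a local Otsu rank
filter (disk neighborhood, radius `min(frame)/5`, at least 15 px) with a
global-Otsu floor that suppresses speckle in flat background. Because
the tissue band often bridges the two caps into a single component, the
threshold is escalated (a second Otsu restricted to the current
foreground) until two laterally separated candidates emerge; candidates
touching the border or smaller than 0.1% of the frame are discarded, and
the two largest whose centroid-column separation exceeds one candidate
width are kept. For `type2` data (dark cantilever tips on a bright
background) polarity is inverted when the bright class is the majority.
All of this detail — the radius, the floor, the escalation, the
type-2 prior — is this package's own design; only "local Otsu
thresholding" is inherited from the measurement idea itself. When
segmentation fails the error directs the user to supply external masks
(0/1 text grid or binary PNG).

**Tracking.** Markers are Shi-Tomasi corners (minimum eigenvalue of the
structure tensor, via scikit-image) inside each mask, thresholded at a
fraction of the maximal masked response with non-maximum suppression.
They are tracked frame-to-frame by a pyramidal iterative Lucas-Kanade
solver written in-package on numpy/scipy: per marker, the displacement
solves the windowed normal equations on Sobel gradients of the earlier
frame, iterated to convergence (ε = 0.01 px, ≤30 iterations) and refined
coarse-to-fine over a Gaussian pyramid (3 levels by default, capped so
the coarsest level keeps ≥16 px per side). Trajectories are cumulative
positions; markers are dropped when the structure tensor degenerates,
the single-step displacement exceeds the window extent, or the position
leaves the frame. At least 5 markers per pillar must survive.

Parameter auto-adjustment is a deterministic schedule: quality level
halved from 0.1 down to 0.005 until ≥10 markers are found; if the floor
is reached on a small mask, the suppression radius is reduced 3 → 2 → 1
and the schedule replayed; the integration window (default 15 px) grows
to a quarter of the mask bounding box for large pillars. The entire
tracking path uses no random state.

**Beat segmentation.** Beats are delimited by valley (fully relaxed)
frames. Crucially these are detected on the *inter-pillar separation*
signal (`max(sep) − sep(t)`), which is baseline-free: a displacement
series baselined at frame 0 cannot distinguish a movie that starts
relaxed from one that starts contracted, whereas the separation is
maximal at relaxation whatever the starting phase. The signal is
smoothed (centered moving average over `max(3, fps/10)` frames),
detrended by a rolling-minimum baseline (so drift cannot mask beat
prominence), and beat peaks are found with prominence ≥25% of the
detrended range and separation ≥ fps/3 frames (capping the detectable
rate at 3 Hz); valleys are the smoothed-signal minima between
consecutive peaks. A trailing minimum on the last frame is discarded
(terminal partial beat). If the first valley is not frame 0 the movie is
truncated there and re-tracked. A movie must contain ≥2 complete beats
to be analyzed and ≥3 to be split.

**Drift and irregularity.** Drift is flagged when the mean absolute
displacement at any valley after frame 0 exceeds 0.5 px (below typical
tracking noise a warning would be meaningless; configurable). The
correction — per-beat splitting, only on user request — re-baselines
each beat at its own start-valley marker positions. Irregular beating is
flagged (warning only) when the beat-period coefficient of variation
exceeds 20% or any beat's peak deviates >30% from the median peak —
both thresholds are this package's choice, as no canonical rule exists.

**Metrics.** Per beat: peak displacement/force/stress; contraction and
relaxation velocities as the extrema of the central-difference
derivative before/after the peak; FWHM and FW80M as the full widths at
50% / 80% of the peak, with flank crossings located by linear
interpolation. "FW80M" is read as full width at 80% of maximum.
Beating rate is complete beats divided by the first-to-last-valley time.
Summaries are means ± SD across beats (SD reported as 0 with a flag for
a single beat).

**Tissue width.** On the first valley frame, the column-averaged
intensity profile of the central third of the inter-pillar strip is
Otsu-thresholded (hence invariant to global intensity rescaling) and the
width is the longest contiguous above-threshold run of rows. The method
is this package's own; a manual width can be supplied instead.

## Synthetic data generator

The generator renders what the tracker actually faces: two
speckle-textured caps (band-limited seeded noise, 40% contrast by
default so corner detection always has support) joined by a dimmer
tissue band that stretches linearly between the moving inner cap edges.
Sub-pixel motion is realized by cubic-spline resampling of precomputed
texture fields — never integer rolls. Noise (Gaussian, default 2% of
dynamic range) and optional drift are applied after motion;
quantization to 8 or 16 bit is last. Defaults: 128×256 px frames, 40 px
caps (≈160 μm at the Type-1 length scale of 4 μm/px, matching real
pillar cap dimensions — large enough that a 5×5-kernel erosion applied
four times still leaves a trackable core), raised-cosine waveform,
amplitude 3 px, period 30 frames, 3 beats, plus a third of a period past
the final valley so that valley is an interior minimum.

Drift is modeled as a rigid translation of both caps *perpendicular* to
the contraction axis (row direction), emulating stage/focal drift; it
adds in quadrature to the contraction displacement, walks the valley
baseline linearly, and leaves the inter-pillar separation untouched —
the regime in which per-beat re-baselining is an effective correction.

The renderer is validated before it judges the tracker: an exhaustive
sub-pixel SSD registration of cap-interior crops (0.02 px grid — no
gradients or pyramids shared with the tracker) must agree with the
manifest within 0.1 px.

What the generator does **not** emulate: out-of-plane motion and
defocus, pillar rotation or cap deformation, uneven illumination,
photobleaching, and non-stationary noise. Passing tests therefore show
correctness of the algorithmic chain on in-plane translational motion
with stationary Gaussian noise, not robustness to every real-world
artifact.

## Numerical choices and degenerate inputs

* Bilinear sampling inside the LK solver; Sobel/8 gradients; structure
  tensors with determinant ≤1e-12 invalidate a marker.
* Valley detection boundary rule: the leading minimum before the first
  beat peak is always a valley; a trailing minimum is a valley only if
  the signal rises after it.
* Near-constant frames (intensity range <1% or <3 gray levels) are
  rejected before thresholding.
* Erosion that splits a mask keeps the largest piece (logged); erosion
  that empties a mask is an error.
* Velocities use unsmoothed central differences; beats shorter than 5
  frames or flat beats are metric errors, and a beat whose flanks never
  cross the width level yields NaN widths with a warning rather than
  aborting the run.

## Problem sizes

The validation suite runs on 128×256 px movies of ~100 frames with
20–200 markers per pillar — small enough to iterate quickly, large
enough that amplitudes of 1.5–5 px with 2% noise exercise the sub-pixel
regime the accuracy claims are about.

## Known limitations

* Exactly two pillars; no support for multi-post arrays.
* Pure translation tracking: rotation or deformation of a cap is
  averaged, not modeled.
* The drift correction assumes drift accumulates slowly relative to a
  beat; fast jerks are neither detected nor corrected.
* Type-2 handling is a polarity prior, not a shape model.
* The AI-based segmentation path available in some tools (fine-tuned
  foundation segmentation models) is out of scope here; local Otsu plus
  external masks is the full segmentation surface.
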