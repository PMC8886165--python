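# Methods

## Measurement model

The package quantifies subacromial motion from two landmarks annotated on
every frame of a dynamic ultrasound recording: the lateral edge of the
acromion and the greater tuberosity (GT) of the humeral head. The acromial
annotation of the *same frame* is the reference point, so the relative
position (GT − acromion), scaled by the probe calibration, is immune to
slow transducer drift common to both landmarks; a fixed first-frame
reference would fold that drift into the trajectory, which is why per-frame
referencing is the default and only mode. Coordinates follow the image
convention (y increases with depth); the vertical component of the relative
position is therefore a positive "vertical acromiohumeral distance" when
the GT sits below the acromial edge. Ingestion for sources with an upward
y axis flips the sign at calibration time so this invariant always holds
downstream.

The kinematic model is planar: during one abduction or adduction phase the
GT is assumed to travel a circular arc about a fixed humeral rotation
centre. The circle is estimated per phase by minimising the geometric cost
F = Σ(rᵢ − r_c)² over centre and radius; the rotation angle θ is measured
between the observed leftmost and rightmost points of the phase as seen
from the fitted centre — deliberately from data extremes rather than fitted
arc endpoints, so θ degrades gracefully when the arc is noisy. θ is
expected below 90° for physiologic abduction of this kind; values at or
above 90° are flagged (`exceeds_90`) and warned about but reported
unchanged, since any remedy (clamping, supplement) would silently alter
data.

## Phase segmentation

Peaks and troughs are detected on the relative X signal with
prominence-thresholded peak picking (default prominence: 0.2 of the signal
range — small enough to tolerate asymmetric repetitions, large enough to
reject annotation jitter), followed by an alternation pass that collapses
consecutive same-type extrema to the strongest (ties to the earliest
frame). When no minimum spacing is given, a second pass enforces half the
median inter-extremum interval, suppressing noise twins near flat extremum
plateaus. Trough→peak intervals are abduction phases, peak→trough
adduction; troughs delimit cycles. Of the performed repetitions the middle
three complete cycles are kept (`keep_cycles=3`); with an odd surplus the
extra dropped cycle is the leading one (warm-up repetitions are less
representative than final ones), and with fewer than three complete cycles
all complete cycles are analysed with a warning rather than failing — short
clinical recordings should degrade loudly, not die.

## Reliability statistics

Reliability of repeated measurements uses the single-measure two-way mixed
ICC. The consistency form ICC(3,1) = (MSR − MSE)/(MSR + (k−1)·MSE) is the
default because the intended design is the same fixed rater(s) re-measuring
the same clips, where a systematic session offset should not count against
reliability; the absolute-agreement variant is available via
`model="agreement"`. Confidence intervals are exact F-based bounds
(Satterthwaite-approximated for the agreement form). The pooled SD is the
root of the mean per-column sample variance. SEM = pooled SD·√(1−ICC) and
MDC = 1.96·√2·SEM are always computed from unrounded intermediates —
rounding SEM first (e.g. to 0.08) visibly distorts MDC at the second
decimal. Bland–Altman limits of agreement use the sample (n−1) SD of the
paired differences.

## Synthetic motion generator

`simulate_recording` emulates the acquisition geometry: the GT moves on a
circular arc (radius `true_radius`, default 4.86 cm) about a fixed centre,
sweeping 0→`true_sweep`→0 (default 36°) each cycle with a
sinusoidal-in-time angular profile (smooth start/stop, as arms are raised
naturally). The arc is oriented so the vertical separation attains
`min_separation` (default 0.29 cm) exactly at peak abduction, where the
X coordinate is also maximal — reproducing the empirical sine-wave X
signal. Defaults are five cycles of 4 s sampled at 4 frames/s. Both
landmarks ride a slow common transducer drift (amplitude 0.05 cm), which
per-frame referencing must cancel, and receive independent isotropic
Gaussian jitter (`noise_sd`, default 0.02 cm per landmark — so the relative
trajectory carries √2·noise_sd ≈ 0.028 cm). A single seed fans out to
independent substreams for drift and noise, so the noiseless path is
invariant to the noise setting.

What the generator does **not** emulate: B-mode speckle or any image-level
effect, landmark mislabelling (gross outliers rather than Gaussian jitter),
out-of-plane motion, scapulothoracic contribution, cycle-to-cycle
variability of effort, or fps jitter. Passing recovery tests therefore
demonstrate correctness of the geometry/statistics pipeline under the
idealised annotation-noise model, not robustness to everything a sonographer
will encounter.

## Numerical choices

- Circle fit: algebraic Kåsa fit initialises a Levenberg–Marquardt
  refinement of the radial residuals (scipy `least_squares`, ftol 1e−10,
  iteration cap ≈ 100 Gauss–Newton steps); non-convergence returns the best
  iterate flagged `converged=False`. Collinear or <3 distinct points raise
  a degeneracy error (SVD ratio 1e−9). On random shallow-arc instances the
  returned cost matches a truth-initialised refit to ~1e−15, i.e. the
  global optimum of F is reached in practice.
- Extremum ties (equal prominence/height) resolve to the earliest index;
  leftmost/rightmost point ties likewise.
- Ingestion bridges runs of ≤ 2 consecutive frames with missing/non-finite
  annotations by linear interpolation in time (warned); longer gaps abort —
  interpolating more would invent motion and shift phase timing.
- Negative vertical separations inside a phase (annotation slips placing
  the GT above the acromion) are clipped to 0 with a warning before the
  minimum is taken.
- Distances are meaningful to ~0.01 cm and angles to ~0.01°; reports round
  only at display time.

## Problem sizes used in validation

The test-suite and the reproduction script validate at the generator's
default study scale: recordings of 81 frames (5 × 4 s cycles at 4 fps),
100 seeded repetitions for parameter-recovery medians, 500 seeded 10×2
ratings tables for the variance-components ICC check, and brute-force
circle-cost grids of ~10⁶ candidates per instance. The complete run takes
a few seconds on one core.

## Known limitations

- **Radius identifiability.** A 36° arc observed through 9 samples whose
  spacing clusters at the arc ends (a consequence of the smooth velocity
  profile) determines the radius weakly: at the default annotation noise
  the per-phase radius SD is ≈ 0.5 cm, so even averaging six phases leaves
  a median absolute error of ≈ 0.17 cm at a 4.86 cm radius. This is an
  information limit of the geometry (a truth-initialised optimiser does no
  better), not a solver artefact; the swept angle (≈ 1.2° median error) and
  minimal separation (≈ 0.017 cm) are far better determined. Users should
  treat single-recording radii as noisy and average across recordings.
- The planar circular-arc model ignores out-of-plane humeral translation
  and treats the "most prominent humeral point" fallback annotation as
  equivalent to the true greater tuberosity.
- ICC confidence intervals assume Gaussian components; very small designs
  (m = 2) give extremely wide, though valid, intervals.
- The θ < 90° condition is a model assumption without a remedy; downstream
  statistics include flagged phases unless the caller filters them.
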