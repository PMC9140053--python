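# Methods

`renulm` implements the analysis chain of contrast-enhanced super-resolution
ultrasound (ULM) velocimetry of the rat kidney: microbubbles (MBs) infused
into the blood act as point scatterers; localizing them in every contrast
frame and linking the localizations into tracks yields per-step velocity
vectors that serve as a surrogate for blood velocity in vessels far below
the diffraction limit. Because no raw scanner data are distributable, the
package also contains a synthetic generator that emulates the study design —
three consecutive scans of a coronal kidney cross-section with an
alpha-1-blocker (prazosin) injected early in scan 2 — so that every stage is
testable against ground truth.

## Coordinate and angle conventions

Frames are `[row = axial depth, col = lateral]`; pixel `(r, c)` has its
center at `((c + 0.5)·pitch, (r + 0.5)·pitch)` mm from the top-left corner.
Flow angles are degrees in `[0, 360)` with `angle = atan2(-dy, dx)` (y-up
mathematical convention), so flow toward the transducer is 90°.

## Synthetic phantom

The phantom is a 128 × 128 px field at 0.05 mm pitch (6.4 × 6.4 mm)
containing three concentric annular regions about a center below the field:
inner medulla (0–1.5 mm), outer medulla (1.5–3 mm), cortex (3–4.5 mm).
Each region holds straight radial vessels inside an angular fan pointing
toward the transducer (±40° in the cortex, ±30° in the medulla). Arterial
cortical flow and ascending vasa recta run outward; cortical venous flow and
descending vasa recta run inward, so the venous/ascending bed of every
region opposes its arterial/descending partner by 180°. Each venous vessel
is the arterial vessel's twin shifted 0.45 mm laterally: far enough apart
that two point-spread blobs (σ = 0.075 mm) passing in opposite directions
remain separate connected components at the default detection threshold.
Vessel counts (6/6 cortex, 4/4 OM, 3/3 IM) and the inner-medulla stop radius
(0.7 mm) keep neighbouring vessels separated by more than a blob diameter;
denser geometries make opposed or adjacent bubbles merge, which is exactly
the overlapping-MB regime the tracking method does not claim to resolve.

Default bed speeds are 1.59 (cortical arteries/arterioles) and 0.70 mm/s
(OM descending vasa recta) — the study's baseline means — with plausible
values for the four beds whose baselines are not individually reported
(cortical veins 1.00, OM-AVR 0.55, IM-DVR 0.60, IM-AVR 0.50 mm/s; venous and
ascending beds slower than their arterial partners, medulla slower than
cortex).

## Hemodynamics

The mean arterial pressure (MAP) model is landmark-parameterized: flat at
84 mmHg; from 10 s after injection an exponential decay (time constant =
drop interval / 4) truncated at its minimum 54 mmHg 67 s after injection;
then exponential relaxation (τ = 100 s) toward 65 mmHg. The trough therefore
sits inside the observed 52–82 s post-injection interval, and the final
value of a 410-s post-injection window is within 1 mmHg of the recovery
landmark. Trace noise is white Gaussian, 4 mmHg SD at 1 Hz — a conservative
stand-in for ventilation and pulse-pressure fluctuations of an arterial
line.

Per-bed speed multipliers couple to the normalized MAP excursion
`g(t) = (MAP_baseline − MAP(t)) / (MAP_baseline − MAP_min)`:
`m(t) = 1 − α·g(t)`, with `α` scaled so the mean multiplier over the
post-injection analysis window equals the configured scan-2 target. The
scan-2/3 targets of the responding beds reproduce the reported scan means
(cortex arterial 1.59 → 1.14 → 1.18, OM-DVR 0.70 → 0.66 → 0.69 mm/s); the
cortical veins get a small non-significant dip and the inner medulla none.
The coupling is monotone during the MAP drop by construction.

## Microbubbles and rendering

Arrivals form a Poisson process of 2.5 MB/s total, split evenly across
vessels (thinning preserves Poisson statistics per vessel). This dilute rate
is a deliberate ULM operating point: at several-fold higher rates two
bubbles frequently travel the same vessel within a blob diameter and merge,
which corrupts localization — the generator's default stays in the regime
the tracker is designed for. Each bubble advances once per frame by
`v(t_k)/54 Hz` (per-step displacement exactly matches the commanded
instantaneous speed), and is truncated at vessel exit, scan end, or an
exponential disruption time with per-second probability 0.02 (bubbles
frequently disrupt before reaching the venous side).

Rendering places an isotropic Gaussian blob (σ = 0.075 mm, half the 10-MHz
wavelength; peak 100 a.u.) at each motion-displaced true position and adds
white Gaussian noise (SD 2 a.u.). The B-mode channel is a static synthetic
speckle pattern (Gaussian field, 1.5 px correlation length) warped by the
same motion field. Tissue motion models residual respiration: a purely
axial, spatially weighted sinusoid `d_y = A·sin(2πft)·cos(πx/2L)` with
A = 0.1 mm and f = 69/60 Hz (the ventilation rate); the peak displacement
equals A exactly.

## Localization

Frames are Gaussian-smoothed (σ = 1 px), thresholded (25 a.u. by default, or
a per-frame percentile), and 8-connected components of at least 3 px are
kept. Sub-pixel positions are weighted centroids with weights equal to the
smoothed intensity *above the threshold*; subtracting the cut removes the
truncation bias a hard threshold induces in a plain intensity-weighted
centroid (≤ 0.01 px residual bias on noiseless blobs versus ~0.1 px
without).

## Motion estimation and compensation

Displacement relative to the first frame is estimated per 3 × 3 mm patch at
80% overlap (0.6 mm stride) by maximizing the zero-normalized
cross-correlation over integer shifts within ±0.4 mm, refined per axis by a
parabolic fit through the peak's neighbours; flat (zero-variance) patches
report zero displacement with a low-confidence flag. Implementation:
templates come from the fixed reference frame, so their FFTs are precomputed
and each B-mode frame costs one batched FFT correlation plus integral-image
normalization. The dense field is the bilinear interpolation of patch
vectors, clamped to border values outside the patch-center hull.
Localizations are corrected by subtracting the field of the
nearest-in-time estimated frame; because respiration (~1.15 Hz) is slow
against the 54-Hz frame rate, estimating every 2nd frame changes the
correction by well under a tenth of a pixel.

## Tracking

A constant-velocity Kalman filter per track (state: position + velocity;
white-acceleration process noise 1 mm/s², measurement noise 0.025 mm = half
a pixel). Association is hierarchical: confirmed tracks before tentative
ones and, within a status, slow-speed gates (≤ 5 mm/s) before fast ones; a
track with a single detection has an uninformative velocity estimate and
uses the widest gate. Candidates are gated at
`gate = tier_speed·dt + 3·measurement SD` and matched one-to-one by the
Hungarian algorithm on squared innovation distance. Tracks confirm after 3
hits, terminate after 2 consecutive misses, and need 5 measured positions to
be kept. Finished tracks are Rauch–Tung–Striebel smoothed; per-step
velocities are finite differences of the smoothed positions, timestamped by
the later frame. Steps above the 15 mm/s velocity span break the track
(a 20 mm/s mover also exceeds every gate, so it never forms a confirmed
track in the first place — the span is enforced both ways).

## Maps, bed separation, statistics

Track positions accumulate on a 4× upsampled grid into integer density
images; the velocity map colors each high-resolution pixel by the mean
velocity vector of its contributing steps (hue = direction on the color
wheel, brightness = speed / vmax saturating at vmax; display vmax 20 mm/s
cortex, 5 mm/s medulla — a display scale independent of the tracking span).

A track's region is the one containing the majority of its positions; its
direction is the length-weighted circular mean of its in-region steps.
Directions within half the sector span of the region's mean arterial angle
are arterial, within the same span of the opposite direction venous, and
otherwise excluded. The sector span is read as a TOTAL width — 125° in the
cortex, 90° in the medulla — because a ±125° reading would make the arterial
and venous sectors overlap; a half-width reading remains available through
`FlowSector.span_deg`.

Speed samples are per track position. Dynamic displays use centered 30-s
moving averages stepped every 1 s, with empty windows left missing. Scan
comparisons align scan 2 to the injection time (mean over
`[t_inj, t_inj + 410 s]`; display from 50 s before injection; scans 1/3 use
their first 410 s); the scan-2 sub-periods are the first 30 s, the
contiguous 30-s window with the lowest mean MAP (earliest on ties), and the
last 30 s of the aligned window. Speeds are log-transformed in the cortex
and square-root-transformed in the medulla before testing. Paired t,
one-way repeated-measures ANOVA with Greenhouse–Geisser correction
(ε from the eigenvalues of the double-centered condition covariance,
clipped to `[1/(k−1), 1]`), Tukey's multiple comparisons on the
within-subject error term (studentized range, df = (k−1)(n−1)), and squared
Pearson correlation are implemented from their definitions and
cross-checked in the tests against direct-formula oracles and pingouin.

## Problem sizes and the reference session

The reference session is a desk-scale replica: three 120-s scans at 54 Hz
(6 480 frames per channel per scan) with injection 30 s into scan 2 and the
remaining 90 s as the post-injection analysis window; full-scale 410/460-s
windows are the same code with larger durations and are exercised separately
in the alignment tests. Multi-subject statistics run at the trajectory level
(no rendering): per-subject baselines scale by a lognormal-free Gaussian
factor with 24% coefficient of variation (the reported spread of cortical
arterial baselines across animals) plus small per-subject jitter of the
prazosin response multipliers.

## What the phantom does and does not show

Passing tests demonstrate that the chain — detection, sub-pixel
localization, motion compensation, gated Kalman tracking, direction-based
bed separation, and period statistics — recovers commanded velocities and
detects a prazosin-sized effect under controlled conditions: straight
vessels, isotropic Gaussian PSF, white noise, purely axial periodic motion,
dilute non-interacting bubbles. Real data add curved and out-of-plane
vessels (2-D speeds are biased low), anisotropic and depth-dependent PSFs,
speckle-correlated noise, overlapping bubbles at clinically used
concentrations, and non-periodic motion; none of these are claimed to be
covered. Volume flow, vessel diameters, and pulsatility-based artery/vein
separation are out of scope.

## Numerical choices

Randomness flows through one `numpy` Generator per simulation (seeded;
bit-reproducible). Window predicates use ±1 ns-scale epsilons so integer
second boundaries are inclusive. The ZNCC parabolic refinement is clipped
to ±0.5 px and skipped at a perfect-correlation peak so identical frames
yield an exactly zero field. Degenerate statistics (zero-variance
differences, constant RM-ANOVA data, zero-variance correlates) are flagged
rather than silently propagated as NaN.
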