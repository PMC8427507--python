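# Methods

This note documents the models, conventions, and numerical choices behind
`spinegait`, and what the synthetic-trial generator does and does not
emulate.

## Pose model and axis conventions

A bone pose is six numbers: rotations in degrees about body axes — rx
(axial, craniocaudal axis), ry (lateral, ventrodorsal axis), rz (sagittal,
laterolateral axis) — and translations in cm along the same axes (tx
craniocaudal, ty ventrodorsal, tz laterolateral).  Sign conventions, fixed
in one place:

| DOF | positive direction |
|-----|--------------------|
| rx  | pelvis tilts right side down (caudocranial view, clockwise) |
| ry  | cranial end swings left |
| rz  | anteversion (cranial tilt) |
| tx  | cranial |
| ty  | dorsal |
| tz  | left |

Rotation matrices are built with the intrinsic Euler sequence
rz → ry → rx.  Published rotoscoping rigs rarely document their Euler
order; at the amplitudes of symmetrical gaits (< 15° peak-to-peak) the
order only matters at second order.  Concretely, swapping the full sequence
(XYZ vs ZYX) changes recovered angles by at most ~0.5° at 5° amplitude,
shrinking quadratically — below the ~1.5° measurement accuracy of the
rotoscoping method for all gait-scale motion.  The order is nevertheless
centralised (`kinematics.EULER_ORDER`) so it can be switched.  Orientations
within 1° of the ry gimbal singularity are rejected rather than wrapped;
physiological data never approach them.

Relative motion follows the adjoining-caudal-bone convention: L6 in L7's
frame, L7 in the sacrum's frame, with the sacrum modelled as rigidly
attached to the pelvis (sacroiliac motion is below resolution and the two
bones overlap in lateral projections).  The pelvis itself is reported in
the world (treadmill) frame.

## Synthetic trials

The generator stands in for rotoscoped recordings that are not publicly
available.  Each of the 18 bone × DOF channels is a periodic waveform
defined by extremum anchors (phase of cycle, value) interpolated with a
periodic monotone cubic (PCHIP).  Monotone interpolation is used instead of
a harmonic sum because the published waveforms have asymmetric extremum
placements (e.g. sagittal pelvic maxima at 2.8 % and 54.3 % of the cycle)
that a small Fourier series cannot pin without ringing; between alternating
anchors PCHIP is monotone, so the noise-free curve attains exactly the
anchor extrema and its range equals the stated ROM.

Anchor phases and ROMs encode the published walk/trot summary tables:
duty factors 0.7 (walk) and 0.4 (trot; a 0.5 variant for the one deviant
animal is included but off by default), pelvic ROMs (e.g. rx 12.1°/6.1°,
ry 10.9°/9.0°, rz 7.8°/6.7°), intervertebral ROMs of 2–5° rotation and
0.1–0.2 cm translation, and the printed extremum phases where given.
Choices the source tables do not determine, made once as realistic
defaults:

* stride durations 1.0 s (walk) and 0.5 s (trot), consistent with the
  treadmill speeds (0.8 / 2.4 m/s) and large-dog stride lengths;
* footfall phase offsets: idealized lateral-sequence walk (LH, LF, RH, RF
  at quarter-cycle spacing) and diagonal-couplet trot (LH+RF, RH+LF);
* anchor phases for channels described only as "irregular" or "no
  reproducible pattern" (L7/L6 ry, walk-gait L7/L6 rz, most intervertebral
  translations).  The walk L7 rz anchors sit near quadrature with pelvic rz
  so that a sagittal pelvis–L7 inverse oscillation appears only at a trot,
  matching the observation;
* the published walk pelvic ty extremum phases do not alternate max/min
  around the cycle (an artefact of averaging across animals); the second
  minimum is moved to 92 % to restore alternation, keeping the three other
  printed phases;
* trot pelvic rz reuses the walk anchor phases (no trot phases published).

Stochastic components, all driven by one seed:

* **ROM jitter** — per-stride amplitude scale, SD from the printed ± values
  (capped at 50 % of the mean for trot pelvic rx, whose printed SD of 5.7°
  on a 6.1° mean would otherwise produce sign-degenerate strides);
* **phase jitter** — per-stride common shift of all anchors, SD from the
  printed TOO SDs (one value per channel);
* **timing jitter** — duty factor SD 0.01 (printed) and stride-duration SD
  2 % of the mean;
* **frame noise** — i.i.d. Gaussian, default 0.5° / 0.03 cm, one third of
  the stated measurement accuracy (1.5° / 0.1 cm): the analysis treats
  sub-accuracy wiggles as non-events, so the generator stays below them;
* **treadmill drift** — the near-linear craniocaudal pelvic translation is
  realised as a periodic within-stride ramp (cranial drift, reset around
  touch-down), giving the printed 2.6 cm per-stride range without unbounded
  growth; a `drift_per_stride` term (within-stride ramp added on top) is
  available but zero in all presets.

Vertebral channels are generated in their caudal-neighbor frames and
composed into world poses through the rigid-body chain, so analysis must
invert the chain to recover them.

What the generator does **not** emulate: inter-animal differences (one
template set per gait, not four dogs), ipsilateral limb interactions and
tail-motion interference (the secondary spectral peaks of real recordings),
correlated or pose-dependent rotoscoping error, and any forward dynamics.
Passing round-trip tests therefore demonstrates that the analysis chain is
correct and noise-robust under the stated conditions — not that it would
resolve arbitrary real-world pathology.

## Stride normalization

Strides are segmented at reference-limb (left hindlimb) touch-downs; the
duty factor is the mean stance fraction.  Signals are warped per stride
with the minimal alignment that matches stance/swing shading across
strides: piecewise-linear, stance → [0, 100·DF] %, swing → [100·DF, 100] %,
then linearly resampled onto a fixed 101-point grid (0–100 % inclusive, the
conventional grid in gait analysis).  The warp target defaults to the
trial-mean duty factor; a fixed cohort value can be configured instead
(whether the original analysis warped to each animal's own duty factor or a
cohort mean is not documented).  Warping is monotone, so extremum values
are preserved to interpolation tolerance.  Rotations are never detrended;
per-stride linear detrending is available for treadmill-dominated
translations but off by default.

## Descriptors

**ROM.**  `range_of_motion` is the plain peak-to-trough range of a curve.
At trial level, `summarize_trial` estimates per-stride ROM differently: a
raw per-stride max-minus-min is the maximum of ~100 noisy samples and
overestimates small amplitudes by an extreme-value bias comparable to the
frame noise (≈ 0.5–1°), which would swamp the 2–3° intervertebral signals.
Instead, the per-stride ROM is a *registered amplitude*: the trial mean
curve is computed; its reference ROM is read between its detected extrema
after a peak-preserving local-quadratic (Savitzky–Golay, window 7 points,
order 2) smoothing; each stride's amplitude is then the least-squares scale
of the stride curve against the circularly best-aligned mean curve (shift
search ± 33 % of the cycle absorbs stride-to-stride phase jitter).  This
estimator is unbiased to first order in the noise, recovers noise-free
ROMs to < 2 %, and its across-stride SD tracks the generated amplitude
jitter.  ROM is reported per stride (mean ± SD), matching how such tables
are conventionally printed.

**Extrema and TOO.**  Direction changes are detected on the circularly
continued curve after a centred moving average over 5 % of the stride
(window configurable): peaks/troughs with topographic prominence ≥ the
threshold (defaults: 1.5° rotation, 0.1 cm translation — the measurement
accuracy, below which momentary reversals are not genuine direction
changes), alternation enforced by discarding the weaker of same-kind
neighbors, and phases refined on the unsmoothed curve with a three-point
parabola.  TOO statistics across strides use circular mean and SD on the
0–100 % circle (extrema such as 96 ± 4 % straddle the wrap), with a
√(n/(n−1)) correction so small-dispersion values match the sample-SD
convention of printed tables.  Strides whose extremum count differs from
the reference set are excluded from TOO aggregation with a log notice
(matching of unequal extremum sets across strides has no documented
procedure; nearest-circular-phase matching within kind is the stand-in).

**Phase class.**  1/2/3 max–min pairs per cycle → mono-/bi-/triphasic;
anything else (including no supra-threshold extremum) is irregular.

## Coupling

Spearman's ρ is used for all curve–curve association (ranks are robust to
the monotone distortions a time warp can introduce); strength labels are
|ρ| < 0.4 mild, 0.4–0.7 moderate, > 0.7 strong (the verbal labels carry no
published thresholds; these are config-exposed).  Stride/bone/animal
groupings are summarised by the median |ρ| over distinct pairs.

Fourier analysis operates on the *unwarped* continuous recording truncated
to a whole number of strides (≥ 2), mean removed, with the frequency axis
in cycles per stride; phase warping would alias stride-frequency content
and is never applied here.  The decomposition is written as signed cosine
and sine amplitudes; because recordings start at a reference touch-down,
the cosine sign encodes phase at stride start, and two bones whose cosine
amplitudes at the shared dominant (non-DC) frequency have opposite signs
oscillate inversely.  Both amplitudes must exceed a noise floor (default
10 % of the larger main amplitude) or the relation is reported
indeterminate.  Monophasic channels have their main oscillation at
1 cycle/stride and biphasic channels at 2, which the tests verify.

## Numerical details and edge cases

* 101-point phase grid; anchor recovery tolerances: ROM within 2 %, TOO
  within 1 percentage point (grid resolution plus parabolic refinement).
* Gimbal guard at |ry| ≥ 89°; Euler round trips are exact to 1e−9° inside
  it.
* Rotation-matrix orthonormality is validated at construction (det +1).
* Degenerate inputs raise typed errors rather than returning NaN: empty
  curve lists, zero-variance rank correlations, signals shorter than two
  strides, events violating touch-down/lift-off alternation, pose CSVs
  with missing frames or unknown bones.
* All randomness flows from `TrialSpec.seed` through `numpy` Generators;
  identical seeds give byte-identical outputs.

## Problem sizes

Synthetic trials default to the study's stride counts (6 walk, 9 trot) at
100 Hz — ample for waveforms with ≤ 2 cycles/stride of structure.  The
noise-robustness checks average 20 seeds per gait, enough to pin 20-seed
means well inside one stride-jitter SD for every channel.

## Known limitations

* One template set per gait: the pronounced inter-dog variation of real
  recordings (and GSD 3's deviant trot) is represented only by the optional
  0.5-duty-factor preset variant, not by per-animal templates.
* The registered-amplitude ROM estimator assumes strides share a common
  waveform up to shift and scale; for genuinely pattern-free channels it
  degrades toward the (biased) range of the mean curve.
* Inverse-oscillation detection is a sign test at one frequency; no
  coherence, phase-lag, or wavelet analysis is attempted.
* No footfall detection, 2D–3D registration, or image handling: poses and
  events are inputs.
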