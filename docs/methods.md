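# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `run2d`, in the spirit of a methods section a user could
cite when describing an analysis run with the package.

## Signal conditioning

**Missing samples.** A key-point detection with confidence below 0.05, or
an absent record, is treated as missing. Pose networks emit low-confidence
junk near occlusions; a hard floor is simpler and more predictable than
confidence weighting. The floor is a module constant
(`trajectories.CONFIDENCE_FLOOR`).

**Gap filling.** Missing interior frames are filled per coordinate with a
cubic spline (`scipy.interpolate.CubicSpline`, not-a-knot) through the
present frames. Endpoints must be present — extrapolating a spline at the
ends of a recording is unstable, so callers are told to trim instead. At
least 3 present samples are required (with exactly 3 the interpolant
degenerates to a parabola, which is still well defined). Gap fractions
above 10 % per landmark are logged as warnings.

**Low-pass filtering.** Trajectories are smoothed with a zero-lag
4th-order Butterworth low-pass, cutoff 6 Hz, applied to coordinates before
angle computation. A zero-lag Butterworth is defined by zero phase and the
squared single-pass magnitude, i.e. gain `1/(1+(f/f_c)^(2n))`. We apply
that exact response spectrally (real FFT, multiply, inverse FFT) after
odd-reflection padding of about `3·f_s/f_c` samples per end, rather than
running `filtfilt` with a bilinear-transform design: the bilinear design's
gain warps away from the analog curve as frequency rises (≈16 % low at
10 Hz and orders of magnitude off deep in the stopband at 30 Hz for
f_s = 100 Hz), whereas the spectral application matches the closed form to
machine precision at all frequencies. For gait signals, whose content sits
far below Nyquist, the two are practically indistinguishable; the spectral
route simply makes the filter's defining property exact. No cutoff
compensation is applied for the implied double pass — the nominal 6 Hz is
the two-pass cutoff, matching common gait-lab convention. DC gain is
exactly 1, the operator is linear, and it commutes with time reversal.

## Hip joint centre

The marker-based path has no hip landmark, so the hip joint centre is
regressed from pelvis geometry (Davis/Newington–Gage model). Per frame a
pelvis frame is built from the four iliac-spine markers: origin mid-ASIS,
lateral axis along the ASIS line, anterior axis from mid-PSIS toward
mid-ASIS (orthogonalised), vertical by the right-hand rule. The centre is
offset from the origin by

    C     = 0.115·L − 15.3 mm         (L = leg length)
    x_dis = 0.1288·L − 48.56 mm       (ASIS–trochanter distance)
    ant   = C·cosθ·sinβ − (x_dis + r)·cosβ
    lat   = d_ASIS/2 − C·sinθ          (toward the analysed side)
    vert  = −C·cosθ·cosβ − (x_dis + r)·sinβ

with θ = 28.4°, β = 18°, r the marker radius and d_ASIS the inter-ASIS
distance (measured, or taken from the markers). All constants are fields
of `HipCentreParams`, so other published variants can be substituted. For
a 900 mm leg and 240 mm inter-ASIS distance the offsets are
(−46.7, +78.1, −96.8) mm — a few millimetres' difference from other
regression variants is far below the between-system differences the
agreement statistics target.

## Joint angle conventions

All angles are computed from 2D (anterior = +x, up = +y) landmark tracks;
the marker path projects its (filtered) 3D markers and regressed hip
centre onto the sagittal plane first, then both paths share one code
path.

* **Ankle** — signed angle from the shank direction (knee→ankle) to the
  foot direction (ankle→big toe), minus the same raw angle averaged over a
  ≥ 10-frame neutral static trial. Dorsiflexion positive, neutral
  standing 0°. The static correction absorbs the arbitrary foot-segment
  direction (toe marker vs big-toe key point).
* **Knee** — 180° minus the included angle at the knee between the rays to
  hip and ankle. Flexion positive, full extension 0°; unsigned, so it
  lives in [0°, 180°).
* **Hip** — signed angle of the thigh (hip→knee) relative to the extended
  trunk line (shoulder→hip). Flexion (thigh anterior to the trunk line)
  positive, 0° when thigh and trunk line are collinear. The trunk line is
  a pelvis surrogate: a single side-view camera cannot resolve pelvic
  tilt, which is the main systematic difference from 3D pelvis-femur hip
  angles.

The static neutral correction is applied to the ankle only by default
(`neutral_correction_joints`); knee and hip use their geometric zeros.
All three angles are invariant under translation, rotation and uniform
scaling of the pose (the references rotate with the body), which is why
pixel-space key points and millimetre-space markers can share the code.

## Cycle segmentation, selection and averaging

On a treadmill, ground contact coincides with the ankle reaching its most
anterior position, so cycle boundaries are consecutive peaks of the
(filtered) ankle anterior coordinate, found with a 0.5 s minimum peak
separation (cadences up to 120 cycles/min; the two protocol speeds imply
periods of ~0.68–0.75 s). Peak locations are refined to sub-frame
precision with a three-point parabola: at 80 cycles/min and 60 Hz the
cycle period is an exact integer number of frames, so integer peak indices
would impose the *same* phase offset (up to half a frame, ~1 % of the
cycle) on all averaged cycles, which is the dominant recovery error in
noise-free end-to-end tests (~1–1.6° RMSE unrefined vs ~0.1–0.5° refined).
`segment_cycles(refine=False)` restores integer boundaries.

The butt-kick synchronization event is the global maximum of the ankle
vertical position inside the first 5 s, accepted only if it strictly
exceeds the maximum of the signal outside that window (a steady running
peak can then never trigger; the comparison percentile is a parameter for
recordings with late outliers). With a trigger, the first cycle starting
after it plus one more are discarded and the following 20 analysed;
without one, the first two cycles of the recording are discarded instead.

Each selected cycle is resampled by linear interpolation onto 101 points,
0–100 % inclusive (the standard grid for 1D gait statistics), and the
point-wise mean and sample SD (n−1) across the 20 cycles form the
participant's curve.

## Agreement statistics

For two matched curve sets: the per-percent mean absolute error across
participants, and the per-participant RMSE over the grid. Testing three
joints at family alpha 0.05 uses the Šidák-adjusted per-joint alpha
`1−0.95^(1/3) ≈ 0.017`.

The 1D two-way repeated-measures ANOVA (factor A = system or clothing,
factor B = speed, both within participant) computes the classical
sums-of-squares F statistics point-wise along the cycle; error terms are
the factor-by-participant interactions. Family-wise thresholds come, by
default, from the permutation distribution of the maximum F over the 101
nodes under per-participant sign flips of the within-participant contrast
(exact for a 2×2 within design; the observed labelling is always included
so the test cannot be anti-conservative). The permutation seed is
mandatory and recorded in the result. ≥ 1000 permutations are
recommended; fewer than 100 is recorded as a warning in the result. With
n participants the smallest achievable p-value is `2/2^n`, so detecting
anything at alpha 0.017 needs n ≥ 7. `method="rft"` instead solves for
the threshold using the expected Euler characteristic of a smooth 1D F
field (point probability plus resel count times the 1D EC density), with
smoothness estimated from the gradients of the normalized residuals.
Supra-threshold clusters are maximal runs of cycle percentages with F
strictly above the threshold. Normality of the contrasts is assessed
per node (D'Agostino–Pearson) and reported on the result object
(`normality_min_p`) and in debug logs; it does not gate the analysis,
since the permutation route does not require it.

## The synthetic runner

The generator drives a planar four-segment chain (trunk line 500 mm,
thigh 440, shank 430, foot 150) with periodic joint-angle templates —
truncated Fourier series (mean + 3 harmonics) over cycle phase — whose
conventions exactly invert the analysis conventions above, so
noise-free generated frames must round-trip to the templates. Default
templates resemble published treadmill running curves (hip ≈ −10…+40°,
knee ≈ 10…90°, ankle ≈ ±20°); harmonics above the third are omitted
deliberately, keeping template content below ~4.5 Hz where the 6 Hz
two-pass filter is transparent. The protocol speeds map to cadences of 80
(2.5 m/s) and 88 (3.6 m/s) cycles/min with slightly larger excursions at
the faster speed. The hip point oscillates ±25 mm horizontally (1× cycle
frequency) and ±45 mm vertically (2×).

Rendering produces a 100 Hz 3D marker stream (pelvis cluster positioned
rigidly so the hip-centre regression recovers the true hip point; leg and
acromion markers exactly on the joints) and a 60 Hz key-point stream
scaled to pixels (0.3 px/mm ≈ a 3 m camera at 720 px height), y-flipped to
image convention, with optional Gaussian pixel noise, per-frame dropouts
(never the first or last frame, so spline filling stays well posed) and
constant per-landmark biases (modelling e.g. acromion-vs-shoulder
localisation mismatch). The butt-kick is a one-cycle transient (knee to
172°, +35° hip flexion, stride oscillation damped by the same sin² weight)
whose ankle apex exceeds 1.5× the steady swing peak. Ground-truth
foot-strike times come from a 4001-point phase grid of the noise-free
ankle trajectory; the trigger time is the analytic apex of the transient.

What the generator does **not** emulate: out-of-plane motion and parallax,
soft-tissue artefact, temporally correlated or pose-dependent detector
error, occlusion structure, or appearance effects of clothing beyond a
constant bias. Passing end-to-end tests therefore validates the
*processing chain* — geometry, filtering, segmentation, averaging,
inference — not the pose-estimation network itself.

Curve-level cohorts for the statistics (`curve_panel`) add per-participant
constant offsets (SD 3°) and amplitude scalings (SD 5 %) to the joint
template plus independent Gaussian node noise (default 2°) per cell of the
2×2 design; a system effect can be injected as a constant offset confined
to a percent window. Under the null the two factor-A cells are
exchangeable within participant, which is what the sign-flip permutation
assumes.

## Problem sizes used in the checks

The automated checks run the pipeline on 30 s trials (≈ 39–44 cycles) at
both speeds, clean and with 2 px noise; sweep cadences 70–95 cycles/min ×
20 seeds × both sample rates for segmentation counts; use 200 null
cohorts (n = 30, σ = 2°, 500 permutations) for false-positive calibration
and 50 replicates for offset-detection sensitivity (n = 30, +10° over
40–60 % of the cycle, 1000 permutations). These sizes give stable
pass/fail behaviour at interactive runtimes.

## Known limitations

* Single runner, single side, sagittal plane only; no stance/swing
  sub-phase events.
* The hip angle's trunk-line reference differs systematically from
  pelvis-femur conventions; comparisons across conventions need care.
* The permutation test is specified for 2×2 within designs; factors with
  more levels or missing cells are out of scope.
* The RFT threshold assumes smooth Gaussian residual fields; with few
  participants or rough curves the permutation route is preferable (and
  is the default).
* OpenPifPaf JSON parsing covers the documented prediction layout (one
  frame per entry, first pose used); multi-person scenes are not
  disambiguated.
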