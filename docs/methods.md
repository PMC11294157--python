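# Methods

## Segment model

The trunk is treated as a rigid segment observed through midline skin
markers: CLAV (jugular notch), XP (xiphoid process), M-STRN (mid-sternum,
by construction the midpoint of CLAV and XP), T1 and T10 (1st and 10th
thoracic spinous processes).  The laboratory frame is right-handed with X
along the direction of progression, Y to the subject's left and Z
vertical; with that convention trunk flexion is a positive rotation about
Y, so tilt is signed flexion-positive and the small negative gait means
the pipeline reports correspond to a slightly extended standing lean.

**Anatomical frame (Definition Model).**  Virtual midpoints are formed
from the four defining markers — superior = mid(CLAV, T1), inferior =
mid(XP, T10), anterior = mid(CLAV, XP), posterior = mid(T1, T10).  The
longitudinal axis (superior − inferior, mapped to segment Z) is the
primary axis; the anterior reference (anterior − posterior) is
orthogonalised against it to give segment X, and Y completes the
right-handed triad.  The origin is the marker centroid.

**Technical frames.**  The M-STRN model uses the same midpoint recipe
with M-STRN substituted for XP.  The three-marker models use surface
vectors: No-Thorax takes longitudinal = mid(CLAV, T1) − M-STRN and
anterior = mid(CLAV, M-STRN) − T1; No-Sternum takes longitudinal =
mid(CLAV, T1) − T10 and anterior = CLAV − mid(T1, T10).  The longitudinal
direction is always primary because it is by far the best-conditioned
direction for markers that all lie near the sagittal midline.  The exact
recipe is a free design choice: for a rigid segment any recipe differs
from the anatomical frame by a constant rotation, which the calibration
absorbs, so noise-free kinematics are recipe-independent (this is
asserted to 1e-9 degrees in the tests).

**Calibration and tracking.**  In the static trial both frames are built
on time-averaged marker positions and the offset
`R_offset = R_tech^T R_anat` is stored; during dynamic trials the
anatomical orientation is estimated per frame as
`A(t) = R_tech(t) R_offset`.  Orientation comes from direct vector/cross-
product construction, not a least-squares rigid fit — matching how such
models are usually implemented in clinical pipelines; an SVD (Söderkvist–
Wedin) fit is deliberately out of scope.

**Angles.**  `A` is decomposed as `R_Y(tilt) · R_X'(obliquity) ·
R_Z''(axial)` — an intrinsic sequence whose first, lab-fixed ("permanent")
axis is the mediolateral Y axis.  Angles are global (segment-in-lab) with
no static-posture zeroing.  For motion confined to the sagittal plane the
tilt channel is identical under any ordering of the remaining axes (tested
against an alternative sequence).  A gimbal flag is raised when obliquity
comes within 1e-6 deg of ±90°; trunk motion in gait and jumping stays far
from that configuration.

## Smoothing

Marker trajectories are smoothed with a quintic spline penalising the
integrated squared third derivative.  The smoothing parameter is not set
directly: the user supplies a *predicted mean squared error* (the expected
measurement-noise variance, in mm²) and the parameter is found by
root-finding so that the trace-corrected residual estimate
`RSS(λ) / (n − tr A(λ))` equals that target within 1 %, with `A(λ)` the
hat matrix.  The residual is pooled over a trajectory's coordinates, so
one parameter smooths a marker's x/y/z jointly; the smoother is then a
single linear operator and is exactly equivariant under rigid rotations
and translations of the data (tested to 1e-6 mm).

Implementation: a quintic B-spline interpolation basis (square design
matrix `B`), penalty `Ω` assembled by exact Gauss quadrature of the
third-derivative basis products, and the generalised eigendecomposition of
`L^{-1} Ω L^{-T}` with `B^T B = L L^T` (Demmler–Reinsch).  Each parameter
evaluation is then O(n), and the factorisation is cached per time grid,
which makes cohort smoothing cheap.  Two numerical safeguards matter:
eigenvalues at the numerical noise floor (< 1e-13 of the largest) are
clamped to zero, and the exact quadratic component of the data — which
spans the penalty null space — is removed analytically before the solve
and added back afterwards.  Together these keep two contractual limits
exact: quadratic trajectories are reproduced unchanged at any smoothing
level, and a zero predicted MSE returns the interpolating spline.

Degenerate inputs: fewer than 12 frames and non-uniform sampling are
rejected; a target residual unreachable even at maximal smoothing clamps
to the feasible end of the parameter range.

The pipeline default is 10 mm², the value commonly used for optical
capture data.  The predicted MSE should match the noise actually present:
in the parameter-recovery analyses the smoother is therefore given the
generator's true noise variance (0.25 mm² for σ = 0.5 mm).  Forcing a
10 mm² residual onto much cleaner data over-smooths and introduces
degree-scale ripple around the landing transient of a jump.

## Events and metrics

Gait metrics (mean, max, min, ROM of tilt) are computed over one full
stride, heel-strike to ipsilateral heel-strike, from annotated events.
DVJ events are detected from a heel-proxy marker height: initial contact
is the first frame crossing below 30 mm while descending, take-off the
first later frame crossing back above while ascending (the threshold is
configurable and annotations may always override detection).  DVJ
max/min/ROM are taken over [initial contact, take-off]; the DVJ "mean" is
the tilt at maximum descent — the frame of lowest trunk-origin height in
that window, first index on ties.  ROM is max − min by construction.

## Agreement statistics

Each tracking model is compared with the Definition Model per task and
metric across participants:

- **Mean difference** — the mean of *absolute* per-participant
  differences.  (Signed averaging is ruled out internally: reported gait
  mean differences exceed the corresponding group-mean gaps, which is
  impossible for a signed mean.)
- **Wilcoxon signed-rank** — zeros dropped (classic convention; a Pratt
  option exists), exact two-sided p for n ≤ 25 via a dynamic programme
  over doubled mid-ranks (ties handled exactly), tie-corrected normal
  approximation beyond.  The test oracle is full 2^n sign enumeration.
- **ICC** — two-way mixed-effects, single measurement.  The default is
  absolute agreement, McGraw–Wong ICC(A,1) = (MSR − MSE) /
  (MSR + (k−1)MSE + (k/n)(MSC − MSE)), with the 95 % CI from the F
  distribution; the consistency form ICC(C,1) is available for
  sensitivity checks.  Bands: poor < 0.50 ≤ moderate < 0.75 ≤ good ≤ 0.90
  < excellent (0.90 itself maps to "good" since "excellent" is defined as
  strictly above 0.90).  Degenerate cases (identical columns, zero
  between-participant variance) are resolved explicitly rather than left
  to 0/0 arithmetic.
- **Sex summaries** — female/male group means rounded to two decimals and
  signed male-minus-female differences of the rounded means; no
  inferential testing is attached to them.

Quality control precedes everything: a participant is excluded when any
trial has more than 10 % of frames with at least half of *all* markers
simultaneously missing (session-level "flicker"), while occlusion confined
to individual trunk markers never triggers exclusion.

## Synthetic data

The generator emulates the study conditions the analysis assumes, not a
physiological simulation.  Per participant it produces one static, one
gait and one DVJ trial at 240 Hz from a stature-scaled rigid template
whose anterior face is inclined (the xiphoid sits forward of the jugular
notch) and whose local coordinates are canonicalised so the template's own
anatomical frame is the identity — profile angles are then anatomical
angles with no static offset.

- **Gait** tilt: mean + (ROM/2)·sin(2πt/T), two 1.1 s cycles, with small
  obliquity/axial wobbles; per-sex parameter draws centre on the reported
  group statistics (e.g. gait ROM ≈ 5.0° female / 3.4° male; means ≈
  −1.8/−1.4°), clipped to physiological brackets (ROM ∈ [2, 8]°, mean ∈
  [−6, 2]°).
- **DVJ**: drop from a 31 cm box placed half the participant's stature
  from the landing target, first landing, flight.  Tilt is a raised-
  cosine-power pulse supported on [initial contact, take-off] peaking at
  maximum descent; the excursion parameter is drawn per sex (≈ 38.3°
  female, 52.8° male, SD 11–14°, clipped to [20, 70]°) over a slightly
  extended base (≈ −2°).  All motion primitives are C²-smooth (quintic
  smoothstep ramps, cos⁴ pulse): real kinematics are jerk-limited, and
  this keeps spline attenuation of noise-free metrics below 0.05°.
  Ground-truth contact events are defined by the same 30 mm heel-height
  proximity rule the detector uses, so detector accuracy is a ±1-frame
  discretisation statement.
- **Artifacts**: per-marker soft-tissue sinusoid (default 3 mm at 1.5 Hz,
  random phase and direction), a constant sports-bra XP displacement in
  dynamic trials only (default 15 mm for female templates, directed 20°
  anterior of superior — along the band, with a small lift off the chest;
  a purely superior shift on a symmetric template would be exactly
  invisible to the midpoint recipes), isotropic Gaussian noise (default
  σ = 0.5 mm), scripted occlusion episodes and optional full-set flicker
  (30 % of frames) for seeded QC-failure participants.  Every draw is
  seeded; identical configurations are bit-identical.
- A `center_dvj_rom` option recentres each sex's excursion draws on the
  group target (iterating recentring against the clipping bounds), so the
  realised group mean equals the target exactly and recovery checks
  measure pipeline error alone.

What the generator does **not** model: genuine intra-segmental (non-rigid)
trunk deformation, correlated or task-dependent soft-tissue artifact,
lower-limb kinematics beyond the heel proxy, ground-reaction forces, and
the real distributional shape of bra-induced marker displacement (the
constant offset is a stand-in).  Consequently, passing tests demonstrate
the correctness of the *pipeline* — frame construction, calibration
algebra, smoothing, events, statistics — under the stated noise model;
they do not certify how large between-model discrepancies are on real
athletes, where non-rigid motion dominates.

## Problem sizes and numerical choices

Cohort analyses in the tests and the acceptance script use 8–20
participants with one trial per task (gait ≈ 530 frames, DVJ ≈ 790 frames
at 240 Hz) and 100-replicate recovery/smoothing studies; these sizes give
sub-minute runs while leaving every statistic well-identified.
Tolerances: rotation orthonormality 1e-9; parallel-vector threshold 1e-6
rad; rigid-equivalence and calibration-closure assertions 1e-9 deg;
smoothing residual matching 1 % relative; occlusion gaps ≤ 0.1 s are
linearly interpolated before smoothing, longer gaps propagate as missing
frames and excluded metrics input.  Ties: first index wins at maximum
descent; Wilcoxon zeros dropped; band edges as listed above.

## Known limitations

- Only sagittal-plane (tilt) outputs are validated; obliquity and axial
  rotation are computed but midline marker sets are ill-suited to them.
- The exact axis recipes of the original clinical model are not public;
  only rigid-body-equivalent behaviour is reproducible, and recipe choice
  does affect how *non-rigid* artifact propagates into angles.
- The C3D reader covers the common Intel/float dialect with labelled
  points only (no analog channels, no integer scaling).
- File-based cohorts (CSV dialect) carry no ground truth, so gait trials
  need sidecar annotations and DVJ events fall back to detection.
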