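# Methods

This note documents the model conventions, the synthetic study conditions,
the numerical choices and the limitations of `spinemc`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The rigid-body model

A subject-specific spino-pelvic model is a single serial kinematic chain:
pelvis/sacrum → L5 → … → L1 → T12 → … → T1 (18 bodies), connected by 17
spherical joints (L5_S1 … T1_T2), each with three rotational DOFs. A free
6-DOF base joint places the pelvis in the ground frame; its coordinates are
solved by inverse kinematics but not counted among the 51 reported joint
angles. Coordinates follow the motion-lab convention x mediolateral,
y inferosuperior, z posteroanterior; all rotations use the body-fixed
(intrinsic) x→y→z Euler sequence, so the three angles are
flexion-extension (FE), axial rotation (AR) and lateroflexion (LF). Units
are mm and degrees throughout; SVA is reported in cm.

Three groups of model inputs are operator-dependent, forming a fixed-layout
294-entry parameter vector:

| block | size | units | frame |
|---|---|---|---|
| marker positions | 28 × 3 | mm | attached body |
| body alignment position | 18 × 3 | mm | ground |
| body alignment orientation | 18 × 3 | deg | body-fixed relative |
| joint position | 17 × 3 | mm | parent body |
| joint orientation | 17 × 3 | deg | body-fixed relative |

### Two poses per segment: the isolation contract

Each segment keeps an immutable *chain pose* (the static model-building
pose realised by the joint chain at zero joint angles) and an operator
*alignment pose*. Landmark ground positions are mapped through the relative
transform between the two. Consequences, both deliberate:

- **Body perturbations move landmark geometry only.** They displace the
  spino-pelvic landmarks (endplate centres/normals, body centres, sacral
  plate, hip centres) but touch neither joint frames nor marker locals, so
  marker-driven IK is bitwise unaffected. This isolation is what makes body
  alignment the least influential component in the uncertainty analysis —
  the behaviour expected of a framework in which the alignment is fixed by
  radiographic reconstruction and the joints are defined on top of it.
- **Joint perturbations preserve the static pose.** A joint frame offset
  (position/orientation in the parent) is accompanied by the compensating
  update of the fixed child-side offset, so at zero joint angles nothing
  moves; during motion the rotation centre and axes differ, which is
  exactly how redefining a joint should act. A corollary worth knowing: a
  frame rotation about the joint's own motion axis commutes with the joint
  rotation (q′ = R(δ)⁻¹R(q)R(δ) = R(q)) and has no kinematic effect on a
  pure single-axis motion; offsets about the other axes re-express the
  motion in tilted axes with effect ≈ sin(q)·sin(δ).

Baseline (averaged) models use the arithmetic mean for every position and
the quaternion chordal L2 mean (largest-eigenvector method, scipy's
`Rotation.mean`) for orientations — unique and order-independent at the
few-degree dispersions operator variability produces. Averaging assumes the
variants share a model-building chain pose, which holds for everything this
package constructs (operator variants are perturbations of one subject's
model); the averaged joints' child-side offsets are re-derived from that
shared pose so the average remains kinematically consistent.

## Inverse kinematics

Per frame the solver minimises Σᵢ wᵢ‖xᵢ_obs − xᵢ_model(q)‖² over the 57
generalized coordinates with a damped (Levenberg-style) Gauss-Newton
iteration on an analytic geometric Jacobian. Numerical choices:

- damping floor 1e-6 on the normal equations, increased ×10 on overshoot
  and relaxed ×2 on success; iteration cap 200; convergence when the
  relative cost change is ≤ 1e-8 *and* the step is below 1e-7 rad/mm;
- frame 0 starts from the static model pose, later frames warm-start from
  the previous solution;
- a soft quadratic prior (0.1 mm²/rad², scaled by the mean marker weight)
  pulls toward the warm start. Rationale: with ~1.6 markers per vertebra,
  some multi-joint angle combinations move no marker at all (e.g.
  long-wavelength alternating lateroflexion patterns); without the prior
  those combinations random-walk under noise and perturbation, up to full
  360° Euler-branch jumps. The prior pins them to the previous frame while
  its pull on well-observed DOFs is parts in 10⁴ of the inter-frame step
  (leverage² ≈ 10³–10⁵ mm²/rad² against 0.1). Because damping and prior
  scale with the mean weight, rescaling all marker weights rescales the
  whole objective and leaves the iterate sequence exactly unchanged;
- frames that hit the iteration cap are flagged; more than 5% flagged
  frames raises an error.

Filtering is a 4th-order Butterworth design applied forward-backward
(`sosfiltfilt`), i.e. zero phase with the squared magnitude response; the
moving average uses shrunken edge windows to avoid endpoint bias, which
matters because ROM is defined from the first and last frames; time
normalization is linear interpolation onto 100 points with endpoints
preserved exactly, so ROMs are invariant to it.

### Spino-pelvic parameter definitions

The six parameters are computed per frame from model landmarks in the
sagittal (y–z) plane; the exact clinical definitions used with the original
framework are not published in full, so these are the standard literature
conventions, and the signs are package conventions that cancel in ROMs:

- **LL**: angle between the sacral-plate normal and the L1 superior
  endplate normal;
- **TK**: angle between the T1 superior and T12 inferior endplate normals;
- **SVA**: anteroposterior offset of the T1 body centre from the
  posterior-superior sacral endplate corner (anterior positive, cm). A T1
  rather than C7 plumbline is used because the model ends at T1;
- **PT**: inclination from vertical of bicoxofemoral midpoint → sacral
  plate centre (posterior positive);
- **T1-SPI / T9-SPI**: inclination from vertical of bicoxofemoral midpoint
  → T1/T9 body centre (anterior positive).

All six are invariant to global translation; LL and TK are invariant to a
rigid rotation of the whole model about x while PT and the SPIs shift by
exactly that rotation (equivariance), and the tests assert both.

## Reliability statistics

ICC(2,1) is computed from the two-way ANOVA mean squares (rows = subjects,
columns = sessions or operators), absolute agreement, single measure. The
95% CI follows McGraw & Wong with a Satterthwaite approximation for the
denominator degrees of freedom; the p-value tests H₀: ICC = 0 with
F = MSR/MSE on (n−1, (n−1)(k−1)) df — the convention of standard ICC
software. The test suite cross-checks all of ICC, CI and p against pingouin
on the same tables, and the ICC against a literal brute-force ANOVA.

The SD entering SEM = SD·√(1−ICC) is ambiguous in common usage; two
readings are implemented: SD of the per-subject between-session absolute
differences (default for two columns, the test-retest reading) and the
mean over subjects of each subject's SD about their own mean (default for
three or more columns, the inter-operator reading). Both are exposed via
`sd_between_columns(..., method=...)`. SDD = SEM·1.96·√2 exactly.
Classification: poor < 0.40 ≤ fair to good ≤ 0.75 < excellent, with the
boundary values inside "fair to good" (the closed interval as usually
printed).

## Monte-Carlo uncertainty propagation

Signed deviations of each operator model from its subject's baseline are
pooled over vertebral levels, operators and subjects into 15 groups
(component ∈ {marker, body, joint} × parameter ∈ {position, orientation} ×
direction ∈ {x, y, z}, markers having positions only). A Gaussian-kernel
density with Silverman bandwidth (0.9·min(SD, IQR/1.34)·n^(−1/5)) is fitted
per group on the *signed* deviations — perturbations must go both ways;
absolute values appear only in the deviation summary. Sampling picks a
source sample uniformly and adds kernel noise; with identical samples and
the default zero bandwidth floor the sampler is exactly degenerate, which
gives the clean zero-variance ⇒ zero-width-bands limit.

Each iteration draws one value per scalar parameter (independent across
parameters; no correlation structure is estimated), applies the 294-entry
perturbation to the baseline, re-runs IK on the same filtered trial,
normalizes to 100 frames, smooths, and stores the curves relative to the
baseline solution. Convergence: at candidate n, the running mean and SD of
every output variable (each of the 51 joint angles averaged over the
motion) over the last ⌈0.1·n⌉ iterations must lie within 2% of their values
at n; an absolute tolerance of 0.01° replaces the relative test when the
reference magnitude is below 0.5° (the relative criterion is ill-posed near
zero); checks start at n = 100. Percentile bands use linear interpolation
between order statistics (this matters at small n); t_σ=max ties break to
the earliest frame.

**Sensitivity factors** are Pearson correlations between the *magnitude*
of each sampled perturbation and the maximum over normalized time of the
absolute relative curve, per (parameter, DOF) cell — a 294×51 grid. The
magnitude convention is deliberate: for zero-mean symmetric perturbations
the response magnitude is an even function of the draw, so the signed
correlation is identically zero in expectation for every component and
can express no ranking; the magnitude-to-magnitude association is the
quantity a sensitivity factor is meant to capture. The signed variant
remains available (`magnitude=False`). Cells with zero variance on either
margin are reported as 0 with a quality flag.

## Synthetic study conditions

The generators define the conditions under which the pipeline is validated:

- **Geometry**: lumbar lordosis 40°, thoracic kyphosis 30°, sacral slope
  30° by default, linear inclination profiles, per-level height jitter 3%,
  and a deformity-severity scalar (default 0.3) adding a coronal C-curve
  (≤ 15 mm·severity), axial rotation (≤ 4°·severity) and lateral tilt.
  The generated static pose reproduces the requested LL/TK within 0.5°
  when measured by the package's own landmark definitions (tested).
- **Markers** (28): 4 pelvis (ASIS/PSIS-like), 17 spinous-process markers
  with an alternating ±25 mm lateral offset, 7 paraspinal markers on the
  thoracic levels T12–T1 (±45 mm, alternating sides). The layout is a
  stand-in for an unpublished clinical protocol and is designed for
  *observability*: purely midline markers leave long-wavelength
  lateroflexion combinations of mid-thoracic joints almost unobserved, and
  those artefact modes then dominate the uncertainty analysis. The
  thoracic-heavy paraspinal placement acts as a surrogate for the rib
  cage's stabilisation of the thorax, which the bare chain lacks; with it,
  the largest Monte-Carlo spread appears in the lumbar lateroflexion
  channels, the physiologically expected region.
- **Motion**: seated maximal forward flexion as a smoothstep ramp, total
  spinal flexion 45° distributed lumbar-dominantly (lumbar joints weight
  1.0, thoracic 0.3) plus 50° anterior pelvic tilt, 300 frames at 100 Hz
  by default, i.i.d. Gaussian marker noise of 0.5 mm SD (typical optical
  capture noise). These amplitudes put the six parameter ROMs in the range
  reported for maximal seated flexion in spinal-deformity patients. The
  per-level distribution of flexion in deformity is not known in detail;
  the level weights are a modelling choice.
- **Operator variants**: zero-mean Gaussian deviations per
  component/parameter/direction, with spreads chosen so that for three
  operators the median absolute deviations from the average match the
  reported inter-operator magnitudes (markers ≈ 0.11–0.12 mm, bodies
  ≈ 0.55–0.74 mm and 0.96–1.68°, joints ≈ 0.57–1.06 mm and 1.16–1.95°);
  for spread σ the deviation from a 3-model average has SD σ·√(2/3).
- **Retest jitter**: multiplicative amplitude and level-weight jitter
  (10%) and a 2° start-posture offset emulate execution variability
  between sessions while the underlying model stays fixed — the intrinsic
  component of test-retest variability, as opposed to the extrinsic
  modeling component.

What passing tests on these data do *not* show: soft-tissue artefact,
marker occlusion/relabelling, real operator behaviour (systematic or
skewed errors, level-dependent variability), rib-cage coupling, or any
cohort-specific reliability magnitude. Cohort-level ICCs and CI magnitudes
of the original study are not reproducible without its recordings; they
are covered at formula level and by parameter recovery on synthetic data.

## Problem sizes

The default validation runs are sized for a laptop-class single CPU: IK
recovery on 100-frame noise-free trials, ICC oracle checks on 200 random
4–10 × 2–3 tables, and a scaled-down Monte-Carlo of one subject, 300
iterations on a 50-frame trial (the convergence criterion typically needs
more iterations than 300 to fire at these settings, so the cap binds; the
degenerate zero-variance case converges at the minimum allowed n).

## Run manifests

Every CLI command writes a JSON manifest with the tool version, command,
seed, SHA-256 digests of the inputs and the settings in effect. Manifests
deliberately contain no wall-clock timestamp so that reruns with identical
inputs and seed are bit-identical end to end — reproducibility is treated
as a testable property, and the determinism test compares manifests and
CSVs byte for byte.

## Known limitations

- Intervertebral joints are purely rotational; no translational DOFs.
- No muscle forces, joint reaction forces or any dynamic quantity — the
  uncertainty analysis stops at kinematics.
- Deviation distributions are pooled across vertebral levels and subjects
  (as in the analysis this package implements); level- or
  subject-stratified distributions are out of scope.
- The Euler sequence warns above 80° on the middle (axial) angle; this is
  unreachable for physiological spine motion but the warning is there for
  misuse.
- TRC parsing covers the common tab-delimited dialect with blank cells for
  missing samples; gap filling is linear and limited to 5 frames.
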