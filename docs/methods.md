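# Methods

This note documents the models and numerical choices behind femgait: what
is simulated, which parameters matter, what the synthetic inputs do and do
not emulate, and where the design was genuinely open.

## The study design

The package isolates the effect of proximal femoral geometry on muscle and
joint loading by simulation. A single gait cycle (joint angles + ground
reaction force) is fed through a factorial family of lower-limb models
that differ only in femoral anteversion (AVA) and neck-shaft angle (NSA).
The morphing operator moves only femur-fixed points (muscle attachments
and bony landmarks) and leaves segment masses, inertias and joint centers
untouched, so inverse-dynamics joint angles and net moments are identical
across the family *by construction*; every downstream difference in
muscle force, co-contraction or contact force is attributable to geometry.
The default sweep is ±30° in 15° steps on both angles around the
reference femur (AVA 18°, NSA 123°), i.e. 25 models.

## The lower-limb template

A simplified single-leg (right) model: pelvis (fixed base) → femur (3-DOF
hip: flexion, abduction, internal rotation) → tibia (1-DOF knee) → foot
(1-DOF ankle). Frames are right-handed with X anterior, Y superior, Z
right; positive directions are flexion / abduction / internal rotation /
knee flexion / dorsiflexion. Seventeen muscle–tendon units cover the major
hip- and knee-spanning muscles (gluteus medius/minimus/maximus, iliacus,
psoas, tensor fasciae latae, piriformis, rectus femoris, lumped vasti,
semimembranosus, biceps femoris long and short head, adductor magnus,
gracilis, lumped gastrocnemius, soleus, tibialis anterior) as straight
lines through fixed via points; there are no wrapping surfaces. Attachment
coordinates, segment masses and inertias are adapted from published
gait-model anatomy and stored as a versioned JSON fixture
(`src/femgait/data/template_model.json`, native anthropometry 75.16 kg /
1.80 m, generated by `scripts/build_template_fixture.py`). Scaling to a
subject multiplies masses by the mass ratio, all lengths (geometry,
fiber/tendon lengths) by the height ratio, and inertias by mass × height².

Landmark conventions. AVA is measured as the signed angle between the
neck axis and the condylar *line*, both projected onto the plane
perpendicular to the shaft axis, positive anterior (range (−90°, 90°]);
NSA as the angle between the neck axis and the proximal-pointing shaft
direction. The template landmarks are a synthetic construction placed so
these operators return exactly 18° and 123°; they are measurement
scaffolding and deformation handles, not an anatomical femur surface (the
hip joint center is defined by the joint, not by the head landmark). The
neck base and the proximal shaft landmark coincide on the shaft axis,
which makes the two deformation rotations exact: rotating about the shaft
line changes AVA linearly and leaves NSA unchanged, rotating about the
neck-plane normal through the neck base changes NSA linearly and leaves
AVA unchanged, so one-shot deltas hit any target within numerical
precision (< 0.1° guaranteed, ~1e-14 observed).

Morphing region. Points within 0.4 of the shaft length from the proximal
end (configurable) rotate rigidly; the rotation order is AVA about the
shaft axis first, then NSA, fixed because finite rotations do not commute.
The rotation sense is established by a numeric probe (re-measure after a
1e-6 rad test rotation) rather than a hard-coded sign, which makes the
operator robust to any landmark layout.

## Muscle model

Rigid tendon, zero default pennation. Fiber length is MTU length minus
tendon slack length; the active force–length scalar is a Gaussian
f_L = exp(−((l̃−1)/w)²) with width w = 0.45, and the force–velocity
scalar is a Hill hyperbola in ṽ = v/(l_opt·v_max) with f_V(−1) = 0,
f_V(0) = 1, an eccentric plateau at 1.4, and C¹ continuity at ṽ = 0
(curvature constants 0.25 concentric, 0.08 eccentric); v_max = 10
optimal-fiber-lengths/s. Tendon slack lengths are set so l̃ = 1 at the
anatomical zero posture; optimal fiber lengths are deliberately on the
generous side (0.06–0.17 m) because a rigid tendon funnels the whole MTU
excursion into the fiber — shorter, more anatomical fibers would drive
f_L to zero over the gait range without compliant-tendon dynamics, which
are out of scope. After morphing (or any rescaling), l_opt and l_slack
are multiplied by the ratio of reference-posture MTU lengths between the
deformed and reference model, preserving normalized fiber length at the
reference posture; the operation is idempotent.

The maximum isometric force of every muscle is multiplied by 2 by default
(`fmax_scale`): with anatomical strengths, a heavy, fast-walking adult
drives several muscles onto the 100 % activation plateau, and doubling the
gait-model strengths is the established remedy. The acceptance suite pins
this factor.

## Gait synthesis

The generator emulates one cycle of healthy-adult barefoot walking at the
stated subject parameters (mass 73.1 kg, height 1.71 m, velocity
1.41 m/s). Joint-angle waveforms are truncated Fourier series (8
harmonics) fitted to hand-specified key points that qualitatively match
normal-gait kinematics — hence C∞-smooth and exactly periodic. Stance
occupies 60 % of the cycle (the physiological convention; the exact value
is not prescribed by the emulated inputs) and cadence defaults to 111
steps/min (≈1.08 s stride at 1.41 m/s). The vertical GRF is
A·sin(πu)(1+0.45·cos 2πu) over stance progress u — a double bump with
peaks ≈1.1 BW and a mid-stance trough — with A set analytically so the
stance-phase mean is 0.85 BW (per-leg impulse bookkeeping for a 60 %
stance), and exactly zero in swing. The anteroposterior GRF is a braking/
propulsion sine (±0.16 BW); the center of pressure follows the ankle of a
planar two-link leg under the fixed pelvis with a heel-to-toe progression
added, so the GRF line of action stays consistent with the (pelvis-fixed)
kinematics. Optional angle noise is band-limited (3 harmonics), periodic
and seeded; the same seed reproduces a trial bit for bit.

What a green test does not establish: the trial is not a measured
subject; its moments and contact forces are plausible in magnitude and
shape but not comparable frame-by-frame to any laboratory trial, and the
pelvis is fixed (no trunk dynamics, single leg, no contralateral loading
or double-support force sharing beyond the 0.85 BW stance mean).
Consequently only analytic anchors, design invariants and qualitative
directions are asserted — never the source study's absolute peak forces
or regression coefficients, which depend on the original motion-capture
data and full-anatomy geometry.

## Numerics

- Forward kinematics composes joint rotations root-to-leaf (Rodrigues);
  the generalized force conjugate to a joint angle is the joint moment
  projected on that dof's instantaneous world axis, consistent with
  tendon-excursion moment arms r = −∂L/∂q (central difference, step
  1e-4 rad — below via-point geometry curvature, above float noise; the
  stencil clamps at joint range limits with a warning).
- Inverse dynamics: recursive Newton–Euler in the ground frame; segment
  velocities/accelerations by central differences (`np.gradient`,
  one-sided at endpoints); angular velocity from skew(ω) = ṘRᵀ.
- Static optimization: per frame, the analytic minimum-norm solution
  Aᵀ(AAᵀ)⁻¹τ is accepted when it respects the bounds; otherwise SLSQP
  (ftol 1e-12) followed by an active-set polish that re-solves the
  equality-constrained minimum-norm problem on the free variables,
  driving the equilibrium residual to machine precision. Frames are
  flagged converged when the residual is < 1e-6 N·m; infeasible frames
  (required moment beyond capacity) are flagged, not fatal, and report
  the bounded least-squares minimum violation. The activation lower bound
  is exactly 0 (no activation floor).
- The brute-force oracle enumerates the activation grid over all but one
  muscle and enforces equilibrium exactly by eliminating the muscle with
  the strongest moment contribution. Solving one coordinate exactly
  (rather than accepting an equilibrium tolerance band) prevents the
  enumeration from trading constraint slack for objective, which would
  otherwise displace the grid optimum by O(√tolerance) along the
  constraint; with elimination the oracle converges to the continuum
  optimum at O(step).
- Joint reaction analysis needs only force balances: per segment, contact
  force = m·a_com − m·g − external force − muscle forces on the segment −
  the reaction transmitted from the distal joint; each attachment point
  contributes tension times the unit vectors toward its path neighbors.
  With zero muscle forces this reduces identically to the intersegmental
  force.
- Co-contraction: both moment sums zero gives a missing value (NaN), not
  0 — the index's zero must mean full co-contraction, not no contraction.
  Stance means run over cycle samples 0…round(100·stance_fraction)
  inclusive, excluding missing samples with a reported count. Muscles
  with |moment arm| < 1e-4 m in a plane are classified neutral.
- Regression: OLS by QR with t/F reference distributions from
  scipy.stats; predictors (AVA, NSA) entered untransformed in degrees.
  An independent statsmodels fit cross-checks coefficients, standard
  errors and p values in the test suite.

## Open choices made

- "Agonist" is fixed by plane naming (flexors/abductors/internal rotators
  positive) rather than tied to the net moment direction; this affects
  only the CCI's sign convention, not its distance from zero.
- The activation exponent of the static-optimization objective is 2.
- The regression outcome set is the group-level stance summary:
  activations by functional group (grouped per model by stance-mean
  moment-arm sign), agonist/antagonist moment sums per plane (N·m/kg),
  per-plane CCI, and per-joint contact-force resultants (BW).
- The command-line surface is the set of numbered scripts under
  `analysis/`; the library functions are the programmatic interface.

## Known limitations

Planar knee and locked subtalar behavior are model features (single-DOF
knee and ankle hinges); no wrapping surfaces (via-point paths reproduce
qualitative moment-arm behavior, not subject-specific magnitudes); no
activation dynamics, EMG calibration, muscle-driven simulation or
marker-based scaling; single leg; tibial torsion not modeled. Static
optimization gives the minimum co-contraction compatible with the
prescribed moments, so reported co-contraction is a lower bound.
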