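# Methods

This note records the model, the numerical choices, what the synthetic
data generator does and does not emulate, and the known limitations.
Units everywhere: lengths cm, angles degrees at interfaces (radians
internally), forces N, torques Nm, stresses N/cm².

## Joint and path model

The elbow is a single hinge. Coordinates live in a humerus-fixed
right-handed frame: origin at the joint center, hinge axis +z, humerus
along +y, posterior the −x half-plane. Ulna-fixed points are stored at
the fully extended pose (θ = 0) and rotate counterclockwise about +z with
flexion; the modeled range is 0–130°.

A muscle path is origin → via points → insertion. Wrap objects (cylinder
or sphere) deflect any segment that would penetrate them onto a
tangent–geodesic–tangent detour. For cylinders the problem is solved in
the projection onto the plane normal to the axis and the axial coordinate
is distributed linearly along the unrolled planar arc length (the
geodesic of a cylinder is a helix, i.e. a straight line in the unrolled
development, so this is exact). For spheres the shortest path lies in the
plane through the two endpoints and the center, reducing to the same
planar construction with a great-circle arc.

A wrap object may prescribe its wrapping sense (`side: ccw|cw`, viewed
along +axis) the way anatomical surfaces pin a tendon to one side of a
joint; `auto` takes the shorter detour. With a prescribed side the wrap
stays engaged while the taut-string arc is positive even when the straight
chord would clear the surface (the chord would pass through bone on the
far side); the string lifts off, and the segment straightens, when the
side-consistent arc vanishes. Via points and wraps carry an
`active_range` in joint angle.

The moment arm is the tendon excursion MA = ∂l_mt/∂θ in cm per radian,
central finite differences with a 1° step (one-sided at the range
boundaries). Positive MA = extension moment arm. On hinge toy geometries
the finite difference matches the analytic lever derivative to <1e−6 cm
with a 0.01° step (tested).

### Default geometry and its calibration

No attachment coordinates were available to this package, so the bundled
"default elbow geometry" is a reconstruction constrained by modeled
outputs: each head runs from a humerus-fixed effective origin down the
posterior arm, wraps a hinge-coaxial cylinder standing in for the
trochlea/olecranon surface (prescribed posterior side), and inserts on
the olecranon 2.5 cm past the tangent point. While the tendon is wrapped
on a hinge-coaxial cylinder the moment arm equals the cylinder radius
exactly, so the radii are the target mean moment arms (MHT 1.70, LatHT
1.71, LngHT 1.81 cm over 0–130°). Origin heights are pinned by:

* LngHT: a 21% musculotendon excursion from 0° to 130°
  (l_mt(0°) = R·Δθ/0.21 = 19.556 cm);
* MHT and LatHT: tendon slack lengths of 5.7 and 11.4 cm from the length
  identity at 90° with optimal fascicle lengths 8.8 / 11.0 cm and the
  regression pennation at 90°.

These three constraints cannot simultaneously give LngHT an 18.7 cm slack
length; the geometry-consistent value is 13.30 cm. We keep the moment-arm
and excursion targets (they are the geometry's observable outputs) and
accept the shorter long-head tendon; the ordering l_to(MHT) < l_to(LatHT)
< l_to(LngHT) is preserved. `scripts/calibrate_geometry.py` recomputes and
verifies the coordinates.

Subject specificity: humerus-fixed coordinates, wrap centers and radii
scale with the upper-arm length ratio; ulna-fixed coordinates with the
forearm ratio (reference lengths 30 and 25 cm). Uniform scaling s
multiplies every l_mt and moment arm by s (tested).

## Muscle–tendon model

Curves and coefficients as in the README. Numerical choices:

* **Clamping.** f_a is zero outside the positive lobe of its sine and f_p
  is zero below l_mo: negative normalized forces are non-physical. No
  other reshaping is applied. Notably, with these coefficients
  f_a(l_mo) = 0.670 and the curve's maximum (exactly 1.0) sits near
  l_m/l_mo = 0.68 — "optimal fascicle length" functions as the
  architectural anchor for the passive curve, pennation and tendon slack
  length, not as the argmax of f_a. The curves are used exactly as
  parameterized rather than re-normalized, so that stress estimates are
  comparable with the source parameterization.
* **Tendon transition.** F_c is computed from continuity,
  F_c/F_z = A(e^{k₁ε_c} − 1) = 0.50357, rather than fixed at the nominal
  0.5; the curve is then C0 at ε_c by construction and reaches F_z at
  ε = ε_c + (1 − F_c/F_z)/k₂ = 3.32%.
* **Pennation.** Constant-thickness model by default: l_m sin α is
  conserved, α(l_m) = asin(l_mo sin α_o / l_m). A measured
  pennation-vs-angle table can be carried per muscle for reporting, but
  the equilibrium solve needs α as a function of fiber length, which the
  constant-thickness model provides consistently.
* **Equilibrium solve.** Bracketed Brent root-find on l_m between the
  muscle-thickness bound (α → 90°, zero force along the tendon, tendon
  taut: negative residual) and the zero-tendon-strain fiber length
  (tendon slack: non-negative residual). Residual tolerance 1e−8·F_z;
  agreement with a dense-grid bisection oracle to <1e−5 cm (tested). If
  the tendon is slack at every admissible fiber length the zero-force
  rest state is returned (possible only at a = 0; with activation this is
  a parameter inconsistency and raises).

## Torque and the two-step fit

T(θ) = Σ F_t,i·MA_i/100. The torque is *exactly* linear in the per-muscle
maximal forces: every force term in the equilibrium is proportional to
F_z, so the equilibrium fiber length is F_z-invariant. The estimator
exploits this by precomputing each muscle's torque per unit F_z on the
fit grid once ("torque basis") and evaluating the simplex objective on
the linear combination; this is an algebraic identity with the full
forward solve (asserted to 1e−10 in the tests), not an approximation, and
it makes replicate studies cheap (a full subject fit is ~0.3 s).

Objective: mean-square torque error over the 10–100° grid in 2° steps
(46 points); the reported RMS is its square root. Step 1 is a
one-dimensional Nelder–Mead over the shared stress, initialized at peak
measured torque divided by Σ PCSA_i·MA_i(90°). Step 2 is a
three-dimensional Nelder–Mead over per-muscle forces, initialized at the
step-1 solution, with the box enforced through a logistic
reparameterization x = lo + (hi − lo)·expit(u) so iterates approach but
never cross the bounds (a penalty-free way to honor hard boundaries with
a simplex). Box half-width: 15% of the step-1 force for controls, 30%
for the stroke group. Convergence: 1e−6 Nm² absolute on the objective,
max 2000 iterations per step; if step 2 ends above step 1 (it cannot
meaningfully, but the guard exists) the step-1 solution is returned.
Minimizing the mean square and minimizing the RMS are equivalent.

Measured-curve construction: per-angle MVC torque is the maximum 0.5 s
sliding-window mean over the trials at that angle; the torque–angle
points are fit with the lowest-order polynomial whose R² exceeds 0.9
(capped at order 3; R² defined as 1 for an exact fit to constant data).
The end-to-end pipeline pins order 3, the order used for the optimization
grid; the selection rule is available for exploratory use.

### Identifiability of the per-head split

The three per-head torque bases on the 46-point grid are strongly
collinear (pairwise correlations 0.994–0.9999 across synthetic subjects):
the three heads share similar moment arms and smooth operating ranges, so
the data constrain the *total* extensor strength tightly but the per-head
decomposition only weakly (unconstrained least-squares per-head errors
exceed 100% at 5% torque noise). This is precisely why the estimation is
regularized by the step-2 box: under noise the constrained minimum
typically sits on a bound, so per-head stress is identified up to the box
half-width around the (well-identified, ~2% error) common stress. Results
should therefore be interpreted at the subject/extensor level — as the
group comparisons here do, pooling the three heads per subject — with the
per-head values read as box-constrained refinements, not independent
measurements. The recovery validation in the test suite scores the
subject-level extensor stress and separately asserts the box-level
guarantee on per-head values.

## Signal conditioning

Torque: 4th-order Butterworth low-pass at 5 Hz. EMG: 4th-order
Butterworth band-pass 10–500 Hz, full-wave rectification, centered 100 ms
moving average, normalization by the MVC-trial peak. All filters run
forward–backward (`sosfiltfilt`): zero phase lag at the cost of doubling
the effective order. Default sampling rate 2000 Hz. EMG is carried for
completeness and QC; the torque fit assumes full activation (a = 1) and
does not use EMG.

## Ultrasound parameter derivation

Inputs are digitized landmark coordinates, not images: a fascicle
segment, the deep aponeurosis line, and the extrapolation distances MT1
(fiber proximal end → bone) and MT2 (fiber distal end → superficial
aponeurosis), with a mm/px scale. Pennation is the acute angle between
fascicle and deep aponeurosis (invariant to frame rotation, translation
and pixel scale — tested). Full fascicle length is the planimetric
completion L = L_f + MT1/sin α + MT2/sin α; a visualized-only mode
exists. The optimal elbow angle is fixed at 90° (config-overridable):
l_mo and α_o are read there (linear interpolation between bracketing
frames when permitted), l_mt(90°) comes from the scaled geometry, and
l_to follows from the length identity — a non-positive result raises a
parameter-consistency error.

## Synthetic subjects

The generator emulates the study's data products with hidden ground
truth, at the study's own scale:

* subject stress drawn per group — N(89.3, 21.8) N/cm² control,
  N(50.8, 18.6) stroke — truncated above 10 N/cm² by redraw (redraw, not
  clip, keeps densities smooth); per-head stress adds a multiplicative
  N(1, 0.05) factor truncated to [0.85, 1.15] (the study found no
  significant stress differences among heads);
* optimal fascicle lengths drawn near the per-head study means (8.8 /
  11.0 / 9.2 cm control, 10.9 / 12.8 / 10.5 cm stroke, SDs ~2 cm),
  floored at 4.5 cm so the fiber operating range stays physical at full
  extension; pennation at 90° from the group regression plus N(0, 1°);
  tendon slack length *derived* from the subject's scaled geometry via
  the length identity (so architecture and geometry are always mutually
  consistent);
* pennation-vs-angle frames on the 15–105° grid following the
  unimpaired-group regressions (MHT α = −0.05θ + 11.43; LatHT
  α = 0.019θ + 8.14; LngHT α = −0.051θ + 12.99; the hemiparetic group
  measured similar angles, so both groups share them), fascicle lengths
  from constant thickness, landmark jitter 0.2 mm; the 90° frame realizes
  the true (l_mo, α_o) exactly up to jitter;
* torque at the 0–105° × 15° protocol: forward model at truth plus
  Gaussian noise with SD 5% of the peak; optionally raw 2000 Hz
  ramp–hold–release traces for the signal-processing path;
* anthropometry: upper arm N(30, 2) cm, forearm N(25, 1.8) cm, arm
  circumference N(29.5, 2.5) control / N(28.5, 2.5) stroke; PCSA scaled
  from bundled cadaver-scale values (6.1 / 6.0 / 6.7 cm², cadaver
  circumference 29.4 cm — representative magnitudes, config-overridable).

All randomness flows from explicit `numpy.random.Generator` objects;
cohorts spawn independent child seeds per subject. What the generator
does **not** emulate: coactivation of flexor antagonists, incomplete
voluntary activation (both listed as error sources for hemiparetic
subjects), ultrasound speckle or segmentation error beyond landmark
jitter, torque-sensor drift, or within-session fatigue. Passing recovery
tests therefore demonstrate correctness of the inverse machinery under
the model's own assumptions, not robustness to these real-world effects;
in particular the stroke-group stress estimates inherit the full-
activation assumption exactly as the original analysis does.

## Statistics

Repeated-measures one-way ANOVA is computed from sums of squares
directly (condition, subject, residual; F = MS_cond/MS_resid) so the
decomposition is auditable, and is cross-checked against an independent
implementation in the tests. Pairwise post hoc comparisons multiply raw
p-values by the number of comparisons (Bonferroni), capped at 1. Group
comparisons use Welch's unequal-variance t-test (switchable to pooled).
The combine-then-test rule: if neither group shows a significant
within-group muscle effect, the three heads are pooled per subject
(per-subject mean) before the group t-test; the decision is logged in
the output. Significance threshold 0.05 throughout.

## Problem sizes used in validation

Deterministic geometry targets use the full 131-point angle grid.
Recovery studies use 50 seeded single-subject replicates at default
noise; the cohort power study uses 20 replicates of 20 control + 20
stroke subjects; the rank-correlation check uses one 40-subject cohort.
These sizes give stable pass/fail statistics while a full run of the
suite stays in the minutes range on one core.

## Known limitations

* The default geometry is an output-constrained reconstruction, not
  digitized anatomy; absolute musculotendon lengths (and hence derived
  slack lengths) carry that caveat, and its moment arms are constant in
  angle while real triceps moment arms vary smoothly by a few mm across
  the range.
* Single degree of freedom; no shoulder kinematics, no forearm
  pronation/supination.
* a = 1 during MVC is assumed for both groups; reduced central drive
  after stroke therefore appears as reduced stress, by design.
* PCSA enters only through linear circumference scaling of cadaver
  values; errors in PCSA map inversely onto stress.
* The per-head stress decomposition is box-identified (see above).
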