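# Methods

## Scope and coordinate conventions

The package models the left lower limb of a TKA patient during one
level-walking gait cycle and asks how the peak elongation of the
collateral ligaments depends on the placement of the prosthetic
components. All frames are right-handed with X anterior, Y superior and
Z pointing to the subject's right; the modelled limb is the left one,
so its medial side lies at positive Z. Positions are in millimetres,
angles in degrees, forces in newtons; the dynamics core converts to SI
internally and reports generalized forces in N (pelvis translations)
and N·m (rotations).

## Multibody model

The kinematic chain is a tree rooted at the pelvis: 6-DOF pelvis, 3-DOF
ball-and-socket hip, 1-DOF hinge knee, 1-DOF hinge ankle — 11
generalized coordinates. The foot is a single rigid segment
(metatarsal/toe segments are omitted; their inertia is negligible at
knee level). Segment masses, centres of mass and gyration radii follow
standard anthropometric fractions of body mass and stature. The six
pelvis coordinates are driven by residual actuators that absorb the
dynamic contribution of the missing torso and contralateral limb.

Joint parameters come from least-squares geometric fits: a sphere to
the femoral-head cloud (hip centre; algebraic initialisation, then
Gauss–Newton refinement of the radial residuals), cylinders to the
distal condyles and talar trochlea (knee and ankle axes; principal-axis
initialisation, orthogonal-distance refinement; axis signs normalised
to positive Z so hinge angles have a fixed sense). Post-operatively the
knee hinge is re-derived from the posterior arc of the femoral
component — the region in contact with the insert through most of the
cycle — with a conditioning guard that rejects arcs under 10°.

The patella is massless: its pose in the femur frame (two sagittal
translations and the sagittal rotation; frontal and transverse
rotations neglected) is a function of knee flexion through a knot table
generated from the circular trochlear arc of the femoral component,
interpolated with a natural cubic spline (natural, not clamped, so that
a linear knot table interpolates linearly and the ends are not
artificially flattened) and clamped outside the knot range. The
quadriceps transmit force through the patella as a frictionless pulley:
magnitude preserved, direction redirected along the patellar-ligament
line to the tibial tuberosity.

### Muscle set

A reduced atlas of 16 Hill-type units stands in for a full lower-limb
atlas: gluteus maximus/medius/minimus, deep external rotators,
iliopsoas, adductor magnus, medial and lateral hamstrings, the four
quadriceps heads, both gastrocnemius heads, soleus and tibialis
anterior. Twelve sagittal-plane actuators proved insufficient: the hip
internal/external rotation balance is infeasible without dedicated
rotator units (verified by a feasibility LP), and a straight-line
gluteus maximus loses its extension moment arm once the hip flexes, so
it carries an ischial via point. Attachments are defined on a generic
skeleton of 175 cm stature and mapped onto the subject by per-segment
least-squares affine landmark registrations (≥ 4 non-coplanar landmarks
per segment). Maximum isometric forces and PCSAs are standard
literature-scale values; the muscle-stress cost uses PCSA with a
uniform specific tension, so the objective is proportional to
Σ(F/Fmax)².

### Ligaments

The LCL is a straight line from the femoral epicondyle to the fibular
head; the MCL is two connected segments through a via point fixed in
the tibia frame, imitating its wrap over the medial tibial margin (a
femur-frame via point is a configuration option). Both are one-bundle
tension-only springs: zero force when slack, a quadratic toe
`0.25·k·ε²/ε_l` up to twice the reference strain, then linear
`k·(ε − ε_l)`; the branches are C¹-continuous at `ε = 2ε_l`. Defaults
are k = 4000 N (MCL), 2000 N (LCL), ε_l = 0.03, all overridable. The
strain denominator defaults to the **pre-operative path length at full
extension**, because post-operative elongation is clinically read as a
percentage of the ligament's initial length; a literature resting
length can be substituted via `LigamentSpec.L0`. Strains at or beyond
±10 % are treated as the threshold for irreversible effects.

## Surgical placement

Five variables parameterise component placement after mechanical-axis
alignment: femoral and tibial frontal-plane cut angles (positive =
varus), femoral external rotation about the mechanical axis, tibial
posterior slope, and the gap between the distal cut planes. Cut-plane
rotations act about the plane centroids (the pivot is otherwise
unspecified; centroids are the symmetric choice). Each component is
rigid with its cut plane, so a cut rotation carries the bone — and its
ligament attachments — in the opposite sense relative to the joint
frame. At full extension the tibial plane normal is aligned with the
femoral component's superior axis by the minimal rotation (no
transverse twist transfer), and the tibial plane centroid is placed
`gap` mm distal to the femoral plane centroid along the femoral
mechanical axis; this is the operational definition of "gap". Femoral
external rotation therefore leaves the extension placement untouched
and acts through the reoriented hinge axis during flexion. Gait
kinematics are **not** re-solved per configuration: the same joint
angles drive every placement, assuming post-operative compensation
retains normal kinematics (beyond the extremes of the grids this
assumption weakens).

The synthetic anatomy places the pre-operative cut-plane stations 10 mm
proximal and 10 mm distal of the knee centre, so the neutral plan
(angles 0°, slope 3°, gap = implant thickness 26 mm) distalises the
tibia by ≈ 6 mm and pre-strains the MCL by ≈ +7 % at extension — in the
clinically interesting range just below the damage threshold.

## Dynamics solution

Coordinate trajectories may be taken directly from a trial or recovered
from marker trajectories by per-frame global least squares (all 11
coordinates simultaneously, warm-started from the previous frame).
Inverse dynamics projects every body's Newton–Euler wrench and the
ground reaction (applied at the centre of pressure) through the
kinematic Jacobians (central finite differences of the forward
kinematics, step 1e-4). Body kinematics are differentiated in time with
periodic cubic splines — gait cycles are periodic by construction — and
angular velocities come from central finite rotations.

**Verification.** The solution is replayed through an independent
whole-body momentum balance: the rates of change of total linear and
angular momentum, computed with plain second-order periodic
differences (a different numerical route than the splines used by the
solver), must equal gravity + ground reaction + the pelvis residual
wrench. The residual RMSE, normalised by the peak external load, is the
verification statistic; it is ≈ 0.03 % for both forces and moments on
the synthetic trials, against an acceptance bound of 0.1 %.

**Static optimization.** Per frame, minimise Σ(F_i/PCSA_i)² subject to
R·F = τ on the five actuated coordinates (pelvis residuals excluded —
they are not muscles) and 0 ≤ F ≤ Fmax, with moment arms from the
tendon-excursion derivative of the muscle path lengths. Because the
objective is diagonal, the KKT conditions give the primal as a clipped
linear function of the five multipliers; the dual equations are solved
by least squares with semismooth-Newton polishing, falling back to an
interior-point solve on degenerate active sets. KKT stationarity
residuals are ~1e-12; frames whose torque demand cannot be met raise an
error naming the violated coordinate.

**Knee contact force.** The joint reaction is the force balance of the
distal chain (shank + foot): inertial minus gravity, ground reaction,
muscle forces crossing the knee (the quadriceps routed through the
patellar pulley along the patellar-ligament line) and ligament
tensions. The same reaction evaluated from the proximal chain (using
the pelvis residuals) agrees to ~1e-7 N, the level set by the
finite-difference Jacobians. The magnitude is normalised to body weight
and resampled to the 101-sample cycle axis. The medial/lateral split
uses a transparent lever-arm model, F_med/lat = F/2 ± M_frontal/d with
d = 45 mm by default and the coefficients overridable, since published
instrumented-implant regressions are proprietary to their datasets;
negative compartment loads are clamped to zero with a warning.

## Synthetic data generator

The generator emulates the study conditions of an instrumented-TKA
gait dataset: a 167 cm, 78.4 kg female subject with a left posterior
cruciate-retaining implant, four level-walking cycles, and a telemetric
reference record of total knee contact force. All generators are
deterministic in an explicit seed.

- **Anatomy**: joint-surface point clouds are noisy samples (isotropic
  Gaussian, σ = 0.5 mm default) of known generative primitives, which
  are stored alongside so fits can be checked against ground truth;
  ligament attachments sit on the epicondyles, fibular head and medial
  tibia with a 0.3 mm placement jitter, giving pre-operative lengths
  near 90.5 mm (MCL) and 59.4 mm (LCL), MCL > LCL always.
- **Gait**: knee flexion carries a stance flexion wave (~11°, the
  stiff-knee pattern typical of TKA patients) and a swing peak of
  60 ± 1.5° at 72 ± 2 % of the cycle; hip flexion spans 8 ± 16°;
  pelvis translations oscillate about a fixed station (treadmill
  frame). The vertical ground reaction is the classic double hump
  (≈ 1.0 BW humps, push-off biased) vanishing during the last 40 % of
  the cycle; the centre of pressure comes from the foot's own forward
  kinematics, rolling from the hindfoot to the metatarsal heads; and
  the force line points from the centre of pressure toward a virtual
  pivot above the hip (anteriorly biased in early stance), a documented
  regularity of human walking that keeps the inverse-dynamics joint
  moments physiological. These shapes were chosen so that the full
  pipeline reproduces contact-force peaks in the instrumented-implant
  range (first peak ≈ 1.9–2.1 BW near 11–13 %, second ≈ 2.3–2.7 BW
  near 39–45 %), and then frozen.
- **Reference record**: two Gaussian peaks calibrated to 2.0 ± 0.1 BW
  at 13 ± 3 % and 2.6 ± 0.1 BW at 48 ± 5 %, plus a small swing bump.

What the generator does **not** emulate: soft-tissue artefact in
markers, GRF measurement noise, inter-trial kinematic variability
beyond smooth parameter jitter, double-support force sharing with the
contralateral limb, or any imaging-derived bone geometry. Passing tests
therefore demonstrate the internal consistency and the qualitative
surgical-sensitivity structure of the method, not its accuracy on a
real patient; patient-specific quantities (RMSE against a telemetric
implant, absolute post-operative lengths) depend on real geometry and
are outside what synthetic data can certify.

## Sensitivity analysis

Each surgical variable is swept over its planning grid (varus–valgus
−3…3° step 1°, external rotation 0…6° step 1°, slope 3…5° step 1°)
crossed with the gap grid (18…28 mm step 2 mm), one at a time with all
other variables neutral. Per cell, the elongation of each ligament is
traced over the 101-sample cycle for every trial and only the **peak**
strain is kept; across trials the cell stores the maximum (worst case;
the mean is available by option, and the choice is recorded in the
output metadata). Heat maps render the clamped strain on a diverging
scale — dark aquamarine at ≤ −10 % (slack), white at zero, dark red at
≥ +10 % — while the CSV always retains the raw unclamped values; failed
cells would be NaN in the CSV and hatched in the image.

## Numerical choices and limitations

- Finite-difference steps: 1e-4 (deg/mm) for Jacobians, 0.25° for
  moment arms; fit convergence at relative residual change < 1e-14 or
  200–2000 function evaluations; narrow condylar arcs (< 10°) rejected.
- Peak windows for the two-peak statistics: 0–30 % and 30–65 % of the
  cycle, configurable; R² is computed against the reference record's
  variance; RMSE/R² are reported per trial.
- Cut-plane rotation pivots, the gap measurement direction, and the
  varus sign convention are package conventions documented above; the
  hinge-axis pivot for femoral external rotation is the mechanical
  axis.
- Tibiofemoral contact mechanics, 6-DOF knee kinematics, cruciate
  ligaments, multi-bundle ligaments, viscoelasticity, muscle activation
  dynamics and EMG-driven control are out of scope; the knee is an
  ideal hinge and ligament paths use a single via point.
- Problem sizes: gait trials default to 120 frames per cycle; the test
  suite uses two trials for sweep checks and the acceptance script one
  trial, which keeps every stage to seconds while leaving the
  statistics unchanged at the reported precision.
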