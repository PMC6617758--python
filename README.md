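# tkabalance

Patient-specific prediction of knee soft-tissue balance after total knee
arthroplasty (TKA), during level walking.

A major cause of poor functional outcome after TKA is inadequate
balancing of the collateral ligaments: the positions and orientations of
the femoral and tibial bone cuts decide whether the medial and lateral
collateral ligaments (MCL, LCL) end up slack or over-stretched while the
patient walks. `tkabalance` builds a lower-limb multibody model of a TKA
patient (left knee), solves the gait dynamics, and maps the sensitivity
of peak ligament elongation to the five surgical cut-plane variables —
femoral and tibial varus–valgus, femoral external rotation, tibial
posterior slope, and the gap between the distal cut planes — as heat
maps clamped at the ±10 % strain threshold for irreversible ligament
damage.

## What it computes

- **Geometry** (`tkabalance.geometry`): least-squares sphere, cylinder
  and 12-parameter affine fits. The hip centre is a sphere fitted to
  the femoral-head point cloud, the knee and ankle hinge axes are
  cylinders fitted to the distal femoral condyles and the talar
  trochlea, and a generic muscle atlas is registered onto the subject
  with per-segment affine landmark transforms.
- **Model** (`tkabalance.knee_model`): an 11-coordinate chain — 6-DOF
  pelvis with residual actuators, ball-and-socket hip, hinge knee and
  ankle — with a 16-unit Hill-type muscle set, one-bundle
  nonlinear-spring collateral ligaments (the MCL wraps a tibial via
  point, the LCL is a straight line), and a patella that is coupled to
  knee flexion by a spline and transmits the quadriceps force to the
  tibial tuberosity as a frictionless pulley.
- **Surgery** (`tkabalance.surgery`): cut planes from the five surgical
  variables (rotations about the plane centroids after mechanical-axis
  alignment) and component placement; the post-operative hinge axis is
  a cylinder fitted to the posterior arc of the femoral component.
- **Dynamics** (`tkabalance.dynamics`): inverse kinematics (optional,
  marker-based), inverse dynamics by Newton–Euler wrenches projected
  through the kinematic Jacobians, static optimization of muscle forces
  (minimum Σ(F/PCSA)², a box-constrained QP solved exactly via its
  dual), knee contact force from the distal-chain force balance, and a
  medial/lateral compartment decomposition.
- **Sensitivity** (`tkabalance.sensitivity`): one-at-a-time sweeps over
  the planning grids (varus–valgus −3…3° step 1°, external rotation
  0…6°, slope 3…5°, gap 18…28 mm step 2 mm), peak-strain heat maps with
  a diverging colour scale, white at zero strain and clamped at ±10 %.
- **Validation** (`tkabalance.validation`): 0–100 % gait-cycle
  resampling, two-peak detection, RMSE / R² / peak magnitude-and-timing
  comparison against a reference (instrumented-implant style) record.
- **Synthetic data** (`tkabalance.synthetic_data`): deterministic,
  seeded generators for the anatomy, the gait trials and a reference
  knee-force record with peaks calibrated to 2.0 ± 0.1 BW at 13 ± 3 %
  and 2.6 ± 0.1 BW at 48 ± 5 % of the cycle, so the whole pipeline is
  testable without any external data.

## Worked example

```python
import tkabalance as tk
from tkabalance import dynamics as dyn
from tkabalance.sensitivity import SweepGrid, run_sweep

anatomy = tk.generate_anatomy(seed=1)        # 167 cm, 78.4 kg, left TKA
model   = tk.build_model(anatomy)
model.ligament_lengths(0.0)
# {'MCL': 90.8, 'LCL': 59.9}                 # pre-op lengths at extension, mm

params = tk.neutral_params(anatomy)          # 0°/0°/0°, slope 3°, gap 26 mm
postop = tk.place_components(tk.compute_cut_planes(params, model), params, model)
postop.ligament_lengths(0.0)
# {'MCL': 96.8, 'LCL': 65.6}                 # i.e. +6.6 % and +9.6 % strain

trial = tk.generate_gait_trial(seed=2, anatomy=anatomy)
tau   = dyn.inverse_dynamics(model, trial)
dyn.verify_momentum(model, trial, tau)["force_rmse_percent"]
# 0.033                                      # % of peak GRF, well under 0.1 %

muscles   = dyn.solve_muscle_forces(model, trial, tau)
record, _ = dyn.knee_contact_force(model, trial, muscles)
tk.find_peaks(record.values)
# ((1.88, 12.0), (2.35, 39.0))               # BW and % cycle

trials = [tk.generate_gait_trial(seed=s, anatomy=anatomy) for s in (2, 3, 4, 5)]
hm = run_sweep(model, trials, SweepGrid("vv_tibia"), ligament="MCL")
hm.raw.shape                                 # (7, 6): vv values x gap values
```

The heat-map row for the neutral angle shows MCL peak strain rising from
+1.4 % at an 18 mm gap to +12.1 % at 28 mm — the gap, and the frontal
varus–valgus angles, dominate collateral-ligament balance, while slope
and femoral rotation act more weakly through the flexed part of the
cycle.

The same pipeline is scriptable from the shell:

```bash
tka generate --seed 1 --out data/
tka simulate --anatomy data/anatomy.json --trial data/trial_1.csv --out run/
tka sweep    --anatomy data/anatomy.json --trials data/ --param vv_tibia --out sweep/
tka validate --pred run/contact_force.csv --ref data/reference_force.csv --out stats.json
```

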