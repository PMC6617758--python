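"""Synthetic patient data: anatomy, gait trials, reference knee forces.

The generators emulate the kind of data collected for an instrumented
total-knee-replacement patient (a left-knee recipient of a telemetric
tibial prosthesis): bone landmark sets and joint-surface point clouds
from imaging, collateral-ligament attachment sites, level-walking gait
cycles with ground reactions, and a reference total knee contact force
record with the two characteristic stance peaks (first peak 2.0 +/- 0.1
body weight at 13 +/- 3% cycle, second peak 2.6 +/- 0.1 BW at
48 +/- 5% cycle).

Frames are right-handed with X anterior, Y superior and Z pointing to
the subject's right; positions are in mm, forces in N, angles in
degrees.  The modelled limb is the left one, so the medial side of the
knee lies at positive Z.  Every generator takes an explicit seed and is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .transforms import RigidTransform, hip_rotation, pelvis_rotation

__all__ = [
    "AnatomyFixture",
    "GaitTrial",
    "ContactForceRecord",
    "generate_anatomy",
    "generate_gait_trial",
    "generate_reference_knee_force",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2

#: segment mass fractions of total body mass (standard anthropometry)
MASS_FRACTIONS = {"pelvis": 0.142, "femur": 0.100, "tibia": 0.0465, "foot": 0.0145}
#: proximal center-of-mass fractions and transverse radii of gyration
COM_FRACTIONS = {"femur": 0.433, "tibia": 0.433, "foot": 0.50}
GYRATION_FRACTIONS = {"femur": 0.323, "tibia": 0.302, "foot": 0.475}

#: pre-operative distance between the femoral distal cut and the tibial
#: cut along the mechanical axis (mm); each plane sits 10 mm from the
#: knee centre.
FEMORAL_CUT_OFFSET = 10.0
TIBIAL_CUT_OFFSET = 10.0
DEFAULT_IMPLANT_THICKNESS = 26.0


@dataclass(frozen=True)
class AnatomyFixture:
    """Synthetic patient anatomy in body-fixed segment frames.

    The femur frame has its origin at the hip centre with the knee
    centre at ``knee_center_femur``; the tibia frame has its origin at
    the knee centre with the ankle centre at ``ankle_center_tibia``.
    Point clouds carry measurement noise; the noiseless generative
    primitives they were sampled from are kept in ``generative`` so that
    fitted joint parameters can be checked against ground truth.
    """

    height: float                      # mm
    body_mass: float                   # kg
    body_weight: float                 # N
    landmarks: dict                    # segment -> {name: (3,) mm}
    femoral_head_cloud: np.ndarray     # femur frame
    condyle_cloud: np.ndarray          # femur frame (distal condyles)
    trochlea_cloud: np.ndarray         # tibia frame (talar trochlea)
    posterior_arc_cloud: np.ndarray    # femur frame (implant posterior arc)
    mcl_origin: np.ndarray             # femur frame
    mcl_via: np.ndarray                # tibia frame
    mcl_insertion: np.ndarray          # tibia frame
    lcl_origin: np.ndarray             # femur frame
    lcl_insertion: np.ndarray          # tibia frame
    implant_thickness: float           # mm
    hip_center_pelvis: np.ndarray      # pelvis frame
    knee_center_femur: np.ndarray      # femur frame
    ankle_center_tibia: np.ndarray     # tibia frame
    segment_masses: dict               # kg
    segment_coms: dict                 # segment frame, mm
    segment_inertias: dict             # kg mm^2, diagonal 3x3 about COM
    generative: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("femoral_head_cloud", "condyle_cloud", "trochlea_cloud",
                     "posterior_arc_cloud", "mcl_origin", "mcl_via",
                     "mcl_insertion", "lcl_origin", "lcl_insertion",
                     "hip_center_pelvis", "knee_center_femur", "ankle_center_tibia"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.body_weight <= 0 or self.height <= 0:
            raise ParameterError("height and body weight must be positive")
        if any(m <= 0 for m in self.segment_masses.values()):
            raise ParameterError("segment masses must be positive")

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x
        return {k: conv(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomyFixture":
        def arr(x):
            return np.asarray(x, dtype=float)
        kwargs = dict(d)
        for name in ("femoral_head_cloud", "condyle_cloud", "trochlea_cloud",
                     "posterior_arc_cloud", "mcl_origin", "mcl_via",
                     "mcl_insertion", "lcl_origin", "lcl_insertion",
                     "hip_center_pelvis", "knee_center_femur", "ankle_center_tibia"):
            kwargs[name] = arr(d[name])
        kwargs["landmarks"] = {
            seg: {k: arr(v) for k, v in pts.items()} for seg, pts in d["landmarks"].items()
        }
        kwargs["segment_coms"] = {k: arr(v) for k, v in d["segment_coms"].items()}
        kwargs["segment_inertias"] = {k: arr(v) for k, v in d["segment_inertias"].items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class GaitTrial:
    """One level-walking gait cycle, heel strike to subsequent heel strike.

    ``pelvis_pose`` holds 3 translations (mm) and 3 rotations (deg) per
    frame; ``grf`` is the 3-D ground reaction on the stance foot (N) and
    ``cop`` its centre of pressure (mm, ground frame).
    """

    time: np.ndarray
    pelvis_pose: np.ndarray        # (n, 6)
    hip_angles: np.ndarray         # (n, 3): flexion, adduction, rotation
    knee_flexion: np.ndarray       # (n,)
    ankle_flexion: np.ndarray      # (n,)
    grf: np.ndarray                # (n, 3)
    cop: np.ndarray                # (n, 3)
    heel_strikes: tuple            # (first, second) sample indices

    def __post_init__(self):
        for name in ("time", "pelvis_pose", "hip_angles", "knee_flexion",
                     "ankle_flexion", "grf", "cop"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        if self.heel_strikes[0] != 0 or self.heel_strikes[1] != n - 1:
            raise ParameterError("trial must span exactly one cycle")
        if np.any(self.knee_flexion < -1e-9) or np.any(self.knee_flexion > 90 + 1e-9):
            raise ParameterError("knee flexion must stay within [0, 90] deg")
        if np.any(self.grf[:, 1] < -1e-9):
            raise ParameterError("vertical GRF must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def swing_mask(self) -> np.ndarray:
        """Frames with no ground contact."""
        return self.grf[:, 1] <= 1e-9


@dataclass(frozen=True)
class ContactForceRecord:
    """Total knee contact force in body weights on the 101-sample cycle axis."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != 101:
            raise ParameterError("contact-force record must have 101 samples")
        if np.any(v < -1e-12):
            raise ParameterError("contact force must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return 101


def _sample_sphere_cap(rng, center, radius, n, noise, direction, cap_deg=80.0):
    """Noisy points on the spherical cap around ``direction``."""
    d = np.asarray(direction, float) / np.linalg.norm(direction)
    cos_min = np.cos(np.deg2rad(cap_deg))
    u = rng.uniform(cos_min, 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - u**2)
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    # rotate local +Z to the cap direction
    from .transforms import rotation_between
    R = rotation_between([0, 0, 1], d)
    pts = center + radius * local @ R.T
    return pts + rng.normal(0.0, noise, pts.shape) if noise > 0 else pts


def _sample_cylinder_arc(rng, axis_point, axis_dir, radius, half_length, n,
                         noise, arc_center_deg, arc_span_deg):
    """Noisy points on an angular sector of a cylinder surface.

    Angles are measured in the plane orthogonal to the axis, from the
    +X direction toward +Y (femur frame: 0 deg anterior, 180 posterior,
    -90 distal)."""
    d = np.asarray(axis_dir, float) / np.linalg.norm(axis_dir)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    ang = np.deg2rad(arc_center_deg + arc_span_deg * (rng.uniform(-0.5, 0.5, n)))
    z = rng.uniform(-half_length, half_length, n)
    pts = (np.asarray(axis_point, float)
           + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
           + np.outer(z, d))
    return pts + rng.normal(0.0, noise, pts.shape) if noise > 0 else pts


def generate_anatomy(seed: int, height: float = 1670.0,
                     body_weight: float = 78.4 * GRAVITY,
                     noise: float = 0.5,
                     implant_thickness: float = DEFAULT_IMPLANT_THICKNESS,
                     ) -> AnatomyFixture:
    """Generate the synthetic patient anatomy.

    Defaults correspond to the modelled subject: a 167 cm, 78.4 kg woman
    with a left total knee replacement.  ``noise`` is the isotropic
    Gaussian sigma (mm) added to the joint-surface point clouds.
    """
    if height <= 0 or body_weight <= 0:
        raise ParameterError("height and body weight must be positive")
    rng = np.random.default_rng(seed)
    mass = body_weight / GRAVITY

    L_f = 0.245 * height     # hip centre to knee centre
    L_t = 0.246 * height     # knee centre to ankle centre
    L_foot = 0.152 * height

    knee_center = np.array([0.0, -L_f, 0.0])           # femur frame
    ankle_center = np.array([0.0, -L_t, 0.0])          # tibia frame
    hip_center_pelvis = np.array([0.0, -80.0, -0.05 * height])  # left hip

    # --- joint-surface point clouds (generative primitives + noise) ---
    head_radius = 24.0
    head = _sample_sphere_cap(rng, np.zeros(3), head_radius, 400, noise,
                              direction=[0.0, 0.3, -1.0])
    condyle_radius = 22.0
    condyle = _sample_cylinder_arc(rng, knee_center, [0, 0, 1.0], condyle_radius,
                                   32.0, 400, noise, arc_center_deg=-125.0,
                                   arc_span_deg=150.0)
    trochlea_radius = 18.0
    trochlea = _sample_cylinder_arc(rng, ankle_center, [0, 0, 1.0], trochlea_radius,
                                    15.0, 200, noise, arc_center_deg=90.0,
                                    arc_span_deg=100.0)
    # posterior arc of the femoral component: single-radius posterior curvature
    arc_center = knee_center + np.array([-6.0, 4.0, 0.0])
    arc_radius = 20.0
    posterior_arc = _sample_cylinder_arc(rng, arc_center, [0, 0, 1.0], arc_radius,
                                         28.0, 150, noise, arc_center_deg=-160.0,
                                         arc_span_deg=80.0)

    # --- collateral ligament attachments (left knee: medial = +Z) ---
    jitter = lambda: rng.normal(0.0, 0.3, 3)
    mcl_origin = knee_center + np.array([0.0, 10.0, 42.0]) + jitter()
    mcl_via = np.array([0.0, -16.0, 40.0]) + jitter()          # tibia frame
    mcl_insertion = np.array([8.0, -76.0, 18.0]) + jitter()    # tibia frame
    lcl_origin = knee_center + np.array([0.0, 12.0, -44.0]) + jitter()
    lcl_insertion = np.array([-8.0, -46.7, -48.0]) + jitter()  # tibia frame

    # --- landmarks for affine registration and marker-based tracking ---
    landmarks = {
        "pelvis": {
            "RASIS": np.array([70.0, 0.0, 120.0]),
            "LASIS": np.array([70.0, 0.0, -120.0]),
            "RPSIS": np.array([-90.0, 10.0, 50.0]),
            "LPSIS": np.array([-90.0, 10.0, -50.0]),
            "SACRUM": np.array([-100.0, -10.0, 0.0]),
        },
        "femur": {
            "GREATER_TROCHANTER": np.array([-10.0, -15.0, -55.0]),
            "MEDIAL_EPICONDYLE": knee_center + np.array([0.0, 8.0, 45.0]),
            "LATERAL_EPICONDYLE": knee_center + np.array([0.0, 10.0, -47.0]),
            "MID_SHAFT": np.array([10.0, -L_f / 2, -5.0]),
        },
        "tibia": {
            "TIBIAL_TUBEROSITY": np.array([35.0, -40.0, 0.0]),
            "FIBULA_HEAD": np.array([-15.0, -25.0, -45.0]),
            "MEDIAL_MALLEOLUS": ankle_center + np.array([0.0, -5.0, 30.0]),
            "LATERAL_MALLEOLUS": ankle_center + np.array([0.0, -10.0, -32.0]),
        },
        "patella": {
            "PATELLA_CENTER": np.array([0.0, 0.0, 0.0]),
            "PATELLA_APEX": np.array([3.0, -20.0, 0.0]),
            "PATELLA_BASE": np.array([-2.0, 18.0, 0.0]),
            "PATELLA_LATERAL": np.array([0.0, 0.0, -20.0]),
        },
        "foot": {
            "HEEL": np.array([-0.35 * L_foot, -30.0, 0.0]),
            "TOE": np.array([0.65 * L_foot, -35.0, 0.0]),
            "MET5": np.array([0.35 * L_foot, -30.0, -35.0]),
            "NAVICULAR": np.array([0.15 * L_foot, -10.0, 10.0]),
        },
    }

    # --- inertial properties (diagonal, segment frame, about the COM) ---
    seg_lengths = {"femur": L_f, "tibia": L_t, "foot": L_foot}
    masses, coms, inertias = {}, {}, {}
    for seg, frac in MASS_FRACTIONS.items():
        m = frac * mass
        masses[seg] = m
        if seg == "pelvis":
            coms[seg] = np.array([0.0, -30.0, -0.02 * height])
            inertias[seg] = np.diag([m * 110.0**2, m * 120.0**2, m * 100.0**2])
        else:
            L = seg_lengths[seg]
            if seg == "foot":
                coms[seg] = np.array([COM_FRACTIONS[seg] * L - 0.35 * L, -30.0, 0.0])
            else:
                coms[seg] = np.array([0.0, -COM_FRACTIONS[seg] * L, 0.0])
            it = m * (GYRATION_FRACTIONS[seg] * L) ** 2
            inertias[seg] = np.diag([it, 0.15 * it, it])

    generative = {
        "head_sphere": {"center": [0.0, 0.0, 0.0], "radius": head_radius},
        "condyle_cylinder": {"axis_point": knee_center.tolist(),
                             "axis_direction": [0.0, 0.0, 1.0],
                             "radius": condyle_radius},
        "trochlea_cylinder": {"axis_point": ankle_center.tolist(),
                              "axis_direction": [0.0, 0.0, 1.0],
                              "radius": trochlea_radius},
        "posterior_arc_cylinder": {"axis_point": arc_center.tolist(),
                                   "axis_direction": [0.0, 0.0, 1.0],
                                   "radius": arc_radius},
        "noise": noise,
    }

    return AnatomyFixture(
        height=height, body_mass=mass, body_weight=body_weight,
        landmarks=landmarks,
        femoral_head_cloud=head, condyle_cloud=condyle, trochlea_cloud=trochlea,
        posterior_arc_cloud=posterior_arc,
        mcl_origin=mcl_origin, mcl_via=mcl_via, mcl_insertion=mcl_insertion,
        lcl_origin=lcl_origin, lcl_insertion=lcl_insertion,
        implant_thickness=implant_thickness,
        hip_center_pelvis=hip_center_pelvis,
        knee_center_femur=knee_center, ankle_center_tibia=ankle_center,
        segment_masses=masses, segment_coms=coms, segment_inertias=inertias,
        generative=generative,
    )


def _periodic_wave(knot_fractions, knot_values):
    """Periodic cubic spline through (cycle fraction, value) knots."""
    x = np.asarray(knot_fractions, dtype=float)
    y = np.asarray(knot_values, dtype=float)
    return CubicSpline(np.r_[x, 1.0], np.r_[y, y[0]], bc_type="periodic")


def generate_gait_trial(seed: int, n_frames: int = 120, cadence: float = 101.0,
                        anatomy: Optional[AnatomyFixture] = None) -> GaitTrial:
    """Generate one synthetic level-walking gait cycle.

    The knee flexion trace carries the canonical stance flexion wave and
    a swing peak near 60 deg around 70-75% of the cycle; the vertical
    ground reaction is the classic double hump scaled to body weight and
    vanishes during swing (last ~40% of the cycle).  Pelvis translations
    oscillate about a fixed station (treadmill frame).  Small seeded
    perturbations of amplitudes and timings differentiate trials.
    """
    if n_frames < 50:
        raise ParameterError("need at least 50 frames per cycle")
    if anatomy is None:
        anatomy = generate_anatomy(seed=0, noise=0.0)
    rng = np.random.default_rng(seed)
    bw = anatomy.body_weight

    cycle_T = 120.0 / cadence            # two steps per cycle
    t = np.linspace(0.0, cycle_T, n_frames)
    s = t / cycle_T                      # cycle fraction

    swing_peak = float(np.clip(60.0 + rng.normal(0.0, 1.5), 56.0, 64.0))
    swing_time = float(np.clip(0.72 + rng.normal(0.0, 0.02), 0.67, 0.80))
    stance_wave = float(np.clip(11.0 + rng.normal(0.0, 1.0), 8.0, 14.0))
    knee_spline = _periodic_wave(
        [0.0, 0.12, 0.40, 0.55, swing_time, 0.90],
        [5.0, stance_wave, 8.0, 32.0, swing_peak, 14.0])
    knee = np.clip(knee_spline(s), 0.0, 90.0)

    hip_amp = 16.0 + rng.normal(0.0, 1.0)
    hip_flex = 8.0 + hip_amp * np.cos(2 * np.pi * s)
    hip_add = (4.0 + rng.normal(0.0, 0.5)) * np.sin(2 * np.pi * s)
    hip_rot = (2.0 + rng.normal(0.0, 0.3)) * np.sin(2 * np.pi * s + 0.5)
    ankle_spline = _periodic_wave(
        [0.0, 0.07, 0.45, 0.60, 0.80],
        [0.0, -6.0 + rng.normal(0.0, 0.8), 12.0 + rng.normal(0.0, 1.0), -15.0, -2.0])
    ankle = ankle_spline(s)

    pelvis_y0 = 0.55 * anatomy.height
    pelvis = np.column_stack([
        (25.0 + rng.normal(0.0, 2.0)) * np.sin(2 * np.pi * s),
        pelvis_y0 + (14.0 + rng.normal(0.0, 1.0)) * np.sin(4 * np.pi * s + 1.0),
        (20.0 + rng.normal(0.0, 2.0)) * np.cos(2 * np.pi * s),
        (2.0 + rng.normal(0.0, 0.3)) * np.sin(4 * np.pi * s),       # list (about X)
        (5.0 + rng.normal(0.0, 0.5)) * np.sin(2 * np.pi * s),       # axial rotation
        (3.0 + rng.normal(0.0, 0.3)) * np.cos(2 * np.pi * s),       # tilt (about Z)
    ])

    stance_frac = 0.60
    u = np.clip(s / stance_frac, 0.0, 1.0)
    in_stance = s < stance_frac
    v_amp = 1.04 + rng.normal(0.0, 0.02)
    fy = bw * (v_amp * np.sin(np.pi * u) + 0.34 * np.sin(3 * np.pi * u)
               - 0.12 * np.sin(2 * np.pi * u))   # push-off biased
    fy = np.where(in_stance, np.maximum(fy, 0.0), 0.0)

    # centre of pressure from the forward kinematics of the stance foot
    # (treadmill frame: the foot travels backwards under the pelvis),
    # progressing heel to toe through stance and projected to the ground
    heel_l = anatomy.landmarks["foot"]["HEEL"]
    toe_l = anatomy.landmarks["foot"]["TOE"]
    hip_center_pelvis = anatomy.hip_center_pelvis
    knee_center = anatomy.knee_center_femur
    ankle_center = anatomy.ankle_center_tibia
    hip_world = np.zeros((n_frames, 3))
    cop = np.zeros((n_frames, 3))
    for k in range(n_frames):
        T_p = RigidTransform(pelvis_rotation(*pelvis[k, 3:6]), pelvis[k, 0:3])
        R_h = hip_rotation(hip_flex[k], hip_add[k], hip_rot[k])
        T_f = T_p @ RigidTransform(R_h, hip_center_pelvis)
        T_t = T_f @ RigidTransform(
            Rotation.from_euler("z", -knee[k], degrees=True).as_matrix(), knee_center)
        T_ft = T_t @ RigidTransform(
            Rotation.from_euler("z", ankle[k], degrees=True).as_matrix(), ankle_center)
        hip_world[k] = T_p.apply(hip_center_pelvis)
        # hindfoot contact just behind the ankle at heel strike, rolling
        # to the toe through terminal stance
        w = 0.28 + np.clip(1.2 * u[k] - 0.20, 0.0, 0.56)
        point = (1 - w) * T_ft.apply(heel_l) + w * T_ft.apply(toe_l)
        cop[k] = np.array([point[0], 0.0, point[2]])

    # the ground-reaction line points from the centre of pressure toward
    # a virtual pivot above the hip (biased anteriorly in early stance),
    # as in human level walking, so joint moments stay physiological
    pivot = hip_world + np.array([0.0, 150.0, 0.0])
    pivot[:, 0] += np.clip(40.0 - 55.0 * u, -5.0, 40.0)  # anterior bias early
    d = pivot - cop
    with np.errstate(divide="ignore", invalid="ignore"):
        fx = fy * d[:, 0] / d[:, 1]
        fz = fy * d[:, 2] / d[:, 1]
    fx = np.where(in_stance, fx, 0.0)
    fz = np.where(in_stance, fz, 0.0)
    grf = np.column_stack([fx, fy, fz])
    cop = np.where(in_stance[:, None], cop, 0.0)

    return GaitTrial(time=t, pelvis_pose=pelvis,
                     hip_angles=np.column_stack([hip_flex, hip_add, hip_rot]),
                     knee_flexion=knee, ankle_flexion=ankle, grf=grf, cop=cop,
                     heel_strikes=(0, n_frames - 1))


def generate_reference_knee_force(trial: GaitTrial, seed: int) -> ContactForceRecord:
    """Reference total knee contact force emulating a telemetric implant.

    Calibrated so that across seeds the first peak falls at
    2.0 +/- 0.1 BW around 13 +/- 3% cycle and the second at
    2.6 +/- 0.1 BW around 48 +/- 5% cycle.
    """
    if trial.n_frames < 2:
        raise ParameterError("invalid trial")
    rng = np.random.default_rng(seed)
    p1 = float(np.clip(2.0 + rng.normal(0.0, 0.04), 1.91, 2.09))
    t1 = float(np.clip(13.0 + rng.normal(0.0, 1.2), 10.2, 15.8))
    p2 = float(np.clip(2.6 + rng.normal(0.0, 0.04), 2.51, 2.69))
    t2 = float(np.clip(48.0 + rng.normal(0.0, 1.8), 43.5, 52.5))
    p = np.arange(101.0)
    rec = (p1 * np.exp(-0.5 * ((p - t1) / 6.0) ** 2)
           + p2 * np.exp(-0.5 * ((p - t2) / 7.0) ** 2)
           + 0.35 * np.exp(-0.5 * ((p - 78.0) / 9.0) ** 2))
    return ContactForceRecord(values=rec)
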