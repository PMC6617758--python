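"""Lower-limb multibody model assembly.

The kinematic chain is a tree rooted at the pelvis: a 6-DOF free pelvis
(three translations, three rotations — the residual-actuated
coordinates), a ball-and-socket hip (3 DOF), and hinge knee and ankle
joints (1 DOF each), for 11 generalized coordinates in total.  The hip
centre comes from the sphere fitted to the femoral head; the knee and
ankle hinge axes from cylinders fitted to the distal femoral condyles
and the talar trochlea.  Post-operatively the knee hinge is taken from
the posterior arc of the femoral component, which is the part in
contact with the polyethylene insert through most of the gait cycle.

Muscles are straight-line (optionally via-point) Hill-type units whose
attachments are mapped from a generic atlas onto the subject's bones
with per-segment affine landmark registrations.  A reduced 16-unit
lower-limb atlas is used by default: it retains the main sagittal- and
frontal-plane torque generators at each joint (gluteals, iliopsoas,
adductors, hamstrings, the four quadriceps heads, both gastrocnemius
heads, soleus, tibialis anterior).

The patella is a massless force-redirection body: its pose in the femur
frame is a clamped cubic spline of the knee flexion angle (two sagittal
translations and one sagittal rotation — frontal and transverse
rotations are neglected), and the quadriceps force is transmitted to
the tibial tuberosity along the patellar-ligament line with unchanged
magnitude (frictionless pulley).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateInputError, GeometryError, ParameterError
from .geometry import apply_affine, fit_affine, fit_cylinder, fit_sphere
from .ligament import LigamentSpec, path_length
from .synthetic_data import AnatomyFixture
from .transforms import RigidTransform, hip_rotation, pelvis_rotation, rot_about_axis
from scipy.spatial.transform import Rotation

__all__ = [
    "MuscleUnit",
    "PatellaCoupling",
    "LowerLimbModel",
    "build_model",
    "default_atlas",
    "knee_axis_from_implant",
    "eval_patella_pose",
    "quadriceps_pulley",
]

SEGMENTS = ("pelvis", "femur", "tibia", "foot")
#: generalized coordinates, in order
COORDINATES = (
    "pelvis_tx", "pelvis_ty", "pelvis_tz",
    "pelvis_rx", "pelvis_ry", "pelvis_rz",
    "hip_flexion", "hip_adduction", "hip_rotation",
    "knee_flexion", "ankle_flexion",
)
N_COORDINATES = 11

#: nominal stature (mm) of the generic muscle atlas skeleton
ATLAS_HEIGHT = 1750.0


@dataclass(frozen=True)
class MuscleUnit:
    """Straight-line musculotendon unit with optional via points.

    ``path`` is an ordered list of ``(segment, point)`` pairs from
    origin to insertion, points in segment frames (mm).  The segment
    name ``"patella"`` marks a point riding on the patella coupling.
    """

    name: str
    fmax: float          # N
    pcsa: float          # cm^2
    path: tuple          # ((segment, (3,) mm), ...)

    def __post_init__(self):
        if self.fmax <= 0 or self.pcsa <= 0:
            raise ParameterError("Fmax and PCSA must be positive")
        if len(self.path) < 2:
            raise ParameterError("muscle path needs at least 2 points")
        norm = tuple((seg, np.asarray(pt, dtype=float)) for seg, pt in self.path)
        object.__setattr__(self, "path", norm)

    def to_dict(self) -> dict:
        return {"name": self.name, "fmax": self.fmax, "pcsa": self.pcsa,
                "path": [[seg, pt.tolist()] for seg, pt in self.path]}


@dataclass(frozen=True)
class PatellaCoupling:
    """Patella pose as a function of knee flexion.

    ``knot_angles`` (deg, strictly increasing) map to ``knot_poses``
    rows of (tx, ty, rotation) in the femur frame (mm, mm, deg).
    Evaluation interpolates with a natural cubic spline (so a linear
    knot table interpolates linearly) and clamps outside the knot range.
    """

    knot_angles: np.ndarray
    knot_poses: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.knot_angles, dtype=float)
        p = np.asarray(self.knot_poses, dtype=float).reshape(len(a), 3)
        if np.any(np.diff(a) <= 0):
            raise ParameterError("knot angles must be strictly increasing")
        object.__setattr__(self, "knot_angles", a)
        object.__setattr__(self, "knot_poses", p)
        spline = CubicSpline(a, p, axis=0, bc_type="natural")
        object.__setattr__(self, "_spline", spline)

    def to_dict(self) -> dict:
        return {"knot_angles": self.knot_angles.tolist(),
                "knot_poses": self.knot_poses.tolist()}


def eval_patella_pose(coupling: PatellaCoupling, knee_angle: float) -> np.ndarray:
    """Patella (tx, ty, rotation) at ``knee_angle`` deg, clamped to the
    knot range outside it."""
    a = float(np.clip(knee_angle, coupling.knot_angles[0], coupling.knot_angles[-1]))
    return np.asarray(coupling._spline(a), dtype=float)


def quadriceps_pulley(quadriceps_force: float, patella_point, tuberosity_point) -> np.ndarray:
    """Force on the tibia from the quadriceps routed over the patella.

    The patella acts as a frictionless pulley: the magnitude is
    transmitted unchanged and redirected along the patellar-ligament
    line from the patella to the tibial tuberosity.
    """
    if quadriceps_force < 0:
        raise ParameterError("quadriceps force must be non-negative")
    p = np.asarray(patella_point, dtype=float)
    t = np.asarray(tuberosity_point, dtype=float)
    line = t - p
    n = np.linalg.norm(line)
    if n < 1e-12:
        raise GeometryError("patellar-ligament line has zero length")
    return quadriceps_force * line / n


@dataclass(frozen=True)
class LowerLimbModel:
    """Assembled lower-limb model (left limb).

    ``placement`` is the tibia pose in the femur frame at full
    extension; pre-operatively the tibia frame sits at the knee centre
    with no relative rotation, post-operatively it is derived from the
    component placement.  The knee hinge (``knee_axis_point``,
    ``knee_axis_direction``, femur frame) comes from the condylar
    cylinder pre-op or the implant posterior arc post-op.
    """

    anatomy: AnatomyFixture
    hip_center_femur: np.ndarray       # femur frame (fitted)
    hip_center_pelvis: np.ndarray      # pelvis frame
    knee_center_femur: np.ndarray
    ankle_center_tibia: np.ndarray
    knee_axis_point: np.ndarray        # femur frame
    knee_axis_direction: np.ndarray
    ankle_axis_point: np.ndarray       # tibia frame
    ankle_axis_direction: np.ndarray
    muscles: tuple                     # MuscleUnit, attachments in subject frames
    ligaments: dict                    # name -> LigamentSpec
    patella_coupling: PatellaCoupling
    placement: RigidTransform          # tibia in femur frame at extension
    surgical_params: Optional[dict] = None
    is_postop: bool = False

    def __post_init__(self):
        for name in ("hip_center_femur", "hip_center_pelvis", "knee_center_femur",
                     "ankle_center_tibia", "knee_axis_point", "knee_axis_direction",
                     "ankle_axis_point", "ankle_axis_direction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    # ---- bookkeeping -------------------------------------------------
    @property
    def n_coordinates(self) -> int:
        return N_COORDINATES

    @property
    def coordinate_names(self) -> tuple:
        return COORDINATES

    @property
    def segment_masses(self) -> dict:
        return self.anatomy.segment_masses

    # ---- kinematics --------------------------------------------------
    def tibia_pose(self, knee_angle_deg: float) -> RigidTransform:
        """Tibia pose in the femur frame at the given flexion angle.

        Flexion rotates the tibia about the knee hinge axis from the
        full-extension placement; positive flexion carries the distal
        tibia posteriorly.
        """
        hinge = rot_about_axis(self.knee_axis_direction, -knee_angle_deg,
                               self.knee_axis_point)
        return hinge @ self.placement

    def patella_pose(self, knee_angle_deg: float) -> RigidTransform:
        """Patella pose in the femur frame from the coupling spline."""
        tx, ty, rot = eval_patella_pose(self.patella_coupling, knee_angle_deg)
        R = Rotation.from_euler("z", rot, degrees=True).as_matrix()
        return RigidTransform(R, np.array([tx, ty, 0.0]))

    def segment_poses(self, q) -> dict:
        """World pose of every segment for generalized coordinates ``q``
        (mm and degrees, ordered as ``COORDINATES``)."""
        q = np.asarray(q, dtype=float)
        if len(q) != N_COORDINATES:
            raise ParameterError("expected 11 generalized coordinates")
        pelvis = RigidTransform(pelvis_rotation(q[3], q[4], q[5]), q[0:3])
        R_hip = hip_rotation(q[6], q[7], q[8])
        femur = pelvis @ RigidTransform(
            R_hip, self.hip_center_pelvis - R_hip @ self.hip_center_femur)
        tibia = femur @ self.tibia_pose(q[9])
        ankle_hinge = rot_about_axis(self.ankle_axis_direction, q[10],
                                     self.ankle_axis_point)
        foot = tibia @ ankle_hinge @ RigidTransform(np.eye(3), self.ankle_center_tibia)
        patella = femur @ self.patella_pose(q[9])
        return {"pelvis": pelvis, "femur": femur, "tibia": tibia, "foot": foot,
                "patella": patella}

    def ligament_lengths(self, knee_angle_deg: float = 0.0) -> dict:
        """Path lengths (mm) of all ligaments at one flexion angle."""
        femur = RigidTransform.identity()
        tibia = self.tibia_pose(knee_angle_deg)
        return {name: path_length(lig, femur, tibia)
                for name, lig in self.ligaments.items()}

    # ---- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "hip_center_femur": self.hip_center_femur.tolist(),
            "hip_center_pelvis": self.hip_center_pelvis.tolist(),
            "knee_center_femur": self.knee_center_femur.tolist(),
            "ankle_center_tibia": self.ankle_center_tibia.tolist(),
            "knee_axis_point": self.knee_axis_point.tolist(),
            "knee_axis_direction": self.knee_axis_direction.tolist(),
            "ankle_axis_point": self.ankle_axis_point.tolist(),
            "ankle_axis_direction": self.ankle_axis_direction.tolist(),
            "muscles": [m.to_dict() for m in self.muscles],
            "ligaments": {k: v.to_dict() for k, v in self.ligaments.items()},
            "patella_coupling": self.patella_coupling.to_dict(),
            "placement": self.placement.to_dict(),
            "surgical_params": self.surgical_params,
            "is_postop": self.is_postop,
            "anatomy": self.anatomy.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LowerLimbModel":
        return cls(
            anatomy=AnatomyFixture.from_dict(d["anatomy"]),
            hip_center_femur=d["hip_center_femur"],
            hip_center_pelvis=d["hip_center_pelvis"],
            knee_center_femur=d["knee_center_femur"],
            ankle_center_tibia=d["ankle_center_tibia"],
            knee_axis_point=d["knee_axis_point"],
            knee_axis_direction=d["knee_axis_direction"],
            ankle_axis_point=d["ankle_axis_point"],
            ankle_axis_direction=d["ankle_axis_direction"],
            muscles=tuple(
                MuscleUnit(m["name"], m["fmax"], m["pcsa"],
                           tuple((seg, np.array(pt)) for seg, pt in m["path"]))
                for m in d["muscles"]),
            ligaments={k: LigamentSpec.from_dict(v) for k, v in d["ligaments"].items()},
            patella_coupling=PatellaCoupling(np.array(d["patella_coupling"]["knot_angles"]),
                                             np.array(d["patella_coupling"]["knot_poses"])),
            placement=RigidTransform.from_dict(d["placement"]),
            surgical_params=d.get("surgical_params"),
            is_postop=d.get("is_postop", False),
        )


# ---------------------------------------------------------------------
# generic muscle atlas
# ---------------------------------------------------------------------

def _atlas_landmarks(height: float) -> dict:
    """Landmark set of a skeleton of the given stature, matching the
    subject landmark layout so that per-segment affines can be fitted."""
    from .synthetic_data import generate_anatomy
    return generate_anatomy(seed=0, height=height, noise=0.0).landmarks


def default_atlas(height: float = ATLAS_HEIGHT) -> tuple:
    """Reduced 16-unit lower-limb atlas (left limb) with landmark set.

    Returns ``(muscles, landmarks)``; attachment coordinates are in the
    atlas skeleton's segment frames and must be registered onto a
    subject via per-segment affine transforms.
    """
    s = height / ATLAS_HEIGHT
    L_f = 0.245 * height
    L_t = 0.246 * height
    L_foot = 0.152 * height
    kc = np.array([0.0, -L_f, 0.0])
    heel = np.array([-0.35 * L_foot, -30.0 * s, 0.0])
    tub = np.array([35.0 * s, -40.0 * s, 0.0])  # tibial tuberosity

    def M(name, fmax, pcsa, *path):
        return MuscleUnit(name, fmax, pcsa, tuple(path))

    quad_path_tail = (("patella", np.array([0.0, 0.0, 0.0])), ("tibia", tub))
    muscles = (
        M("gluteus_maximus", 1900.0, 31.0,
          ("pelvis", np.array([-110.0, 30.0, -50.0]) * s),
          ("pelvis", np.array([-80.0, -70.0, -55.0]) * s),   # wraps the ischium
          ("femur", np.array([-22.0, -150.0, -28.0]) * s)),
        M("gluteus_medius", 1800.0, 30.0,
          ("pelvis", np.array([-20.0, 10.0, -110.0]) * s),
          ("femur", np.array([-8.0, -18.0, -52.0]) * s)),
        M("hip_external_rotators", 800.0, 13.0,
          ("pelvis", np.array([-85.0, -40.0, -25.0]) * s),
          ("femur", np.array([-12.0, -12.0, -48.0]) * s)),
        M("gluteus_minimus", 800.0, 13.0,
          ("pelvis", np.array([35.0, -5.0, -95.0]) * s),
          ("femur", np.array([-18.0, -22.0, -48.0]) * s)),
        M("iliopsoas", 1500.0, 25.0,
          ("pelvis", np.array([20.0, -40.0, -70.0]) * s),
          ("femur", np.array([8.0, -45.0, 8.0]) * s)),
        M("adductor_magnus", 1200.0, 20.0,
          ("pelvis", np.array([30.0, -90.0, -45.0]) * s),
          ("femur", np.array([2.0, -0.45 * L_f, 18.0 * s]))),
        M("hamstrings_medial", 1300.0, 21.0,
          ("pelvis", np.array([-60.0, -80.0, -55.0]) * s),
          ("tibia", np.array([-22.0, -55.0, 22.0]) * s)),
        M("hamstrings_lateral", 1300.0, 21.0,
          ("pelvis", np.array([-62.0, -80.0, -68.0]) * s),
          ("tibia", np.array([-15.0, -28.0, -42.0]) * s)),
        M("rectus_femoris", 1200.0, 20.0,
          ("pelvis", np.array([40.0, -30.0, -70.0]) * s),
          ("femur", kc + np.array([35.0, 0.45 * L_f, 0.0 * s])),
          *quad_path_tail),
        M("vastus_medialis", 1300.0, 21.0,
          ("femur", kc + np.array([18.0, 0.30 * L_f, 12.0 * s])),
          *quad_path_tail),
        M("vastus_lateralis", 1900.0, 31.0,
          ("femur", kc + np.array([18.0, 0.33 * L_f, -16.0 * s])),
          *quad_path_tail),
        M("vastus_intermedius", 1300.0, 21.0,
          ("femur", kc + np.array([22.0, 0.28 * L_f, 0.0])),
          *quad_path_tail),
        M("gastrocnemius_medialis", 1600.0, 26.0,
          ("femur", kc + np.array([-20.0, 14.0 * s, 14.0 * s])),
          ("femur", kc + np.array([-30.0, 2.0 * s, 14.0 * s])),  # wraps condyle
          ("foot", heel)),
        M("gastrocnemius_lateralis", 1100.0, 18.0,
          ("femur", kc + np.array([-20.0, 14.0 * s, -16.0 * s])),
          ("femur", kc + np.array([-30.0, 2.0 * s, -16.0 * s])),
          ("foot", heel)),
        M("soleus", 3500.0, 58.0,
          ("tibia", np.array([-16.0 * s, -0.2 * L_t, 2.0 * s])),
          ("foot", heel)),
        M("tibialis_anterior", 1100.0, 18.0,
          ("tibia", np.array([16.0 * s, -0.25 * L_t, 8.0 * s])),
          ("foot", np.array([0.15 * L_foot, -10.0 * s, 10.0 * s]))),
    )
    return muscles, _atlas_landmarks(height)


# ---------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------

def _default_patella_coupling(anatomy: AnatomyFixture) -> PatellaCoupling:
    """Patella knot table from the congruent arc-of-circle geometry of
    the femoral component: the patella button rides on a circular
    trochlear arc, rotating around it as the knee flexes."""
    kc = anatomy.knee_center_femur
    center = kc + np.array([5.0, 10.0, 0.0])
    radius = 38.0
    angles = np.arange(0.0, 121.0, 15.0)
    beta0 = np.deg2rad(25.0)
    poses = []
    for a in angles:
        beta = beta0 - 0.7 * np.deg2rad(a)
        pos = center + radius * np.array([np.cos(beta), np.sin(beta), 0.0])
        poses.append([pos[0], pos[1], -0.7 * a])
    return PatellaCoupling(knot_angles=angles, knot_poses=np.array(poses))


def knee_axis_from_implant(posterior_arc_points, min_arc_deg: float = 10.0):
    """Hinge axis of the post-operative knee from the posterior arc of
    the femoral component.

    Fits a cylinder to points sampling the posterior condylar curvature
    (the region in contact with the insert during most of the cycle)
    and returns ``(axis_direction, axis_point)``.  An arc subtending
    less than ``min_arc_deg`` is rejected as ill-conditioned.
    """
    pts = np.asarray(posterior_arc_points, dtype=float)
    if len(pts) < 6:
        raise DegenerateInputError("need at least 6 posterior-arc points")
    fit = fit_cylinder(pts, initial_axis=[0.0, 0.0, 1.0])
    rel = pts - fit.axis_point
    d = fit.axis_direction
    radial = rel - np.outer(rel @ d, d)
    ang = np.arctan2(radial @ _any_orthogonal(d, 1), radial @ _any_orthogonal(d, 0))
    span = np.ptp(np.unwrap(np.sort(ang)))
    span = min(span, 2 * np.pi - span) if span > np.pi else span
    if np.rad2deg(span) < min_arc_deg:
        raise DegenerateInputError(
            f"posterior arc spans only {np.rad2deg(span):.1f} deg; axis ill-conditioned")
    return fit.axis_direction, fit.axis_point


def _any_orthogonal(d, which):
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ d) * d
    e1 /= np.linalg.norm(e1)
    if which == 0:
        return e1
    return np.cross(d, e1)


def build_model(anatomy: AnatomyFixture, atlas=None,
                ligament_params: Optional[dict] = None) -> LowerLimbModel:
    """Assemble the pre-operative subject-specific model.

    The hip centre is the fitted femoral-head sphere centre, the knee
    and ankle hinges are fitted condylar/trochlear cylinder axes, and
    atlas muscle attachments are mapped through per-segment affine
    landmark registrations.  Ligament resting lengths default to the
    pre-operative path lengths at full extension; ``ligament_params``
    may override ``{"MCL": {"k": ..., "eps_l": ..., "L0": ...}, ...}``.
    """
    if atlas is None:
        atlas = default_atlas()
    atlas_muscles, atlas_landmarks = atlas

    hip = fit_sphere(anatomy.femoral_head_cloud)
    knee = fit_cylinder(anatomy.condyle_cloud, initial_axis=[0.0, 0.0, 1.0])
    ankle = fit_cylinder(anatomy.trochlea_cloud, initial_axis=[0.0, 0.0, 1.0])

    # per-segment affine registration of the atlas onto the subject
    transforms = {}
    for seg in ("pelvis", "femur", "tibia", "foot"):
        names = sorted(atlas_landmarks[seg])
        src = np.array([atlas_landmarks[seg][n] for n in names])
        tgt = np.array([anatomy.landmarks[seg][n] for n in names])
        transforms[seg] = fit_affine(src, tgt)

    muscles = []
    for m in atlas_muscles:
        path = tuple(
            (seg, pt if seg == "patella" else apply_affine(transforms[seg], pt))
            for seg, pt in m.path)
        muscles.append(replace(m, path=path))

    # collateral ligaments; resting length = pre-op length at extension
    defaults = {"MCL": {"k": 4000.0, "eps_l": 0.03},
                "LCL": {"k": 2000.0, "eps_l": 0.03}}
    if ligament_params:
        for name, p in ligament_params.items():
            defaults.setdefault(name, {}).update(p)
    preop_tibia = RigidTransform(np.eye(3), anatomy.knee_center_femur)
    femur_pose = RigidTransform.identity()
    ligaments = {}
    for name, origin, insertion, via in (
            ("MCL", anatomy.mcl_origin, anatomy.mcl_insertion, anatomy.mcl_via),
            ("LCL", anatomy.lcl_origin, anatomy.lcl_insertion, None)):
        p = defaults[name]
        lig = LigamentSpec(name=name, origin=origin, insertion=insertion,
                           via_point=via, k=p["k"], eps_l=p["eps_l"], L0=1.0)
        L0 = p.get("L0") or path_length(lig, femur_pose, preop_tibia)
        ligaments[name] = lig.with_resting_length(L0)

    return LowerLimbModel(
        anatomy=anatomy,
        hip_center_femur=hip.center,
        hip_center_pelvis=anatomy.hip_center_pelvis,
        knee_center_femur=anatomy.knee_center_femur,
        ankle_center_tibia=anatomy.ankle_center_tibia,
        knee_axis_point=knee.axis_point,
        knee_axis_direction=knee.axis_direction,
        ankle_axis_point=ankle.axis_point,
        ankle_axis_direction=ankle.axis_direction,
        muscles=tuple(muscles),
        ligaments=ligaments,
        patella_coupling=_default_patella_coupling(anatomy),
        placement=preop_tibia,
        is_postop=False,
    )
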