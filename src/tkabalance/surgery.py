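"""TKA component placement from the five surgical cut-plane variables.

The five variables a surgeon controls in pre-operative planning, after
mechanical-axis alignment with the hip and ankle centres, are:

====================  =========  =====================================
variable              range      meaning (left knee)
====================  =========  =====================================
``vv_femur``          -3..3 deg  frontal tilt of the distal femoral cut
                                 (positive = varus: rotation about the
                                 anterior axis tilting the cut lower
                                 laterally once placed)
``vv_tibia``          -3..3 deg  frontal tilt of the tibial cut
                                 (positive = varus)
``ext_rot_femur``     0..6 deg   femoral component external rotation
                                 about the mechanical axis
``post_slope``        3..5 deg   posterior-inferior sagittal tilt of
                                 the tibial cut
``gap``               18..28 mm  distance between the femoral and
                                 tibial distal cut planes, measured
                                 along the femoral mechanical axis at
                                 full extension
====================  =========  =====================================

Values outside the listed sweep ranges raise a warning, not an error.

Placement logic: each component is rigidly attached to its cut plane,
so a cut rotation (about the plane centroid) carries the bone — with
its ligament attachments — in the opposite sense relative to the joint
frame defined by the implant.  At full extension the tibial component's
superior axis is aligned with the femoral component's distal normal
(minimal rotation, no transverse twist transfer) and the tibial plane
centroid sits ``gap`` millimetres distal to the femoral plane centroid
along the femoral mechanical axis.  Femoral external rotation does not
move the extension placement (it is a rotation about the mechanical
axis); it reorients the post-operative hinge axis and therefore acts
through knee flexion.  Gait kinematics are not re-solved per
configuration: the same joint-angle trajectories drive every placement,
assuming post-operative compensation preserves normal kinematics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .knee_model import LowerLimbModel, knee_axis_from_implant
from .synthetic_data import AnatomyFixture, FEMORAL_CUT_OFFSET, TIBIAL_CUT_OFFSET
from .transforms import RigidTransform, rot_about_axis, rotation_between

__all__ = ["SurgicalParams", "CutPlanes", "neutral_params", "compute_cut_planes",
           "place_components"]

SWEEP_RANGES = {
    "vv_femur": (-3.0, 3.0),
    "vv_tibia": (-3.0, 3.0),
    "ext_rot_femur": (0.0, 6.0),
    "post_slope": (3.0, 5.0),
    "gap": (18.0, 28.0),
}


@dataclass(frozen=True)
class SurgicalParams:
    """The five cut-plane variables (degrees; gap in mm)."""

    vv_femur: float = 0.0
    vv_tibia: float = 0.0
    ext_rot_femur: float = 0.0
    post_slope: float = 3.0
    gap: float = 26.0

    def __post_init__(self):
        for name, (lo, hi) in SWEEP_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                warnings.warn(
                    f"{name}={v} outside the usual planning range [{lo}, {hi}]",
                    stacklevel=3)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in SWEEP_RANGES}

    @classmethod
    def from_dict(cls, d: dict) -> "SurgicalParams":
        return cls(**{k: float(d[k]) for k in SWEEP_RANGES if k in d})

    def replace(self, **kw) -> "SurgicalParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CutPlanes:
    """Distal cut planes: femoral in the femur frame (normal pointing
    distally), tibial in the tibia frame (normal pointing proximally)."""

    femoral_point: np.ndarray
    femoral_normal: np.ndarray
    tibial_point: np.ndarray
    tibial_normal: np.ndarray

    def __post_init__(self):
        for name in ("femoral_point", "femoral_normal", "tibial_point", "tibial_normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("femoral_normal", "tibial_normal"):
            n = getattr(self, name)
            if abs(np.linalg.norm(n) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must be a unit vector")


def neutral_params(anatomy: AnatomyFixture) -> SurgicalParams:
    """The neutral plan: all angles zero except a 3 deg posterior slope,
    gap equal to the implant thickness."""
    return SurgicalParams(vv_femur=0.0, vv_tibia=0.0, ext_rot_femur=0.0,
                          post_slope=3.0, gap=anatomy.implant_thickness)


def _mech_axis(model: LowerLimbModel) -> np.ndarray:
    u = model.hip_center_femur - model.knee_center_femur
    return u / np.linalg.norm(u)


def compute_cut_planes(params: SurgicalParams, model: LowerLimbModel) -> CutPlanes:
    """Cut planes in bone frames for a set of surgical parameters.

    The femoral plane starts perpendicular to the mechanical axis
    (hip centre to knee centre) and is rotated by ``vv_femur`` about the
    anterior axis and ``ext_rot_femur`` about the mechanical axis; the
    tibial plane is rotated by ``vv_tibia`` (frontal) and ``post_slope``
    (sagittal).  All rotations are about the plane centroids.
    """
    u = _mech_axis(model)
    anterior = np.array([1.0, 0.0, 0.0])
    ml_axis = np.array([0.0, 0.0, 1.0])

    c_f = model.knee_center_femur + FEMORAL_CUT_OFFSET * u
    R_f = (rot_about_axis(u, params.ext_rot_femur).rotation
           @ rot_about_axis(anterior, params.vv_femur).rotation)
    n_f = R_f @ (-u)

    c_t = np.array([0.0, -TIBIAL_CUT_OFFSET, 0.0])
    R_t = (rot_about_axis(anterior, params.vv_tibia).rotation
           @ rot_about_axis(ml_axis, params.post_slope).rotation)
    n_t = R_t @ np.array([0.0, 1.0, 0.0])

    return CutPlanes(femoral_point=c_f, femoral_normal=n_f,
                     tibial_point=c_t, tibial_normal=n_t)


def place_components(cuts: CutPlanes, params: SurgicalParams,
                     model: LowerLimbModel) -> LowerLimbModel:
    """Post-operative model for the given cut planes.

    Returns a copy of ``model`` whose extension placement follows the
    component assembly (see module docstring), and whose knee hinge is
    the implant posterior-arc axis carried by the femoral component
    rotations.  Ligament attachments stay fixed to their bones and move
    rigidly with them; resting lengths are untouched, so post-operative
    strain is read against the pre-operative length.
    """
    if params.gap <= 0:
        raise ParameterError("gap must be positive")
    u = _mech_axis(model)
    anterior = np.array([1.0, 0.0, 0.0])

    # tibia-bone orientation in the femur frame: minimal rotation taking
    # the tibial plane normal onto the femoral component's superior axis
    s_f = -cuts.femoral_normal
    R_B = rotation_between(cuts.tibial_normal, s_f)
    p = (cuts.femoral_point - params.gap * u) - R_B @ cuts.tibial_point
    placement = RigidTransform(R_B, p)

    # post-operative hinge: posterior arc of the femoral component,
    # reoriented by the component rotations about the plane centroid
    axis_dir, axis_pt = knee_axis_from_implant(model.anatomy.posterior_arc_cloud)
    R_fc = (rot_about_axis(u, params.ext_rot_femur, cuts.femoral_point)
            @ rot_about_axis(anterior, params.vv_femur, cuts.femoral_point))
    axis_pt = R_fc.apply(axis_pt)
    axis_dir = R_fc.rotation @ axis_dir

    return replace(model, placement=placement, knee_axis_point=axis_pt,
                   knee_axis_direction=axis_dir, surgical_params=params.to_dict(),
                   is_postop=True)
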