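"""Collateral-ligament geometry, strain and nonlinear spring force.

The lateral collateral ligament (LCL) is a single straight line from its
femoral origin to the fibular insertion.  The medial collateral ligament
(MCL) wraps over the medial tibial margin and is modelled as two
connected line segments through a via point.  Both are one-bundle
tension-only nonlinear springs with a quadratic toe region: slack under
compression, stiffening quadratically up to twice the reference strain,
then linear.

Strain is reported relative to the pre-operative length at full
extension by default, because post-operative elongation is clinically
read as a percentage of the ligament's initial length; a literature
resting length may be supplied instead through ``LigamentSpec.L0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ParameterError
from .transforms import RigidTransform

__all__ = ["LigamentSpec", "ElongationTrace", "path_length", "strain", "force",
           "elongation_trace"]

#: strain beyond which irreversible ligament damage is assumed
DAMAGE_THRESHOLD = 0.10


@dataclass(frozen=True)
class LigamentSpec:
    """One-bundle collateral ligament.

    Attachments are expressed in body-fixed frames: the origin in the
    femur frame, the insertion (and the MCL via point) in the tibia
    frame, all in mm.  ``k`` is the spring stiffness parameter (N),
    ``eps_l`` the reference strain and ``L0`` the resting length (mm)
    used as the strain denominator.
    """

    name: str
    origin: np.ndarray
    insertion: np.ndarray
    via_point: Optional[np.ndarray] = None
    k: float = 2000.0
    eps_l: float = 0.03
    L0: float = 60.0

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "insertion", np.asarray(self.insertion, dtype=float))
        if self.via_point is not None:
            object.__setattr__(self, "via_point", np.asarray(self.via_point, dtype=float))
        if self.k <= 0:
            raise ParameterError("ligament stiffness must be positive")
        if not (0 < self.eps_l < 0.1):
            raise ParameterError("reference strain must lie in (0, 0.1)")
        if self.L0 <= 0:
            raise ParameterError("resting length must be positive")

    def with_resting_length(self, L0: float) -> "LigamentSpec":
        return replace(self, L0=float(L0))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "origin": self.origin.tolist(),
            "insertion": self.insertion.tolist(),
            "via_point": None if self.via_point is None else self.via_point.tolist(),
            "k": self.k,
            "eps_l": self.eps_l,
            "L0": self.L0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LigamentSpec":
        via = d.get("via_point")
        return cls(name=d["name"], origin=np.array(d["origin"]),
                   insertion=np.array(d["insertion"]),
                   via_point=None if via is None else np.array(via),
                   k=d["k"], eps_l=d["eps_l"], L0=d["L0"])


@dataclass(frozen=True)
class ElongationTrace:
    """Ligament length and strain over one normalised gait cycle
    (101 samples, 0-100% in 1% steps)."""

    name: str
    percent_cycle: np.ndarray
    length: np.ndarray
    strain: np.ndarray
    surgical_params: Optional[dict] = None

    def __post_init__(self):
        for f in ("percent_cycle", "length", "strain"):
            object.__setattr__(self, f, np.asarray(getattr(self, f), dtype=float))
        if len(self.length) != len(self.percent_cycle) or len(self.strain) != len(self.length):
            raise ParameterError("trace arrays must have equal length")
        if np.any(self.length <= 0):
            raise ParameterError("ligament length must stay positive")


def path_length(lig: LigamentSpec, femur_pose: RigidTransform,
                tibia_pose: RigidTransform) -> float:
    """Ligament path length (mm) for the given body poses.

    Straight origin-insertion distance for a ligament without a via
    point; sum of the two segment lengths through the via point (fixed
    in the tibia frame) otherwise.
    """
    o = femur_pose.apply(lig.origin)
    i = tibia_pose.apply(lig.insertion)
    if lig.via_point is None:
        return float(np.linalg.norm(i - o))
    v = tibia_pose.apply(lig.via_point)
    return float(np.linalg.norm(v - o) + np.linalg.norm(i - v))


def strain(length: float, L0: float):
    """Engineering strain (length - L0) / L0; vectorised over ``length``."""
    if L0 <= 0:
        raise ParameterError("resting length must be positive")
    return (np.asarray(length, dtype=float) - L0) / L0


def force(eps, k: float, eps_l: float):
    """Tension of the one-bundle nonlinear spring (N).

    Zero when slack (eps <= 0), quadratic toe ``k eps^2 / (4 eps_l)`` up
    to ``2 eps_l``, then linear ``k (eps - eps_l)``; continuous with
    continuous slope at the transition.  Vectorised over ``eps``.
    """
    if k <= 0 or eps_l <= 0:
        raise ParameterError("k and eps_l must be positive")
    e = np.asarray(eps, dtype=float)
    toe = 0.25 * k * e**2 / eps_l
    linear = k * (e - eps_l)
    out = np.where(e <= 0, 0.0, np.where(e <= 2 * eps_l, toe, linear))
    return float(out) if np.isscalar(eps) or np.ndim(eps) == 0 else out


def elongation_trace(model, trial, lig: LigamentSpec,
                     surgical_params: Optional[dict] = None) -> ElongationTrace:
    """Ligament length and strain over one gait cycle of ``trial``.

    The knee flexion trace is resampled to the standard 101-point cycle
    axis; at each sample the tibia pose follows the model's hinge
    kinematics (post-operative placement included for a placed model)
    and the path length is measured in the femur frame.
    """
    from .validation import resample_percent_cycle

    flexion = resample_percent_cycle(trial.knee_flexion, trial.heel_strikes)
    percent = np.arange(101.0)
    femur_pose = RigidTransform.identity()
    lengths = np.array([
        path_length(lig, femur_pose, model.tibia_pose(angle)) for angle in flexion
    ])
    return ElongationTrace(
        name=lig.name,
        percent_cycle=percent,
        length=lengths,
        strain=strain(lengths, lig.L0),
        surgical_params=surgical_params,
    )
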