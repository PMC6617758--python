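"""Gait mechanics: inverse dynamics, static optimization, knee loads.

The solution chain mirrors standard musculoskeletal practice:

1. joint-angle trajectories (from the gait trial, or recovered from
   markers by global-optimization inverse kinematics) drive the 11-DOF
   model;
2. inverse dynamics balances the recorded ground reaction, yielding the
   generalized forces on all coordinates, including the six pelvis
   residual actuators that stand in for the missing torso and
   contralateral limb;
3. static optimization resolves muscle redundancy per frame by
   minimizing the sum of squared muscle stresses subject to the joint
   torque balance and physiological force bounds;
4. the knee contact force is the joint reaction of the distal (shank +
   foot) chain with muscle forces routed through the patellar pulley
   and ligament tensions included, normalized to body weight and
   resampled onto the 101-sample cycle axis;
5. the axial load can be decomposed into medial/lateral compartment
   forces with a transparent lever-arm model.

Inverse dynamics is computed by projecting every body's Newton-Euler
wrench through the kinematic Jacobians (virtual-work formulation), with
body kinematics differentiated in time by periodic cubic splines.  The
solution is verified by an independent whole-body momentum balance
(`verify_momentum`): the rates of change of total linear and angular
momentum, computed with plain second-order finite differences, must
match the sum of gravity, ground reaction and the solved pelvis
residuals.  The residual RMSE of this replay, normalized by the peak
external load, is the model verification statistic.

Internally SI units (m, rad, s, N) are used; the public containers keep
forces in N and torques in N m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import InfeasibleFrameError, ParameterError
from .knee_model import COORDINATES, LowerLimbModel, N_COORDINATES
from .synthetic_data import ContactForceRecord, GaitTrial, GRAVITY
from .validation import resample_percent_cycle

__all__ = [
    "GeneralizedForces", "MuscleForces", "CompartmentForces",
    "inverse_kinematics", "inverse_dynamics", "verify_momentum",
    "static_optimization", "solve_muscle_forces", "knee_contact_force",
    "decompose_compartments", "forward_markers",
]

_BODIES = ("pelvis", "femur", "tibia", "foot")
_DISTAL = frozenset({"tibia", "foot"})
_GRAV = np.array([0.0, -GRAVITY, 0.0])  # m/s^2
_MM = 1e-3


@dataclass(frozen=True)
class GeneralizedForces:
    """Per-frame generalized forces: N for the pelvis translations,
    N m for all rotational coordinates."""

    time: np.ndarray
    values: np.ndarray          # (n, 11)
    names: tuple = COORDINATES

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.time), N_COORDINATES):
            raise ParameterError("generalized force shape mismatch")
        if not np.all(np.isfinite(v)):
            raise ParameterError("generalized forces must be finite")
        object.__setattr__(self, "values", v)

    @property
    def pelvis_residual_force(self) -> np.ndarray:
        """World-frame net residual force (N) on the pelvis, per frame."""
        return self.values[:, 0:3]


@dataclass(frozen=True)
class MuscleForces:
    """Per-frame muscle tensions (N), one column per muscle."""

    time: np.ndarray
    values: np.ndarray
    names: tuple
    kkt_residuals: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class CompartmentForces:
    """Medial and lateral compartment forces (BW)."""

    medial: np.ndarray
    lateral: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "medial", np.asarray(self.medial, dtype=float))
        object.__setattr__(self, "lateral", np.asarray(self.lateral, dtype=float))


# ---------------------------------------------------------------------
# trajectories and body kinematics
# ---------------------------------------------------------------------

def q_from_trial(trial: GaitTrial) -> np.ndarray:
    """Stack the trial's pose series into (n, 11) generalized coordinates
    (mm and degrees, ordered as ``COORDINATES``)."""
    return np.column_stack([
        trial.pelvis_pose, trial.hip_angles, trial.knee_flexion, trial.ankle_flexion,
    ])


def _periodic(y: np.ndarray) -> np.ndarray:
    """Force exact periodicity by averaging the duplicate end samples."""
    y = y.copy()
    mean = 0.5 * (y[0] + y[-1])
    y[0] = mean
    y[-1] = mean
    return y


def _pspline(t, y):
    return CubicSpline(t, _periodic(np.asarray(y, dtype=float)), axis=0,
                       bc_type="periodic")


def _periodic_gradient(y: np.ndarray, dt: float) -> np.ndarray:
    """Second-order central difference with periodic wrap; the duplicate
    final sample (same phase as the first) is handled transparently."""
    core = np.asarray(y, dtype=float)[:-1]    # unique samples
    out = (np.roll(core, -1, axis=0) - np.roll(core, 1, axis=0)) / (2 * dt)
    return np.concatenate([out, out[:1]], axis=0)


class _BodyKinematics:
    """World pose, velocity and acceleration of every segment over one
    periodic gait cycle, differentiated with periodic splines."""

    def __init__(self, model: LowerLimbModel, trial: GaitTrial):
        self.model = model
        self.trial = trial
        self.t = trial.time
        self.q = q_from_trial(trial)
        n = len(self.t)
        anat = model.anatomy
        self.masses = {b: anat.segment_masses[b] for b in _BODIES}
        self.inertias = {b: anat.segment_inertias[b] * 1e-6 for b in _BODIES}  # kg m^2
        self.coms_local = {b: anat.segment_coms[b] for b in _BODIES}           # mm

        self.R = {b: np.zeros((n, 3, 3)) for b in _BODIES}
        self.r_com = {b: np.zeros((n, 3)) for b in _BODIES}                    # m
        self.origin = {b: np.zeros((n, 3)) for b in _BODIES}                   # m
        for k in range(n):
            poses = model.segment_poses(self.q[k])
            for b in _BODIES:
                T = poses[b]
                self.R[b][k] = T.rotation
                self.origin[b][k] = T.translation * _MM
                self.r_com[b][k] = T.apply(self.coms_local[b]) * _MM

        dt = self.t[1] - self.t[0]
        self.v_com, self.a_com = {}, {}
        self.omega, self.alpha = {}, {}
        for b in _BODIES:
            sp = _pspline(self.t, self.r_com[b])
            self.v_com[b] = sp(self.t, 1)
            self.a_com[b] = sp(self.t, 2)
            w = self._angular_velocity(self.R[b], dt)
            self.omega[b] = w
            self.alpha[b] = _pspline(self.t, w)(self.t, 1)

    @staticmethod
    def _angular_velocity(R: np.ndarray, dt: float) -> np.ndarray:
        """World-frame angular velocity from central finite rotations."""
        n = len(R)
        core = R[:-1]
        w = np.zeros((n - 1, 3))
        for k in range(n - 1):
            Rp = core[(k + 1) % (n - 1)]
            Rm = core[(k - 1) % (n - 1)]
            w[k] = Rotation.from_matrix(Rp @ Rm.T).as_rotvec() / (2 * dt)
        return np.concatenate([w, w[:1]], axis=0)

    def world_inertia(self, body: str, k: int) -> np.ndarray:
        R = self.R[body][k]
        return R @ self.inertias[body] @ R.T


def _jacobians(model: LowerLimbModel, q: np.ndarray, delta: float = 1e-4):
    """COM translational and angular Jacobians of every body by central
    finite differences, per native coordinate unit (mm for the pelvis
    translations, deg for all rotations): m/unit and rad/unit."""
    Jv = {b: np.zeros((3, N_COORDINATES)) for b in _BODIES}
    Jw = {b: np.zeros((3, N_COORDINATES)) for b in _BODIES}
    coms = {b: model.anatomy.segment_coms[b] for b in _BODIES}
    for j in range(N_COORDINATES):
        qp = q.copy()
        qm = q.copy()
        qp[j] += delta
        qm[j] -= delta
        pp = model.segment_poses(qp)
        pm = model.segment_poses(qm)
        for b in _BODIES:
            dr = (pp[b].apply(coms[b]) - pm[b].apply(coms[b])) * _MM / (2 * delta)
            Jv[b][:, j] = dr
            dR = pp[b].rotation @ pm[b].rotation.T
            Jw[b][:, j] = Rotation.from_matrix(dR).as_rotvec() / (2 * delta)
    return Jv, Jw


def _point_jacobian(model: LowerLimbModel, q: np.ndarray, body: str,
                    point_local_mm: np.ndarray, delta: float = 1e-4) -> np.ndarray:
    """Translational Jacobian (m per coordinate unit) of a material
    point of ``body``."""
    J = np.zeros((3, N_COORDINATES))
    for j in range(N_COORDINATES):
        qp = q.copy()
        qm = q.copy()
        qp[j] += delta
        qm[j] -= delta
        pp = model.segment_poses(qp)[body].apply(point_local_mm)
        pm = model.segment_poses(qm)[body].apply(point_local_mm)
        J[:, j] = (pp - pm) * _MM / (2 * delta)
    return J


#: scale factors turning per-coordinate-unit generalized forces into
#: N (translations, per mm) and N m (rotations, per deg)
_COORD_SCALE = np.array([1e3, 1e3, 1e3] + [np.rad2deg(1.0)] * 8)


def inverse_dynamics(model: LowerLimbModel, trial: GaitTrial,
                     angles: Optional[np.ndarray] = None) -> GeneralizedForces:
    """Generalized forces balancing the trial's motion and ground reaction.

    Projects each body's Newton-Euler wrench (inertial minus gravity)
    and the ground reaction applied at the centre of pressure through
    the kinematic Jacobians.  The first six components are the pelvis
    residual actuators absorbing the unmodelled torso and contralateral
    limb.  ``angles`` may override the trial's coordinate trajectories
    (e.g. with an inverse-kinematics solution).
    """
    kin = _BodyKinematics(model, trial)
    q_traj = kin.q if angles is None else np.asarray(angles, dtype=float)
    n = len(kin.t)
    tau = np.zeros((n, N_COORDINATES))
    for k in range(n):
        q = q_traj[k]
        Jv, Jw = _jacobians(model, q)
        acc = np.zeros(N_COORDINATES)
        for b in _BODIES:
            m = kin.masses[b]
            f_inert = m * (kin.a_com[b][k] - _GRAV)
            Iw = kin.world_inertia(b, k)
            n_inert = Iw @ kin.alpha[b][k] + np.cross(kin.omega[b][k],
                                                      Iw @ kin.omega[b][k])
            acc += Jv[b].T @ f_inert + Jw[b].T @ n_inert
        grf = kin.trial.grf[k]
        if np.linalg.norm(grf) > 0:
            foot_pose = model.segment_poses(q)["foot"]
            cop_local = foot_pose.inverse().apply(kin.trial.cop[k])
            Jp = _point_jacobian(model, q, "foot", cop_local)
            acc -= Jp.T @ grf
        # per-native-unit generalized forces -> N (per m) and N m (per rad)
        tau[k] = acc * _COORD_SCALE
    return GeneralizedForces(time=kin.t, values=tau)


def verify_momentum(model: LowerLimbModel, trial: GaitTrial,
                    gen_forces: GeneralizedForces) -> dict:
    """Whole-body momentum replay of an inverse-dynamics solution.

    Independently of the Jacobian projection, the rate of change of
    total linear momentum (plain periodic central differences) must
    equal gravity + ground reaction + the pelvis residual force; the
    rate of total angular momentum about the world origin must equal
    the corresponding external moments.  Returns the residual RMSEs and
    their values as a percentage of the peak external load.
    """
    kin = _BodyKinematics(model, trial)
    n = len(kin.t)
    dt = kin.t[1] - kin.t[0]
    total_mass = sum(kin.masses.values())

    # linear momentum from independent differencing of COM positions
    P = np.zeros((n, 3))
    L = np.zeros((n, 3))
    for b in _BODIES:
        v = _periodic_gradient(kin.r_com[b], dt)
        P += kin.masses[b] * v
        for k in range(n):
            L[k] += (np.cross(kin.r_com[b][k], kin.masses[b] * v[k])
                     + kin.world_inertia(b, k) @ kin.omega[b][k])
    P_dot = _periodic_gradient(P, dt)
    L_dot = _periodic_gradient(L, dt)

    F_res = gen_forces.pelvis_residual_force
    # world residual moment from the Euler-coordinate generalized forces
    q_traj = q_from_trial(trial)
    M_res = np.zeros((n, 3))
    r_pelvis = kin.origin["pelvis"]
    for k in range(n):
        G = _pelvis_rotation_generators(q_traj[k])
        M_res[k] = np.linalg.solve(G.T, gen_forces.values[k, 3:6])

    grf = trial.grf
    cop_m = trial.cop * _MM
    force_residual = P_dot - (total_mass * _GRAV + grf + F_res)
    moment_grf = np.cross(cop_m, grf)
    moment_grav = np.zeros((n, 3))
    for b in _BODIES:
        moment_grav += np.cross(kin.r_com[b], kin.masses[b] * _GRAV)
    moment_residual = L_dot - (moment_grav + moment_grf + M_res
                               + np.cross(r_pelvis, F_res))

    peak_force = float(np.max(np.linalg.norm(grf, axis=1)))
    peak_moment = float(np.max(np.linalg.norm(moment_grf, axis=1)))
    rmse_f = float(np.sqrt(np.mean(force_residual**2)))
    rmse_m = float(np.sqrt(np.mean(moment_residual**2)))
    return {
        "force_rmse": rmse_f,
        "moment_rmse": rmse_m,
        "force_rmse_percent": 100.0 * rmse_f / peak_force,
        "moment_rmse_percent": 100.0 * rmse_m / max(peak_moment, 1e-12),
        "peak_external_force": peak_force,
    }


def _pelvis_rotation_generators(q: np.ndarray, delta: float = 1e-6) -> np.ndarray:
    """Matrix G with columns = world rotation axes generated by each
    pelvis Euler coordinate (rad per deg), so omega = G @ qdot_euler."""
    G = np.zeros((3, 3))
    base = Rotation.from_euler("xyz", q[3:6], degrees=True).as_matrix()
    for j in range(3):
        qp = q[3:6].copy()
        qp[j] += delta
        Rp = Rotation.from_euler("xyz", qp, degrees=True).as_matrix()
        G[:, j] = Rotation.from_matrix(Rp @ base.T).as_rotvec() / np.deg2rad(delta)
    return G


# ---------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------

def forward_markers(model: LowerLimbModel, q: np.ndarray) -> dict:
    """World positions of all anatomical landmarks at coordinates ``q``."""
    poses = model.segment_poses(q)
    out = {}
    for seg in _BODIES:
        for name, pt in model.anatomy.landmarks[seg].items():
            out[name] = poses[seg].apply(pt)
    return out


def _marker_residual(model, q, targets_flat, names_segments):
    poses = model.segment_poses(q)
    sim = np.concatenate([
        poses[seg].apply(model.anatomy.landmarks[seg][name])
        for name, seg in names_segments])
    return sim - targets_flat


def inverse_kinematics(markers: dict, model: LowerLimbModel,
                       q0: Optional[np.ndarray] = None,
                       tol: float = 1e-10) -> np.ndarray:
    """Recover coordinate trajectories from marker trajectories.

    ``markers`` maps marker names to (n, 3) world trajectories; names
    must match anatomical landmarks.  Each frame solves the global
    weighted least-squares pose over all 11 coordinates simultaneously;
    the first frame is initialised from ``q0`` or a zero-pose guess
    with the pelvis near the marker centroid, subsequent frames from
    the previous solution.
    """
    seg_of = {name: seg for seg in _BODIES
              for name in model.anatomy.landmarks[seg]}
    names_segments = [(n, seg_of[n]) for n in markers if n in seg_of]
    if not names_segments:
        raise ParameterError("no usable markers")
    n_frames = len(next(iter(markers.values())))
    q_out = np.zeros((n_frames, N_COORDINATES))
    q_prev = None
    if q0 is not None:
        q_prev = np.asarray(q0, dtype=float)
    for k in range(n_frames):
        target = np.concatenate([markers[n][k] for n, _ in names_segments])
        if q_prev is None:
            q_prev = np.zeros(N_COORDINATES)
            pelvis_names = [n for n, seg in names_segments if seg == "pelvis"]
            if pelvis_names:
                cent = np.mean([markers[n][k] for n in pelvis_names], axis=0)
                local = np.mean([model.anatomy.landmarks["pelvis"][n]
                                 for n in pelvis_names], axis=0)
                q_prev[0:3] = cent - local
        res = least_squares(
            lambda q: _marker_residual(model, q, target, names_segments),
            q_prev, xtol=tol, ftol=tol, gtol=tol, method="lm")
        if not np.all(np.isfinite(res.x)):
            raise InfeasibleFrameError("inverse kinematics diverged", frame=k)
        q_out[k] = res.x
        q_prev = res.x
    return q_out


# ---------------------------------------------------------------------
# static optimization
# ---------------------------------------------------------------------

#: coordinates actuated by muscles (pelvis residuals excluded)
ACTUATED = tuple(range(6, 11))


def muscle_lengths(model: LowerLimbModel, q: np.ndarray) -> np.ndarray:
    """Path length (mm) of every muscle at coordinates ``q``."""
    poses = model.segment_poses(q)
    out = np.zeros(len(model.muscles))
    for i, m in enumerate(model.muscles):
        pts = np.array([poses[seg].apply(pt) for seg, pt in m.path])
        out[i] = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    return out


def moment_arm_matrix(model: LowerLimbModel, q: np.ndarray,
                      delta: float = 0.25) -> np.ndarray:
    """Moment arms (m, tendon-excursion convention) of every muscle
    about every actuated coordinate: ``R[j, i] = -d l_i / d q_j``."""
    R = np.zeros((len(ACTUATED), len(model.muscles)))
    for row, j in enumerate(ACTUATED):
        qp = q.copy()
        qm = q.copy()
        qp[j] += delta
        qm[j] -= delta
        dl = (muscle_lengths(model, qp) - muscle_lengths(model, qm)) / (2 * delta)
        R[row] = -dl * _MM / np.deg2rad(1.0)      # mm/deg -> m/rad
    return R


def solve_stress_qp(R: np.ndarray, tau: np.ndarray, pcsa: np.ndarray,
                    fmax: np.ndarray) -> tuple:
    """Minimum-squared-stress muscle force distribution.

    Minimises ``sum (F_i / PCSA_i)^2`` subject to ``R F = tau`` and
    ``0 <= F_i <= Fmax_i``; returns ``(F, violation)`` with the torque
    residual vector.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    pcsa = np.asarray(pcsa, dtype=float)
    fmax = np.asarray(fmax, dtype=float)
    W = 1.0 / pcsa**2

    # The problem is a diagonal QP with box bounds, so the KKT
    # stationarity condition gives the primal in closed form from the
    # torque-balance multipliers:  F(lam) = clip(R^T lam / (2 W), 0, Fmax).
    # The dual equations R F(lam) = tau are piecewise linear and
    # monotone; solve them by least squares, then polish.
    def primal(lam):
        return np.clip((R.T @ lam) / (2.0 * W), 0.0, fmax)

    def dual_residual(lam):
        return R @ primal(lam) - tau

    def polish(lam):
        # semismooth Newton on the active set; the dual Jacobian is
        # R diag(free / 2W) R^T with `free` the strictly interior forces
        best_lam, best_res = lam, np.linalg.norm(dual_residual(lam))
        for _ in range(60):
            F = primal(lam)
            resid = R @ F - tau
            rn = np.linalg.norm(resid)
            if rn < best_res:
                best_lam, best_res = lam.copy(), rn
            if rn < 1e-12:
                break
            interior = (F > 0.0) & (F < fmax)
            J = (R[:, interior] / (2 * W[interior])) @ R[:, interior].T
            try:
                step = np.linalg.solve(J + 1e-12 * np.eye(len(tau)), -resid)
            except np.linalg.LinAlgError:
                break
            lam = lam + np.clip(step, -1e6, 1e6)
        return best_lam

    best = None
    for lam0 in (np.zeros(len(tau)),
                 np.linalg.lstsq(R @ np.diag(1.0 / (2 * W)) @ R.T, tau,
                                 rcond=None)[0]):
        sol = least_squares(dual_residual, lam0, method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        lam = polish(sol.x)
        cost = np.linalg.norm(dual_residual(lam))
        if best is None or cost < best[1]:
            best = (lam, cost)
    F = primal(best[0])
    violation = R @ F - tau
    if np.linalg.norm(violation) > 1e-8 * max(1.0, float(np.linalg.norm(tau))):
        # fall back to an interior-point solve when the dual Newton
        # stalls on a degenerate active set
        from scipy.optimize import LinearConstraint, minimize as _minimize

        res = _minimize(lambda x: float(np.sum(W * x**2)), F,
                        jac=lambda x: 2.0 * W * x,
                        hess=lambda x: np.diag(2.0 * W),
                        bounds=[(0.0, fm) for fm in fmax],
                        constraints=[LinearConstraint(R, tau, tau)],
                        method="trust-constr",
                        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 500})
        if np.linalg.norm(R @ res.x - tau) < np.linalg.norm(violation):
            F = np.clip(res.x, 0.0, fmax)
            violation = R @ F - tau
    return F, violation


def static_optimization(tau_actuated: np.ndarray, model: LowerLimbModel,
                        q: np.ndarray) -> tuple:
    """Muscle forces for one frame by minimum squared muscle stress.

    Solves the stress QP for the actuated coordinates (pelvis residuals
    excluded) at pose ``q``.  Returns ``(forces, info)`` with the KKT
    stationarity residual, the torque-balance violation and the
    objective; an unbalanced coordinate raises
    :class:`InfeasibleFrameError` naming it.
    """
    tau = np.asarray(tau_actuated, dtype=float)
    if tau.shape != (len(ACTUATED),):
        raise ParameterError("expected one torque per actuated coordinate")
    R = moment_arm_matrix(model, q)
    pcsa = np.array([m.pcsa for m in model.muscles])
    fmax = np.array([m.fmax for m in model.muscles])
    W = 1.0 / pcsa**2
    F, violation = solve_stress_qp(R, tau, pcsa, fmax)

    def obj(F):
        return float(np.sum(W * F**2))

    def grad(F):
        return 2.0 * W * F

    vnorm = float(np.linalg.norm(violation))
    if vnorm > 1e-6 * max(1.0, float(np.linalg.norm(tau))):
        worst = int(np.argmax(np.abs(violation)))
        raise InfeasibleFrameError(
            f"torque balance violated on {COORDINATES[ACTUATED[worst]]} "
            f"by {violation[worst]:.3g} N m",
            coordinate=COORDINATES[ACTUATED[worst]])
    # KKT stationarity on the free set
    g = grad(F)
    free = (F > 1e-7 * fmax) & (F < fmax * (1 - 1e-7))
    if np.any(free):
        lam, *_ = np.linalg.lstsq(R[:, free].T, g[free], rcond=None)
        stat = float(np.max(np.abs(R[:, free].T @ lam - g[free])))
        scale = max(1.0, float(np.max(np.abs(g))))
        kkt = stat / scale
    else:
        kkt = 0.0
    info = {"kkt_residual": kkt, "constraint_violation": vnorm,
            "objective": obj(F)}
    return F, info


def solve_muscle_forces(model: LowerLimbModel, trial: GaitTrial,
                        gen_forces: GeneralizedForces) -> MuscleForces:
    """Static optimization over every frame of a trial."""
    q_traj = q_from_trial(trial)
    n = len(trial.time)
    out = np.zeros((n, len(model.muscles)))
    kkt = np.zeros(n)
    for k in range(n):
        tau_act = gen_forces.values[k, list(ACTUATED)]
        F, info = static_optimization(tau_act, model, q_traj[k])
        out[k] = F
        kkt[k] = info["kkt_residual"]
    return MuscleForces(time=trial.time, values=out,
                        names=tuple(m.name for m in model.muscles),
                        kkt_residuals=kkt)


# ---------------------------------------------------------------------
# knee loads
# ---------------------------------------------------------------------

def _crossing_forces(model: LowerLimbModel, poses: dict, muscle, tension: float):
    """Forces exerted on distal-side bodies by a muscle crossing the
    knee: at each proximal->distal path transition the tension pulls the
    distal attachment toward its proximal neighbour (for the quadriceps
    this is the patellar-ligament line, i.e. the frictionless pulley)."""
    forces = []
    world = [(seg, poses[seg].apply(pt)) for seg, pt in muscle.path]
    for (seg_a, pa), (seg_b, pb) in zip(world[:-1], world[1:]):
        a_distal = seg_a in _DISTAL
        b_distal = seg_b in _DISTAL
        if a_distal == b_distal:
            continue
        prox_pt, dist_pt = (pb, pa) if a_distal else (pa, pb)
        dist_seg = seg_a if a_distal else seg_b
        line = prox_pt - dist_pt
        nrm = np.linalg.norm(line)
        if nrm < 1e-9:
            continue
        forces.append((dist_seg, dist_pt, tension * line / nrm))
    return forces


def _ligament_forces(model: LowerLimbModel, poses: dict):
    """(point, force) pairs on the tibia from the collateral springs."""
    from .ligament import force as lig_force, path_length, strain

    out = []
    femur, tibia = poses["femur"], poses["tibia"]
    for lig in model.ligaments.values():
        length = path_length(lig, femur, tibia)
        eps = strain(length, lig.L0)
        f = lig_force(float(eps), lig.k, lig.eps_l)
        if f <= 0:
            continue
        origin_w = femur.apply(lig.origin)
        attach_w = tibia.apply(lig.via_point if lig.via_point is not None
                               else lig.insertion)
        line = origin_w - attach_w
        out.append((attach_w, f * line / np.linalg.norm(line)))
    return out


def knee_contact_force(model: LowerLimbModel, trial: GaitTrial,
                       muscle_forces: MuscleForces,
                       include_ligaments: bool = True,
                       side: str = "tibia",
                       gen_forces: Optional[GeneralizedForces] = None) -> tuple:
    """Knee joint reaction from the force balance of the distal chain.

    For each frame the reaction transmitted through the knee equals the
    inertial force of shank + foot minus gravity, ground reaction,
    muscle forces applied to the distal segments (quadriceps routed
    through the patellar pulley) and ligament tensions.  With
    ``side="femur"`` the same reaction is evaluated from the proximal
    chain instead (pelvis + femur, using the pelvis residual force from
    ``gen_forces``); both routes must agree.  Returns
    ``(ContactForceRecord, per_frame)`` with the record in body weights
    on the 101-sample axis and ``per_frame`` a dict of raw arrays
    (force vector N, frontal moment about the knee centre N m).
    """
    if side not in ("tibia", "femur"):
        raise ParameterError("side must be 'tibia' or 'femur'")
    if side == "femur" and gen_forces is None:
        raise ParameterError("femur-side balance needs the generalized forces")
    kin = _BodyKinematics(model, trial)
    n = len(kin.t)
    bw = model.anatomy.body_weight
    bodies = _DISTAL if side == "tibia" else frozenset({"pelvis", "femur"})
    sign = 1.0 if side == "tibia" else -1.0
    F_joint = np.zeros((n, 3))
    M_frontal = np.zeros(n)
    for k in range(n):
        q = kin.q[k]
        poses = model.segment_poses(q)
        knee_w = poses["femur"].apply(model.knee_axis_point) * _MM
        F = np.zeros(3)
        M = np.zeros(3)
        for b in bodies:
            m = kin.masses[b]
            F += m * (kin.a_com[b][k] - _GRAV)
            Iw = kin.world_inertia(b, k)
            M += (Iw @ kin.alpha[b][k]
                  + np.cross(kin.omega[b][k], Iw @ kin.omega[b][k])
                  + np.cross(kin.r_com[b][k] - knee_w,
                             kin.masses[b] * (kin.a_com[b][k] - _GRAV)))
        grf = trial.grf[k]
        if side == "tibia" and np.linalg.norm(grf) > 0:
            F -= grf
            M -= np.cross(trial.cop[k] * _MM - knee_w, grf)
        if side == "femur":
            F -= gen_forces.pelvis_residual_force[k]
        for i, musc in enumerate(model.muscles):
            tension = muscle_forces.values[k, i]
            if tension <= 0:
                continue
            for _seg, pt, fvec in _crossing_forces(model, poses, musc, tension):
                # on the femur side the crossing force acts with the
                # opposite sign (reaction on the proximal attachment)
                F -= sign * fvec
                M -= sign * np.cross(pt * _MM - knee_w, fvec)
        if include_ligaments:
            for pt, fvec in _ligament_forces(model, poses):
                F -= sign * fvec
                M -= sign * np.cross(pt * _MM - knee_w, fvec)
        F_joint[k] = sign * F
        # frontal-plane moment = component about the tibia's anterior axis
        anterior_w = poses["tibia"].rotation @ np.array([1.0, 0.0, 0.0])
        M_frontal[k] = M @ anterior_w
    magnitude_bw = np.linalg.norm(F_joint, axis=1) / bw
    record = ContactForceRecord(
        values=np.maximum(resample_percent_cycle(magnitude_bw, trial.heel_strikes), 0.0))
    return record, {"force": F_joint, "frontal_moment": M_frontal,
                    "magnitude_bw": magnitude_bw}


def decompose_compartments(axial_force, frontal_moment, lever_mm: float = 45.0,
                           clamp: bool = True) -> CompartmentForces:
    """Medial/lateral split of the axial knee load.

    Default lever-arm model: ``F_med = F/2 + M/d``, ``F_lat = F/2 - M/d``
    with the intercondylar half-distance ``d`` in the units of
    ``frontal_moment / axial_force``; a published regression can be
    emulated by transforming the inputs accordingly.  Negative
    compartment loads are clamped to zero with a warning.
    """
    import warnings as _w

    if lever_mm <= 0:
        raise ParameterError("lever arm must be positive")
    F = np.asarray(axial_force, dtype=float)
    M = np.asarray(frontal_moment, dtype=float)
    med = F / 2.0 + M / lever_mm
    lat = F / 2.0 - M / lever_mm
    if clamp and (np.any(med < 0) or np.any(lat < 0)):
        _w.warn("negative compartment force clamped to zero", stacklevel=2)
        med = np.maximum(med, 0.0)
        lat = np.maximum(lat, 0.0)
    return CompartmentForces(medial=med, lateral=lat)
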