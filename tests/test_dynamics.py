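"""Inverse dynamics, momentum replay, static optimization, knee loads."""

import numpy as np
import pytest

import tkabalance as tk
from tkabalance import InfeasibleFrameError, ParameterError
from tkabalance import dynamics as dyn
from conftest import make_static_trial


class TestInverseDynamics:
    def test_static_posture_knee_torque_matches_gravity_oracle(self, model, trial):
        """Standing with the knee flexed: the knee generalized force
        equals the gravitational moment of shank + foot about the hinge
        axis, hand-computed from the cross product."""
        static = make_static_trial(trial, knee_deg=30.0)
        tau = dyn.inverse_dynamics(model, static)
        k = static.n_frames // 2
        q = dyn.q_from_trial(static)[k]
        poses = model.segment_poses(q)
        axis_w = poses["femur"].rotation @ model.knee_axis_direction
        point_w = poses["femur"].apply(model.knee_axis_point) * 1e-3
        g = np.array([0.0, -9.81, 0.0])
        oracle = 0.0
        for b in ("tibia", "foot"):
            r = poses[b].apply(model.anatomy.segment_coms[b]) * 1e-3
            # flexion coordinate rotates the distal chain about -axis
            dr_dq = np.cross(-axis_w, r - point_w)
            oracle += -model.anatomy.segment_masses[b] * g @ dr_dq
        assert tau.values[k, 9] == pytest.approx(oracle, rel=1e-4, abs=1e-6)

    def test_zero_gravity_static_all_forces_vanish(self, model, trial,
                                                   monkeypatch):
        monkeypatch.setattr(dyn, "_GRAV", np.zeros(3))
        static = make_static_trial(trial, knee_deg=20.0)
        tau = dyn.inverse_dynamics(model, static)
        assert np.max(np.abs(tau.values)) < 1e-6

    @pytest.mark.parametrize("seed", [2, 3])
    def test_momentum_conservation_replay(self, model, anatomy, seed):
        """Forward replay of the solved forces through the whole-body
        momentum balance leaves a residual below 0.1% of the peak
        external load, for both forces and moments."""
        trial = tk.generate_gait_trial(seed=seed, anatomy=anatomy)
        tau = dyn.inverse_dynamics(model, trial)
        chk = dyn.verify_momentum(model, trial, tau)
        assert chk["force_rmse_percent"] < 0.1
        assert chk["moment_rmse_percent"] < 0.1

    def test_generalized_forces_validation(self, trial):
        with pytest.raises(ParameterError):
            dyn.GeneralizedForces(time=trial.time,
                                  values=np.zeros((3, 11)))


class TestInverseKinematics:
    def _markers_from(self, model, q_traj, noise=0.0, rng=None):
        names = [n for seg in ("pelvis", "femur", "tibia", "foot")
                 for n in model.anatomy.landmarks[seg]]
        out = {n: np.zeros((len(q_traj), 3)) for n in names}
        for k, q in enumerate(q_traj):
            w = dyn.forward_markers(model, q)
            for n in names:
                out[n][k] = w[n]
                if noise:
                    out[n][k] += rng.normal(0, noise, 3)
        return out

    def test_round_trip_recovery(self, model, trial):
        q_true = dyn.q_from_trial(trial)[::10]
        markers = self._markers_from(model, q_true)
        q_est = dyn.inverse_kinematics(markers, model, q0=q_true[0] + 0.5)
        assert np.max(np.abs(q_est[:, 6:] - q_true[:, 6:])) < 0.01      # deg
        assert np.max(np.abs(q_est[:, 0:3] - q_true[:, 0:3])) < 0.05    # mm

    def test_static_markers_give_constant_angles(self, model, trial):
        q0 = dyn.q_from_trial(make_static_trial(trial, knee_deg=25.0))[:5]
        markers = self._markers_from(model, q0)
        q_est = dyn.inverse_kinematics(markers, model, q0=q0[0] + 0.3)
        assert np.ptp(q_est, axis=0).max() < 1e-6

    def test_noisy_markers_residual_matches_noise(self, model, trial):
        rng = np.random.default_rng(0)
        q_true = dyn.q_from_trial(trial)[::20]
        markers = self._markers_from(model, q_true, noise=1.0, rng=rng)
        q_est = dyn.inverse_kinematics(markers, model, q0=q_true[0])
        res = []
        for k, q in enumerate(q_est):
            w = dyn.forward_markers(model, q)
            res.extend(np.linalg.norm(w[n] - markers[n][k]) for n in markers)
        rms = np.sqrt(np.mean(np.square(res)))
        assert 0.5 < rms / np.sqrt(3) < 2.0       # per-axis rms ~ 1 mm


class TestStaticOptimization:
    def test_single_muscle_closed_form(self):
        F, viol = dyn.solve_stress_qp(np.array([[0.05]]), np.array([12.0]),
                                      np.array([20.0]), np.array([5000.0]))
        assert F[0] == pytest.approx(12.0 / 0.05, rel=1e-9)
        assert np.linalg.norm(viol) < 1e-9

    def test_two_muscle_lagrangian_split(self):
        r, p1, p2, tau = 0.04, 30.0, 10.0, 20.0
        F, viol = dyn.solve_stress_qp(np.array([[r, r]]), np.array([tau]),
                                      np.array([p1, p2]),
                                      np.array([1e5, 1e5]))
        expect = tau / r * np.array([p1**2, p2**2]) / (p1**2 + p2**2)
        assert np.allclose(F, expect, rtol=1e-9)
        assert np.linalg.norm(viol) < 1e-9

    def test_matches_brute_force_grid_on_two_muscle_problem(self):
        """QP optimum agrees with a dense grid search on the feasible
        segment of a bounded 2-muscle problem."""
        R = np.array([[0.03, 0.05]])
        tau = np.array([15.0])
        pcsa = np.array([12.0, 25.0])
        fmax = np.array([400.0, 280.0])
        F, _ = dyn.solve_stress_qp(R, tau, pcsa, fmax)
        # grid over F1; F2 follows from the constraint
        f1 = np.linspace(0, fmax[0], 200001)
        f2 = (tau[0] - R[0, 0] * f1) / R[0, 1]
        ok = (f2 >= 0) & (f2 <= fmax[1])
        cost = (f1 / pcsa[0]) ** 2 + (f2 / pcsa[1]) ** 2
        cost[~ok] = np.inf
        best = np.argmin(cost)
        assert F[0] == pytest.approx(f1[best], abs=fmax[0] / 100000)
        obj = (F[0] / pcsa[0]) ** 2 + (F[1] / pcsa[1]) ** 2
        assert obj <= cost[best] + 1e-9

    def test_gait_frames_satisfy_constraints_and_kkt(self, model, trial,
                                                     solved_gait):
        tau, muscles = solved_gait
        assert np.all(muscles.values >= 0)
        fmax = np.array([m.fmax for m in model.muscles])
        assert np.all(muscles.values <= fmax + 1e-9)
        assert muscles.kkt_residuals.max() < 1e-6
        q = dyn.q_from_trial(trial)
        for k in range(0, trial.n_frames, 17):
            R = dyn.moment_arm_matrix(model, q[k])
            t = tau.values[k, list(dyn.ACTUATED)]
            assert (np.linalg.norm(R @ muscles.values[k] - t)
                    < 1e-6 * max(1.0, np.linalg.norm(t)))

    def test_impossible_demand_raises_named_error(self, model, trial):
        q = dyn.q_from_trial(trial)[0]
        bad = np.array([0.0, 0.0, 0.0, 1e5, 0.0])
        with pytest.raises(InfeasibleFrameError) as exc:
            dyn.static_optimization(bad, model, q)
        assert exc.value.coordinate == "knee_flexion"


class TestKneeContactForce:
    def test_static_no_muscles_reaction_is_distal_weight(self, model, trial):
        static = make_static_trial(trial, knee_deg=0.0)
        zero = dyn.MuscleForces(time=static.time,
                                values=np.zeros((static.n_frames,
                                                 len(model.muscles))),
                                names=tuple(m.name for m in model.muscles))
        record, per = dyn.knee_contact_force(model, static, zero,
                                             include_ligaments=False)
        masses = model.anatomy.segment_masses
        expect = (masses["tibia"] + masses["foot"]) * 9.81
        assert np.allclose(np.linalg.norm(per["force"], axis=1), expect,
                           rtol=1e-6)

    def test_doubling_muscle_forces_increases_stance_reaction(self, model,
                                                              trial,
                                                              solved_gait):
        _, muscles = solved_gait
        rec1, per1 = dyn.knee_contact_force(model, trial, muscles)
        import dataclasses
        doubled = dataclasses.replace(muscles, values=2.0 * muscles.values)
        rec2, per2 = dyn.knee_contact_force(model, trial, doubled)
        stance = ~trial.swing_mask
        assert np.all(per2["magnitude_bw"][stance]
                      > per1["magnitude_bw"][stance])

    def test_tibia_and_femur_side_balances_agree(self, model, trial,
                                                 solved_gait):
        tau, muscles = solved_gait
        rec_t, _ = dyn.knee_contact_force(model, trial, muscles)
        rec_f, _ = dyn.knee_contact_force(model, trial, muscles, side="femur",
                                          gen_forces=tau)
        assert np.max(np.abs(rec_t.values - rec_f.values)) \
            * model.anatomy.body_weight < 1e-6  # N


class TestCompartments:
    def test_zero_moment_splits_equally(self):
        c = dyn.decompose_compartments(2.0, 0.0)
        assert c.medial == c.lateral == pytest.approx(1.0)

    def test_lever_arm_closed_form(self):
        c = dyn.decompose_compartments(2.0, 45.0 * 0.5)
        assert c.medial == pytest.approx(1.5)
        assert c.lateral == pytest.approx(0.5)

    def test_conservation_without_clamping(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(1.0, 3.0, 50)
        M = rng.uniform(-20.0, 20.0, 50)
        c = dyn.decompose_compartments(F, M)
        assert np.allclose(c.medial + c.lateral, F, atol=1e-12)

    def test_negative_compartment_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            c = dyn.decompose_compartments(1.0, 100.0)
        assert c.lateral == 0.0

    def test_invalid_lever(self):
        with pytest.raises(ParameterError):
            dyn.decompose_compartments(1.0, 0.0, lever_mm=0.0)
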