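import dataclasses

import numpy as np
import pytest

import tkabalance as tk


@pytest.fixture(scope="session")
def anatomy():
    return tk.generate_anatomy(seed=1)


@pytest.fixture(scope="session")
def noiseless_anatomy():
    return tk.generate_anatomy(seed=1, noise=0.0)


@pytest.fixture(scope="session")
def model(anatomy):
    return tk.build_model(anatomy)


@pytest.fixture(scope="session")
def trials(anatomy):
    return [tk.generate_gait_trial(seed=s, anatomy=anatomy) for s in (2, 3)]


@pytest.fixture(scope="session")
def trial(trials):
    return trials[0]


@pytest.fixture(scope="session")
def neutral_postop(model, anatomy):
    params = tk.neutral_params(anatomy)
    cuts = tk.compute_cut_planes(params, model)
    return tk.place_components(cuts, params, model)


@pytest.fixture(scope="session")
def solved_gait(model, trial):
    """Inverse dynamics + static optimization for one trial (slow; shared)."""
    from tkabalance import dynamics as dyn

    tau = dyn.inverse_dynamics(model, trial)
    muscles = dyn.solve_muscle_forces(model, trial, tau)
    return tau, muscles


def make_static_trial(trial, knee_deg=30.0, with_grf=False):
    """Constant-pose variant of a gait trial (all coordinates frozen at
    a standing posture), optionally with zero ground reaction."""
    n = trial.n_frames
    pelvis = np.tile(trial.pelvis_pose[0] * 0, (n, 1))
    pelvis[:, 1] = trial.pelvis_pose[0, 1]
    grf = trial.grf if with_grf else np.zeros((n, 3))
    return dataclasses.replace(
        trial,
        pelvis_pose=pelvis,
        hip_angles=np.zeros((n, 3)),
        knee_flexion=np.full(n, float(knee_deg)),
        ankle_flexion=np.zeros(n),
        grf=grf,
        cop=np.zeros((n, 3)),
    )
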