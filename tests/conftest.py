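import numpy as np
import pytest

from diffent import synth, tracking


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_fbm_trajectories(k_alpha, alpha, n_traj, n_steps=100, dt=0.3, seed=0):
    """Batch of fBM trajectories as Trajectory objects."""
    spec = synth.TrajectorySpec(k_alpha=k_alpha, alpha=alpha, n_steps=n_steps,
                                dt_frame=dt, seed=seed)
    pos = synth.simulate_fbm_ensemble(spec, n_traj)
    t = np.arange(n_steps) * dt
    return [tracking.Trajectory(i, t, pos[i]) for i in range(n_traj)]
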