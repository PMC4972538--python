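import numpy as np
import pytest

import hippoblink as hb
from hippoblink.io import Session
from hippoblink.pipeline import analyze_session


@pytest.fixture(scope="session")
def arousal_session():
    """Full-scale arousal-model benchmark: 100 cells, 150 trials.

    Session-scoped because simulation plus the complete analysis takes on
    the order of a minute; several end-to-end tests share it.
    """
    cfg = hb.SessionConfig(duration=1500.0, n_cells=100, n_trials=150)
    s = hb.simulate_session(cfg, seed=7)
    sess = Session(s.trajectory, s.states, s.spikes, s.trials,
                   lfp=s.lfp, emg=s.emg, ground_truth=s.ground_truth)
    results = analyze_session(sess)
    return s, sess, results


@pytest.fixture(scope="session")
def cs_cell_session():
    """Control session of spatially flat units under the cs_cell model."""
    cfg = hb.SessionConfig(
        duration=1000.0, n_cells=20, n_trials=100, non_spatial_cells=True,
        model=hb.ResponseModel(kind="cs_cell", gain=4.0),
        include_lfp=False, include_emg=False,
    )
    s = hb.simulate_session(cfg, seed=11)
    sess = Session(s.trajectory, s.states, s.spikes, s.trials)
    results = analyze_session(sess)
    return s, sess, results


@pytest.fixture(scope="module")
def small_session():
    """A quick session with every modality, for pipeline-level tests."""
    cfg = hb.SessionConfig(duration=400.0, n_cells=6, n_trials=30)
    return hb.simulate_session(cfg, seed=3)


@pytest.fixture()
def track_sweep():
    """Constant-speed back-and-forth track traversals (uniform occupancy)."""

    def _make(speed=20.0, n_passes=30, sample_rate=25.0):
        env = hb.EnvironmentSpec()
        leg = env.track_length / speed
        t_total = n_passes * leg
        t = np.arange(0.0, t_total, 1.0 / sample_rate)
        # triangular wave between 0 and track_length
        phase = (t / leg) % 2.0
        x = np.where(phase < 1.0, phase, 2.0 - phase) * env.track_length
        traj = hb.Trajectory(t, x, np.zeros_like(x), env=env)
        return traj

    return _make
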