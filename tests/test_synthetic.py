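"""Generators: determinism, degenerate cases, and parameter recovery."""

import numpy as np
import pytest

import hippoblink as hb
from hippoblink.session import EnvironmentSpec, TrialTable
from hippoblink.synthetic import (
    PlaceCellSpec,
    ResponseModel,
    RippleParams,
    TrajectoryParams,
    expected_sit_fraction,
    simulate_emg,
    simulate_lfp,
    simulate_spikes,
    simulate_trajectory,
)

ENV = EnvironmentSpec()


class TestTrajectory:
    def test_determinism(self):
        a, sa = simulate_trajectory(ENV, 120.0, seed=5)
        b, sb = simulate_trajectory(ENV, 120.0, seed=5)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(sa, sb)

    def test_positions_confined(self):
        traj, _ = simulate_trajectory(ENV, 300.0, seed=0)
        assert traj.x.min() > ENV.x_min - 5 and traj.x.max() < ENV.x_max + 5

    def test_single_run_epoch_speeds(self):
        # vanishing sit dwell and a short session: essentially one traversal
        p = TrajectoryParams(mean_sit_duration=1e-4, run_speed_mean=30.0,
                             run_speed_sd=0.0)
        traj, states = simulate_trajectory(ENV, 5.0, p, seed=1)
        run = states == "run"
        interior = run.copy()
        interior[:10] = interior[-10:] = False  # skip smoothing edges
        assert run.mean() > 0.9
        assert np.all(traj.speed[interior] > 8.0)

    def test_sit_fraction_matches_renewal_theory(self):
        p = TrajectoryParams(mean_sit_duration=8.0, run_speed_sd=0.0)
        traj, states = simulate_trajectory(ENV, 4000.0, p, seed=2)
        expected = expected_sit_fraction(p, ENV)
        assert (states == "sit").mean() == pytest.approx(expected, abs=0.05)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_trajectory(ENV, -1.0)
        with pytest.raises(ValueError):
            TrajectoryParams(mean_sit_duration=0.0)


class TestSpikes:
    def _setup(self, duration=200.0, seed=0):
        traj, states = simulate_trajectory(ENV, duration, seed=seed)
        return traj, states

    def test_zero_rate_cell_is_silent(self):
        traj, states = self._setup()
        cell = PlaceCellSpec(peak_rate=0.0, baseline_rate=0.0,
                             ripple_participation_prob=0.0)
        trains, _ = simulate_spikes([cell], traj, states, None,
                                    ResponseModel(), seed=0)
        assert trains[0].n_spikes == 0

    def test_determinism(self):
        traj, states = self._setup()
        cell = PlaceCellSpec()
        a, _ = simulate_spikes([cell], traj, states, None, ResponseModel(), seed=9)
        b, _ = simulate_spikes([cell], traj, states, None, ResponseModel(), seed=9)
        assert np.array_equal(a[0].times, b[0].times)

    def test_trial_outside_span_rejected(self):
        traj, states = self._setup(duration=50.0)
        trials = TrialTable.from_onsets(np.array([200.0]))
        with pytest.raises(ValueError):
            simulate_spikes([PlaceCellSpec()], traj, states, trials,
                            ResponseModel(), seed=0)

    def test_arousal_run_trials_unmodulated(self):
        # trials during running: the arousal model adds nothing, so pooled
        # pre- and post-CS counts agree within Monte Carlo error
        p = TrajectoryParams(mean_sit_duration=1e-4, run_speed_sd=0.0,
                             run_speed_mean=30.0)
        traj, states = simulate_trajectory(ENV, 2500.0, p, seed=3)
        onsets = np.arange(10.0, 2490.0, 8.0)
        trials = TrialTable.from_onsets(onsets)
        cell = PlaceCellSpec(field_center=90.0, field_sigma=40.0,
                             peak_rate=6.0, direction="both")
        trains, _ = simulate_spikes([cell], traj, states, trials,
                                    ResponseModel(kind="arousal_place_cell"),
                                    seed=4)
        from hippoblink.cs_response import window_counts

        pre = window_counts(trains[0], trials, "pre_cs")
        post = window_counts(trains[0], trials, "post_cs")
        se = np.sqrt((pre.var() + post.var()) / len(trials))
        assert abs(post.mean() - pre.mean()) < 3 * se

    def test_arousal_sit_infield_recovery(self):
        # stationary animal inside the field: post-CS counts recover the
        # configured field rate over the aroused fraction of the window
        fs = 25.0
        duration = 3000.0
        t = np.arange(0, duration, 1 / fs)
        x = np.full_like(t, 90.0)
        traj = hb.Trajectory(t, x, np.zeros_like(t), env=ENV)
        states = np.full(len(t), "sit", dtype=object)
        onsets = np.arange(5.0, duration - 5.0, 10.0)  # 300 trials
        trials = TrialTable.from_onsets(onsets)
        model = ResponseModel(kind="arousal_place_cell", arousal_latency=0.05,
                              alert_duration=2.0)
        cell = PlaceCellSpec(field_center=90.0, field_sigma=10.0,
                             peak_rate=8.0, direction="both",
                             baseline_rate=0.0, ripple_participation_prob=0.0)
        trains, _ = simulate_spikes([cell], traj, states, trials, model, seed=5)
        from hippoblink.cs_response import window_counts

        pre = window_counts(trains[0], trials, "pre_cs")
        post = window_counts(trains[0], trials, "post_cs")
        assert post.mean() > pre.mean()
        # oracle from the specified rate trace: alert from cs+latency
        expected = cell.peak_rate * (0.5 - model.arousal_latency)
        se = np.sqrt(expected / len(trials))
        assert post.mean() == pytest.approx(expected, abs=3 * se)
        assert pre.mean() == pytest.approx(0.0, abs=1e-9)


class TestLFP:
    def _session(self, duration=200.0, seed=0, **kw):
        traj, states = simulate_trajectory(ENV, duration, seed=seed)
        return traj, states

    def test_fixed_8hz_phase_log(self):
        traj, states = self._session()
        lfp, _, log = simulate_lfp(traj, states, None,
                                   theta_params=hb.ThetaParams(frequency=8.0),
                                   seed=0)
        # ground-truth phase advances 2*pi every 125 ms
        fs = lfp.sample_rate
        ph = np.unwrap(log["phase"])
        step = int(0.125 * fs)
        adv = ph[step:] - ph[:-step]
        assert np.allclose(adv, 2 * np.pi, atol=1e-6)

    def test_zero_ripple_rate_empty_log(self):
        traj, states = self._session()
        _, events, _ = simulate_lfp(traj, states, None,
                                    ripple_params=RippleParams(rate=0.0), seed=0)
        assert events == []

    def test_out_of_band_ripple_frequency_rejected(self):
        with pytest.raises(ValueError):
            RippleParams(center_freq_low=60.0)
        with pytest.raises(ValueError):
            RippleParams(center_freq_high=300.0, center_freq_low=200.0)

    def test_requires_three_channels(self):
        traj, states = self._session()
        with pytest.raises(ValueError):
            simulate_lfp(traj, states, None, n_channels=2, seed=0)

    def test_determinism(self):
        traj, states = self._session(duration=60.0)
        a, ea, _ = simulate_lfp(traj, states, None, seed=8)
        b, eb, _ = simulate_lfp(traj, states, None, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert ea == eb

    def test_ripple_rate_recovery(self):
        # configured quiet ripple rate recovered by the detection module
        traj, states = self._session(duration=600.0, seed=4)
        lfp, events, _ = simulate_lfp(
            traj, states, None, ripple_params=RippleParams(rate=0.5), seed=4)
        from hippoblink.ripples import detect_ripples

        idx = np.clip(np.searchsorted(traj.times, lfp.times), 0, len(states) - 1)
        sit_mask = states[idx] == "sit"
        detected = detect_ripples(lfp, baseline_mask=sit_mask)
        sit_seconds = sit_mask.mean() * lfp.duration
        rate = len(detected) / sit_seconds
        se = np.sqrt(0.5 / sit_seconds)
        assert rate == pytest.approx(0.5, abs=3 * se)


class TestEMG:
    def test_determinism(self):
        trials = TrialTable.from_onsets(np.arange(2.0, 50.0, 2.0))
        a, la = simulate_emg(trials, 0.5, seed=3)
        b, lb = simulate_emg(trials, 0.5, seed=3)
        assert np.array_equal(a.samples, b.samples)
        assert la == lb

    def test_probability_validated(self):
        trials = TrialTable.from_onsets(np.arange(2.0, 50.0, 2.0))
        with pytest.raises(ValueError):
            simulate_emg(trials, 1.5, seed=0)

    def test_blink_log_matches_probability_extremes(self):
        trials = TrialTable.from_onsets(np.arange(2.0, 50.0, 2.0))
        _, log0 = simulate_emg(trials, 0.0, seed=0)
        _, log1 = simulate_emg(trials, 1.0, seed=0)
        assert not any(e["cr"] for e in log0)
        assert all(e["cr"] for e in log1)


def test_session_determinism():
    cfg = hb.SessionConfig(duration=120.0, n_cells=3, n_trials=10)
    a = hb.simulate_session(cfg, seed=21)
    b = hb.simulate_session(cfg, seed=21)
    assert np.array_equal(a.trajectory.x, b.trajectory.x)
    assert np.array_equal(a.lfp.samples, b.lfp.samples)
    assert np.array_equal(a.emg.samples, b.emg.samples)
    for sa, sb in zip(a.spikes, b.spikes):
        assert np.array_equal(sa.times, sb.times)
    assert np.array_equal(a.trials.cs_onsets, b.trials.cs_onsets)
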