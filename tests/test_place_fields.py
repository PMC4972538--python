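"""Rate-map construction, spatial classification, I_place, cell typing."""

import numpy as np
import pytest

from hippoblink.place_fields import (
    RateMap,
    RateMapParams,
    build_rate_map,
    classify_pyramidal,
    classify_spatial,
    place_field_intensity,
)
from hippoblink.session import EnvironmentSpec, SpikeTrain, Trajectory, TrialTable

ENV = EnvironmentSpec()
NOSMOOTH = RateMapParams(sigma_track=0.0, sigma_box=0.0)


def poisson_spikes(traj, rate_fn, seed=0, dt=0.001):
    """Inhomogeneous-Poisson spikes along a trajectory (test oracle)."""
    rng = np.random.default_rng(seed)
    t = np.arange(traj.start_time, traj.end_time, dt)
    x, _ = traj.position_at(t)
    r = rate_fn(x)
    counts = rng.poisson(r * dt)
    return SpikeTrain(np.repeat(t, counts) + rng.uniform(0, dt, counts.sum()))


def synthetic_map(track_values, box_value=0.0):
    """Hand-built RateMap with everything valid (for I_place arithmetic)."""
    n = len(track_values)
    track = {d: np.asarray(track_values, float) for d in ("rightward", "leftward")}
    valid = {d: np.ones(n, bool) for d in ("rightward", "leftward")}
    occ = {d: np.ones(n) for d in ("rightward", "leftward")}
    bs = 1.0
    spans = {
        "left_box": (np.arange(-ENV.endbox_length, bs / 2, bs),
                     np.arange(-8.0, 8.0 + bs / 2, bs)),
        "right_box": (np.arange(ENV.track_length, ENV.track_length + ENV.endbox_length + bs / 2, bs),
                      np.arange(-8.0, 8.0 + bs / 2, bs)),
    }
    boxes, bval, bocc = {}, {}, {}
    for b, (xe, ye) in spans.items():
        shape = (len(xe) - 1, len(ye) - 1)
        boxes[b] = np.full(shape, box_value)
        bval[b] = np.ones(shape, bool)
        bocc[b] = np.ones(shape)
    return RateMap(
        env=ENV, params=RateMapParams(), track_centers=np.arange(n) + 0.5,
        track=track, track_raw=track, track_counts={d: np.zeros(n) for d in track},
        track_occupancy=occ, track_valid=valid,
        boxes=boxes, boxes_raw=boxes,
        boxes_counts={b: np.zeros_like(boxes[b]) for b in boxes},
        boxes_occupancy=bocc, boxes_valid=bval,
        box_edges=spans,
    )


class TestBuildRateMap:
    def test_rate_is_counts_over_occupancy(self, track_sweep):
        traj = track_sweep(speed=20.0, n_passes=20)
        spikes = poisson_spikes(traj, lambda x: np.full_like(x, 3.0), seed=1)
        m = build_rate_map(spikes, traj, params=NOSMOOTH)
        for d in ("rightward", "leftward"):
            v = m.track_valid[d]
            occ = m.track_occupancy[d][v]
            # raw rate times occupancy recovers integer spike counts
            counts = m.track_raw[d][v] * occ
            assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_zero_spikes_zero_map(self, track_sweep):
        traj = track_sweep()
        m = build_rate_map(SpikeTrain(np.array([])), traj)
        for d in ("rightward", "leftward"):
            assert np.all(m.track[d][m.track_valid[d]] == 0)

    def test_homogeneous_rate_recovered(self, track_sweep):
        r = 5.0
        traj = track_sweep(speed=20.0, n_passes=40)
        spikes = poisson_spikes(traj, lambda x: np.full_like(x, r), seed=2)
        m = build_rate_map(spikes, traj, params=NOSMOOTH)
        occ = np.concatenate([m.track_occupancy[d][m.track_valid[d]]
                              for d in ("rightward", "leftward")])
        rate = np.concatenate([m.track_raw[d][m.track_valid[d]]
                               for d in ("rightward", "leftward")])
        mean = np.sum(rate * occ) / occ.sum()
        se = np.sqrt(r / occ.sum())
        assert mean == pytest.approx(r, abs=3 * se)

    def test_gaussian_field_recovery(self, track_sweep):
        c, sf, p = 90.0, 10.0, 8.0
        traj = track_sweep(speed=20.0, n_passes=60)
        spikes = poisson_spikes(
            traj, lambda x: p * np.exp(-0.5 * ((x - c) / sf) ** 2), seed=3)
        params = RateMapParams(sigma_track=3.0)
        m = build_rate_map(spikes, traj, params=params)
        rate = m.track["rightward"]
        centre = m.track_centers[np.argmax(rate)]
        assert abs(centre - c) <= params.bin_size
        # Gaussian convolved with the smoothing kernel widens predictably
        target_sigma = np.sqrt(sf**2 + params.sigma_track**2)
        half = rate > rate.max() / 2
        fwhm = half.sum() * params.bin_size
        assert fwhm / 2.355 == pytest.approx(target_sigma, rel=0.2)
        target_peak = p * sf / target_sigma
        assert rate.max() == pytest.approx(target_peak, rel=0.2)

    def test_spike_conservation_with_exclusions(self, track_sweep):
        traj = track_sweep(speed=20.0, n_passes=20)
        trials = TrialTable.from_onsets(np.arange(10.0, traj.end_time - 5, 9.0))
        spikes = poisson_spikes(traj, lambda x: np.full_like(x, 4.0), seed=4)
        m = build_rate_map(spikes, traj, trials, params=NOSMOOTH)
        # oracle: count spikes in moving, non-excluded epochs directly
        ok = traj.speed_at(spikes.times) > 2.0
        for cs in trials.cs_onsets:
            ok &= ~((spikes.times >= cs) & (spikes.times < cs + 2.0))
        on_track = ENV.region(*traj.position_at(spikes.times)[:1]) == "track"
        assert m.n_spikes_used == int((ok & on_track).sum())
        total_binned = sum(m.track_counts[d].sum() for d in m.track) + sum(
            m.boxes_counts[b].sum() for b in m.boxes)
        assert total_binned == m.n_spikes_used
        # raw rate × occupancy reproduces the counts on every valid bin
        for d in m.track:
            v = m.track_valid[d]
            assert np.allclose(m.track_raw[d][v] * m.track_occupancy[d][v],
                               m.track_counts[d][v], atol=1e-9)

    def test_directional_cell_silent_in_other_direction(self, track_sweep):
        traj = track_sweep(speed=20.0, n_passes=40)
        # cell fires only while heading rightward
        rng = np.random.default_rng(5)
        dt = 0.001
        t = np.arange(traj.start_time, traj.end_time, dt)
        x, _ = traj.position_at(t)
        d = traj.direction_at(t)
        r = np.where(d > 0, 8.0 * np.exp(-0.5 * ((x - 90) / 10) ** 2), 0.0)
        counts = rng.poisson(r * dt)
        spikes = SpikeTrain(np.repeat(t, counts))
        m = build_rate_map(spikes, traj, params=RateMapParams())
        assert m.track["rightward"].max() > 2.0
        assert m.track["leftward"][m.track_valid["leftward"]].max() < 0.5

    def test_empty_occupancy_warns_all_invalid(self):
        t = np.arange(0, 10, 0.04)
        traj = Trajectory(t, np.full_like(t, 90.0), np.zeros_like(t), env=ENV)
        with pytest.warns(UserWarning):
            m = build_rate_map(SpikeTrain(np.array([1.0])), traj)
        assert m.all_invalid

    def test_smoothing_preserves_uniform_mean(self, track_sweep):
        traj = track_sweep(speed=20.0, n_passes=40)
        spikes = poisson_spikes(traj, lambda x: np.full_like(x, 5.0), seed=6)
        raw = build_rate_map(spikes, traj, params=NOSMOOTH)
        sm = build_rate_map(spikes, traj, params=RateMapParams(sigma_track=3.0))
        d = "rightward"
        inner = slice(15, -15)  # away from edge effects of the kernel
        assert np.nanmean(sm.track[d][inner]) == pytest.approx(
            np.nanmean(raw.track_raw[d][inner]), rel=0.05)


class TestClassifySpatial:
    def test_zero_map_no_field(self):
        m = synthetic_map(np.zeros(180))
        assert classify_spatial(m).label == "no_field"

    def test_endbox_only(self):
        m = synthetic_map(np.zeros(180), box_value=0.0)
        m.boxes["right_box"][5:10, 5:10] = 5.0
        assert classify_spatial(m).label == "endbox_only"

    def test_track_and_endbox(self):
        m = synthetic_map(np.zeros(180))
        m.track["rightward"][50:60] = 6.0
        m.boxes["left_box"][3:8, 3:8] = 4.0
        sc = classify_spatial(m)
        assert sc.label == "track_and_endbox"
        assert sc.peak_rate == pytest.approx(6.0)

    def test_single_bin_blip_ignored(self):
        m = synthetic_map(np.zeros(180))
        m.track["rightward"][77] = 50.0
        assert classify_spatial(m).label == "no_field"

    def test_threshold_sensitivity(self):
        m = synthetic_map(np.zeros(180))
        m.track["rightward"][50:60] = 3.0
        assert classify_spatial(m, peak_thresh=2.0).label == "track_only"
        assert classify_spatial(m, peak_thresh=5.0).label == "no_field"


class TestPlaceFieldIntensity:
    def test_constant_map(self):
        m = synthetic_map(np.full(180, 4.2), box_value=4.2)
        t = np.arange(0, 20, 0.04)
        traj = Trajectory(t, 5.0 * t % 179, np.zeros_like(t), env=ENV)
        assert place_field_intensity(m, traj, 2.0, 4.0) == pytest.approx(4.2)

    def test_stationary_animal_reads_local_value(self):
        vals = np.zeros(180)
        vals[90] = 7.0
        m = synthetic_map(vals)
        t = np.arange(0, 20, 0.04)
        traj = Trajectory(t, np.full_like(t, 90.5), np.zeros_like(t), env=ENV)
        assert place_field_intensity(m, traj, 5.0, 6.0) == pytest.approx(7.0)

    def test_linear_ramp_full_traversal(self):
        # ramp 0 -> 10 Hz; constant-velocity traversal averages to 5 Hz
        m = synthetic_map(np.linspace(0, 10, 180))
        t = np.arange(0, 18.0, 0.04)
        traj = Trajectory(t, 10.0 * t, np.zeros_like(t), env=ENV)
        ip = place_field_intensity(m, traj, 0.0, 17.9)
        assert ip == pytest.approx(5.0, abs=0.2)

    def test_window_outside_trajectory_rejected(self):
        m = synthetic_map(np.zeros(180))
        t = np.arange(0, 10, 0.04)
        traj = Trajectory(t, t, np.zeros_like(t), env=ENV)
        with pytest.raises(ValueError):
            place_field_intensity(m, traj, 8.0, 12.0)


class TestClassifyPyramidal:
    @pytest.mark.parametrize(
        "rate,width,burst,expected",
        [
            (1.0, 0.30, 0.10, True),
            (12.0, 0.30, 0.10, False),   # interneuron-like rate
            (1.0, 0.20, 0.10, False),    # narrow spike
            (1.0, 0.30, 0.05, False),    # burst criterion is strict
            (3.999, 0.251, 0.051, True),
        ],
    )
    def test_criteria(self, rate, width, burst, expected):
        assert classify_pyramidal(rate, width, burst) is expected

    def test_missing_feature_undetermined(self):
        assert classify_pyramidal(None, 0.3, 0.1) is None
        assert classify_pyramidal(1.0, float("nan"), 0.1) is None
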