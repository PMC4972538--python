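"""Synthetic session generator with known ground truth.

Implements the generative account the analyses are designed to test —
place cells whose firing is gated by behavioural state and arousal — plus
the two alternative response models it is compared against:

* ``cs_cell`` — a unit that adds a space-invariant rate bump after the tone
  (CS), regardless of location or state.
* ``cs_place_cell`` — a conjunctive unit whose CS bump is scaled by the
  place-field intensity at the animal's current location, regardless of
  state.
* ``arousal_place_cell`` — a pure place cell.  While the animal runs (or is
  otherwise alert) it fires according to its place field; while the animal
  sits quietly, place-specific firing stops and the cell instead spikes in
  ripple-associated bursts.  The CS triggers arousal: after a short latency
  the cell resumes place-specific firing and ripples cease.  The CS adds no
  modulation beyond this state switch, so trials delivered during running
  produce no rate change at all.

Every generated spike, ripple and blink traces back to a ground-truth cause
recorded in :class:`SessionGroundTruth`, and identical seeds reproduce
sessions bitwise.

Behaviour is an alternating renewal process: exponential sit dwells in the
endboxes alternating with track traversals at a sampled constant speed.
The LFP is additive — theta sinusoid with drifting frequency while running,
1/f background, and Gaussian-envelope ripple wavelets while sitting — with
no biophysical pretensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .session import (
    CS_DURATION,
    US_DELAY,
    US_DURATION,
    EnvironmentSpec,
    SpikeTrain,
    Trajectory,
    TrialTable,
)
from .timeseries import TimeSeries

__all__ = [
    "TrajectoryParams",
    "PlaceCellSpec",
    "ResponseModel",
    "RippleParams",
    "ThetaParams",
    "SessionConfig",
    "SessionGroundTruth",
    "SyntheticSession",
    "simulate_trajectory",
    "simulate_spikes",
    "simulate_lfp",
    "simulate_theta_probe",
    "simulate_emg",
    "simulate_session",
    "expected_sit_fraction",
    "random_cells",
    "flat_cells",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class TrajectoryParams:
    """Alternating renewal process: exponential sit dwells / track runs."""

    mean_sit_duration: float = 8.0     # s, exponential
    run_speed_mean: float = 35.0       # cm/s
    run_speed_sd: float = 5.0          # 0 → deterministic speed
    min_run_speed: float = 10.0
    sample_rate: float = 25.0          # Hz
    sit_jitter: float = 0.5            # cm (SD) positional drift while sitting

    def __post_init__(self) -> None:
        if self.mean_sit_duration <= 0 or self.run_speed_mean <= 0:
            raise ValueError("dwell parameters must be strictly positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be strictly positive")


@dataclass
class PlaceCellSpec:
    """Ground-truth spatial tuning of one unit.

    The field is a Gaussian bump along the track axis; ``direction``
    restricts it to one direction of traversal while on the track
    ('rightward', 'leftward') or applies in both ('both').  Out-of-field
    quiet-state firing is concentrated in ripple windows, each joined with
    probability ``ripple_participation_prob``.
    """

    field_center: float = 90.0        # cm, apparatus x coordinate
    field_sigma: float = 10.0         # cm
    peak_rate: float = 8.0            # Hz
    direction: str = "both"
    baseline_rate: float = 0.05       # Hz while alert, anywhere
    ripple_participation_prob: float = 0.3
    burst_rate: float = 120.0         # Hz inside a joined ripple window

    def __post_init__(self) -> None:
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if self.field_sigma <= 0:
            raise ValueError("field_sigma must be positive")
        if not 0 <= self.ripple_participation_prob <= 1:
            raise ValueError("ripple_participation_prob must be in [0, 1]")
        if self.direction not in ("rightward", "leftward", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def rate_at(self, x: np.ndarray, direction: np.ndarray | None = None,
                on_track: np.ndarray | None = None) -> np.ndarray:
        """Place-field rate at apparatus position x (direction-gated on track)."""
        x = np.asarray(x, dtype=float)
        r = self.peak_rate * np.exp(-0.5 * ((x - self.field_center) / self.field_sigma) ** 2)
        if direction is not None and self.direction != "both":
            want = 1.0 if self.direction == "rightward" else -1.0
            gate = (np.asarray(direction) == want)
            if on_track is not None:
                # fields are non-directional inside the endboxes
                gate = gate | ~np.asarray(on_track, bool)
            r = np.where(gate, r, 0.0)
        return r


@dataclass
class ResponseModel:
    """Which CS-response mechanism generates the spikes.

    kind='arousal_place_cell' uses ``arousal_latency`` (s after CS onset at
    which quiet → alert) and ``alert_duration`` (s the arousal persists).
    kind='cs_cell' adds ``gain`` Hz for ``response_duration`` s after
    ``latency``; 'cs_place_cell' scales that bump by the normalised field
    intensity at the animal's location.
    """

    kind: str = "arousal_place_cell"
    gain: float = 5.0                # Hz, cs_cell / cs_place_cell bump
    latency: float = 0.05            # s, response latency for additive bumps
    response_duration: float = 0.45  # s
    arousal_latency: float = 0.05    # s, quiet → alert transition after CS
    alert_duration: float = 2.0      # s of arousal following the CS

    def __post_init__(self) -> None:
        if self.kind not in ("cs_cell", "cs_place_cell", "arousal_place_cell"):
            raise ValueError(f"unknown response model kind {self.kind!r}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")


@dataclass
class RippleParams:
    rate: float = 0.4                 # events/s during quiet sitting
    center_freq_low: float = 140.0    # Hz
    center_freq_high: float = 220.0
    duration_low: float = 0.04        # s
    duration_high: float = 0.08
    amplitude: float = 60.0           # µV
    channel_fraction: float = 1.0     # fraction of channels carrying each event

    def __post_init__(self) -> None:
        if not (80.0 <= self.center_freq_low <= self.center_freq_high <= 250.0):
            raise ValueError("ripple center frequencies must lie within [80, 250] Hz")
        if self.rate < 0:
            raise ValueError("ripple rate must be >= 0")


@dataclass
class ThetaParams:
    frequency: float = 8.0        # Hz, centre
    freq_jitter_sd: float = 0.0   # Hz, random-walk innovation per sample
    amplitude: float = 100.0      # µV while running
    sit_amplitude: float = 5.0    # residual theta while sitting


@dataclass
class SessionGroundTruth:
    """Everything needed to score a recovery: the causes of every event."""

    seed: int
    cells: list = field(default_factory=list)            # PlaceCellSpec dicts
    model: dict = field(default_factory=dict)
    state_epochs: list = field(default_factory=list)     # (label, t0, t1)
    trial_states: list = field(default_factory=list)     # state at delivery
    ripple_events: list = field(default_factory=list)    # dicts: time, duration, freq
    ripple_membership: list = field(default_factory=list)  # per cell: joined ripple idx
    theta: dict = field(default_factory=dict)
    blink_log: list = field(default_factory=list)        # dicts: trial, cr, ur

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# trajectory


def expected_sit_fraction(params: TrajectoryParams,
                          env: EnvironmentSpec | None = None) -> float:
    """Stationary sitting fraction of the alternating renewal process.

    E[sit] / (E[sit] + E[run]); the run dwell is traversal distance divided
    by speed, with E[1/v] evaluated numerically for stochastic speeds.
    """
    env = env or EnvironmentSpec()
    distance = env.track_length + env.endbox_length  # port to port
    if params.run_speed_sd == 0:
        e_run = distance / params.run_speed_mean
    else:
        v = np.linspace(params.min_run_speed,
                        params.run_speed_mean + 6 * params.run_speed_sd, 4001)
        pdf = np.exp(-0.5 * ((v - params.run_speed_mean) / params.run_speed_sd) ** 2)
        pdf /= np.trapezoid(pdf, v)
        e_run = distance * np.trapezoid(pdf / v, v)
    return params.mean_sit_duration / (params.mean_sit_duration + e_run)


def simulate_trajectory(
    env: EnvironmentSpec,
    duration: float,
    params: TrajectoryParams | None = None,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Alternating run/sit trajectory on the track.

    Returns the trajectory and a per-sample state label array ('run'/'sit').
    The animal sits at an endbox reward port (x at the box centre) with
    small positional jitter, then traverses to the opposite port at a speed
    drawn once per traversal.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = params or TrajectoryParams()
    rng = np.random.default_rng(seed)

    left_port = -env.endbox_length / 2.0
    right_port = env.track_length + env.endbox_length / 2.0
    dt = 1.0 / params.sample_rate
    n = int(round(duration * params.sample_rate))
    times = np.arange(n) * dt

    xs = np.empty(n)
    states = np.empty(n, dtype=object)
    at_left = bool(rng.integers(2))
    t_cursor = 0
    while t_cursor < n:
        # sit at the current port
        sit_n = max(int(round(rng.exponential(params.mean_sit_duration) / dt)), 1)
        sit_n = min(sit_n, n - t_cursor)
        port = left_port if at_left else right_port
        xs[t_cursor : t_cursor + sit_n] = port
        states[t_cursor : t_cursor + sit_n] = "sit"
        t_cursor += sit_n
        if t_cursor >= n:
            break
        # traverse to the opposite port
        v = params.run_speed_mean
        if params.run_speed_sd > 0:
            v = max(rng.normal(params.run_speed_mean, params.run_speed_sd),
                    params.min_run_speed)
        run_n = max(int(round((right_port - left_port) / v / dt)), 2)
        run_n = min(run_n, n - t_cursor)
        target = right_port if at_left else left_port
        start = left_port if at_left else right_port
        xs[t_cursor : t_cursor + run_n] = np.linspace(start, target, run_n)
        states[t_cursor : t_cursor + run_n] = "run"
        t_cursor += run_n
        at_left = not at_left

    # positional jitter while sitting: slow drift (≈0.5 s correlation time)
    # so sitting speeds stay well below the 2 cm/s moving criterion
    def _drift() -> np.ndarray:
        from scipy.ndimage import gaussian_filter1d

        raw = gaussian_filter1d(rng.normal(0, 1, n), 0.5 * params.sample_rate)
        sd = max(np.std(raw), 1e-12)
        return params.sit_jitter * raw / sd

    xs = xs + np.where(states == "sit", _drift(), 0.0)
    ys = np.where(states == "sit", _drift(), 0.0)
    traj = Trajectory(times, xs, ys, env=env)
    return traj, states


def state_epochs(times: np.ndarray, states: np.ndarray) -> list:
    """Collapse a per-sample state log to (label, t0, t1) epochs."""
    edges = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate([[0], edges, [len(states)]])
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    return [
        (str(states[a]), float(times[a]), float(times[b - 1]) + dt)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# spikes


def _alert_mask(t: np.ndarray, run_mask: np.ndarray, trials: TrialTable | None,
                model: ResponseModel) -> np.ndarray:
    """True where place-specific firing is active (running, or CS-aroused).

    A pure CS cell is, by hypothesis, not a place cell at all: its baseline
    firing is state-independent, so under the cs_cell model the mask is
    always True and spiking reduces to homogeneous Poisson plus the CS bump.
    """
    if model.kind == "cs_cell":
        return np.ones_like(run_mask, dtype=bool)
    alert = run_mask.copy()
    if trials is not None and model.kind == "arousal_place_cell":
        for cs in trials.cs_onsets:
            w = (t >= cs + model.arousal_latency) & (t < cs + model.alert_duration)
            alert |= w
    return alert


def simulate_spikes(
    cells: list,
    traj: Trajectory,
    states: np.ndarray,
    trials: TrialTable | None,
    model: ResponseModel,
    seed: int = 0,
    ripple_events: list | None = None,
    dt: float = 0.001,
) -> tuple[list, list]:
    """Inhomogeneous-Poisson spike trains given ground-truth rate traces.

    Returns ``(spike_trains, ripple_membership)`` where membership lists,
    per cell, the indices of the ripple events it joined with a burst.

    The rate trace per cell: while alert (running, or within the arousal
    window after a CS under the arousal model) the cell fires at its
    place-field rate at the current position plus its baseline; while quiet
    it is silent except for bursts inside joined ripple windows.  The
    ``cs_cell`` and ``cs_place_cell`` models add their rate bump on top,
    independent of state.
    """
    if trials is not None and len(trials):
        if not traj.covers(trials.cs_onsets.min() - 1.0, trials.us_offsets.max() + 1.0):
            raise ValueError("trial windows extend outside the trajectory span")
    rng = np.random.default_rng(seed)
    ripple_events = ripple_events or []

    t = np.arange(traj.start_time, traj.end_time, dt)
    x, _ = traj.position_at(t)
    direction = traj.direction_at(t)
    on_track = traj.env.region(x) == "track"
    idx = np.clip(np.searchsorted(traj.times, t), 0, len(states) - 1)
    run_mask = states[idx] == "run"
    alert = _alert_mask(t, run_mask, trials, model)

    bump = np.zeros_like(t)
    if trials is not None and model.kind in ("cs_cell", "cs_place_cell"):
        for cs in trials.cs_onsets:
            w = (t >= cs + model.latency) & (t < cs + model.latency + model.response_duration)
            bump[w] = 1.0

    ripple_windows = [
        (ev["time"] - ev["duration"] / 2, ev["time"] + ev["duration"] / 2)
        for ev in ripple_events
    ]

    trains: list[SpikeTrain] = []
    membership: list[list[int]] = []
    duration = traj.end_time - traj.start_time
    for uid, cell in enumerate(cells):
        rate = np.where(alert, cell.rate_at(x, direction, on_track) + cell.baseline_rate, 0.0)
        if model.kind == "cs_cell":
            rate = rate + model.gain * bump
        elif model.kind == "cs_place_cell":
            norm = cell.rate_at(x, direction, on_track) / max(cell.peak_rate, 1e-12)
            rate = rate + model.gain * bump * norm
        joined = []
        if cell.ripple_participation_prob > 0 and ripple_windows:
            take = rng.random(len(ripple_windows)) < cell.ripple_participation_prob
            for k, (w0, w1) in enumerate(ripple_windows):
                if take[k]:
                    joined.append(k)
                    rate[(t >= w0) & (t < w1) & ~alert] += cell.burst_rate
        counts = rng.poisson(rate * dt)
        spike_times = np.repeat(t, counts) + rng.uniform(0, dt, int(counts.sum()))
        feats = SpikeTrain.summary_features(spike_times, duration)
        trains.append(
            SpikeTrain(spike_times, unit_id=uid, mean_rate=feats["mean_rate"],
                       spike_width=0.35, burst_fraction=feats["burst_fraction"])
        )
        membership.append(joined)
    return trains, membership


# ---------------------------------------------------------------------------
# LFP


def _pink_noise(rng: np.random.Generator, n: int, fs: float, scale: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.normal(0, 1, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n)
    return scale * out / max(np.std(out), 1e-12)


def simulate_lfp(
    traj: Trajectory,
    states: np.ndarray,
    trials: TrialTable | None,
    ripple_params: RippleParams | None = None,
    theta_params: ThetaParams | None = None,
    seed: int = 0,
    n_channels: int = 4,
    sample_rate: float = 1000.0,
    model: ResponseModel | None = None,
    us_artifact_amplitude: float = 0.0,
    noise_amplitude: float = 15.0,
) -> tuple[TimeSeries, list, dict]:
    """Additive multi-channel LFP with ground-truth event logs.

    Running epochs carry theta (4–12 Hz, configurable drift); sitting epochs
    carry large irregular activity plus ripple wavelets synchronised across
    a channel subset.  Under the arousal model ripples cease inside the
    post-CS arousal window.  Returns ``(lfp, ripple_events, theta_log)``
    where the theta log holds the ground-truth phase trace.
    """
    if n_channels < 3:
        raise ValueError("need at least 3 channels for the multi-tetrode "
                         "ripple criterion")
    ripple_params = ripple_params or RippleParams()
    theta_params = theta_params or ThetaParams()
    model = model or ResponseModel()
    rng = np.random.default_rng(seed)

    t0, t1 = traj.start_time, traj.end_time
    n = int(round((t1 - t0) * sample_rate))
    t = t0 + np.arange(n) / sample_rate

    idx = np.clip(np.searchsorted(traj.times, t), 0, len(states) - 1)
    run_mask = states[idx] == "run"
    alert = _alert_mask(t, run_mask, trials, model) if trials is not None else run_mask

    # theta: phase integrates a drifting frequency; amplitude gated by state
    freq = np.full(n, theta_params.frequency)
    if theta_params.freq_jitter_sd > 0:
        walk = np.cumsum(rng.normal(0, theta_params.freq_jitter_sd, n))
        freq = np.clip(freq + walk, 4.0, 12.0)
    phase = 2 * np.pi * np.cumsum(freq) / sample_rate
    amp = np.where(run_mask, theta_params.amplitude, theta_params.sit_amplitude)
    theta_wave = amp * np.cos(phase)

    # ripples: Poisson in quiet (non-alert sit) time, suppressed by arousal
    quiet = ~alert
    ripple_events: list[dict] = []
    quiet_times = t[quiet]
    if ripple_params.rate > 0 and quiet_times.size:
        total_quiet = quiet_times.size / sample_rate
        n_events = rng.poisson(ripple_params.rate * total_quiet)
        if n_events:
            picks = np.sort(rng.choice(quiet_times, size=n_events, replace=False))
            n_on = max(int(round(ripple_params.channel_fraction * n_channels)), 1)
            last_end = -np.inf
            for pt in picks:
                dur = rng.uniform(ripple_params.duration_low, ripple_params.duration_high)
                if pt - dur / 2 <= last_end:  # keep events disjoint
                    continue
                fr = rng.uniform(ripple_params.center_freq_low, ripple_params.center_freq_high)
                chans = sorted(rng.choice(n_channels, size=n_on, replace=False).tolist())
                ripple_events.append(
                    {"time": float(pt), "duration": float(dur),
                     "frequency": float(fr), "channels": chans}
                )
                last_end = pt + dur / 2

    samples = np.empty((n_channels, n))
    for c in range(n_channels):
        lia = _pink_noise(rng, n, sample_rate, noise_amplitude)
        samples[c] = theta_wave + lia
    for ev in ripple_events:
        w = np.exp(-0.5 * ((t - ev["time"]) / (ev["duration"] / 4)) ** 2)
        wave = ripple_params.amplitude * w * np.cos(2 * np.pi * ev["frequency"] * (t - ev["time"]))
        mask = np.abs(t - ev["time"]) < ev["duration"]
        for c in ev["channels"]:
            samples[c, mask] += wave[mask]
    if us_artifact_amplitude > 0 and trials is not None:
        for us in trials.us_onsets:
            m = (t >= us) & (t < us + 0.05)
            samples[:, m] += us_artifact_amplitude * np.exp(
                -(t[m] - us) / 0.01
            )

    theta_log = {"frequency": theta_params.frequency, "phase0": 0.0,
                 "times": t, "phase": np.mod(phase + np.pi, 2 * np.pi) - np.pi}
    return TimeSeries(samples, sample_rate, t0), ripple_events, theta_log


def simulate_theta_probe(
    trials: TrialTable,
    duration: float,
    perturbation: str = "none",
    delta: float = 0.0,
    reset_phase: float = 0.0,
    frequency: float = 8.0,
    amplitude: float = 100.0,
    noise_amplitude: float = 5.0,
    sample_rate: float = 1000.0,
    seed: int = 0,
    phase_jitter_sd: float = 0.0,
) -> tuple[TimeSeries, np.ndarray]:
    """Single-channel theta benchmark with a controlled stimulus perturbation.

    perturbation='none'   — unbroken oscillation through every CS.
    perturbation='reset'  — phase jumps to ``reset_phase`` at each CS onset.
    perturbation='shift'  — phase advances by a constant ``delta`` at each CS.

    Each trial's pre-CS starting phase is randomised, so across trials the
    pre-stimulus phase is uniform.  Returns the trace and the ground-truth
    wrapped phase at each sample.
    """
    if perturbation not in ("none", "reset", "shift"):
        raise ValueError(f"unknown perturbation {perturbation!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    phase = 2 * np.pi * frequency * t + rng.uniform(0, 2 * np.pi)

    boundaries = np.concatenate([[0.0], trials.cs_onsets, [duration]])
    # randomise phase at a point well before each CS so pre-phase is uniform
    for cs in trials.cs_onsets:
        seg_start = cs - 2.0
        m = t >= seg_start
        phase[m] += rng.uniform(0, 2 * np.pi)
    for cs in trials.cs_onsets:
        m = t >= cs
        if perturbation == "reset":
            i = np.searchsorted(t, cs)
            if i < n:
                phase[m] += (reset_phase - phase[i])
        elif perturbation == "shift":
            phase[m] += delta
    if phase_jitter_sd > 0:
        phase += np.cumsum(rng.normal(0, phase_jitter_sd / np.sqrt(sample_rate), n))
    x = amplitude * np.cos(phase) + rng.normal(0, noise_amplitude, n)
    wrapped = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    return TimeSeries(x, sample_rate, 0.0), wrapped


# ---------------------------------------------------------------------------
# EMG


def simulate_emg(
    trials: TrialTable,
    cr_probability: float | np.ndarray = 0.5,
    seed: int = 0,
    duration: float | None = None,
    sample_rate: float = 2000.0,
    baseline_amplitude: float = 5.0,
    ur_gain: float = 12.0,
    cr_gain: float = 8.0,
) -> tuple[TimeSeries, list]:
    """Differential eyelid EMG with unconditioned and conditioned blinks.

    Baseline is broadband noise.  Every trial carries an unconditioned
    blink burst after the US; a Bernoulli(``cr_probability``) subset carries
    a conditioned-response burst in the 100 ms window ending 20 ms before
    the US onset (the anticipatory window the CR detector scores).  Bursts
    are amplitude-modulated broadband noise, so their energy overlaps the
    120–960 Hz detection band.  Returns the trace and a ground-truth blink
    log (one dict per trial: ``cr`` and ``ur`` booleans).
    """
    p = np.broadcast_to(np.asarray(cr_probability, dtype=float), (len(trials),))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("cr_probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = float(trials.us_offsets.max() + 2.0)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = rng.normal(0, baseline_amplitude, n)

    blink_log = []
    gain = np.ones(n)
    for i, cs in enumerate(trials.cs_onsets):
        us_off = cs + US_DELAY + US_DURATION
        gain[(t >= us_off) & (t < us_off + 0.15)] = ur_gain
        cr = bool(rng.random() < p[i])
        if cr:
            gain[(t >= cs + 0.38) & (t < cs + 0.48)] = cr_gain
        blink_log.append({"trial": i, "cr": cr, "ur": True})
    x = x * gain
    return TimeSeries(x, sample_rate, 0.0), blink_log


# ---------------------------------------------------------------------------
# full sessions


def random_cells(
    n_cells: int,
    env: EnvironmentSpec,
    seed: int = 0,
    peak_rate_range: tuple = (4.0, 12.0),
    sigma_range: tuple = (8.0, 14.0),
    participation_range: tuple = (0.15, 0.45),
) -> list:
    """A population of place cells with field centres spanning the apparatus."""
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        centre = rng.uniform(env.x_min + 5, env.x_max - 5)
        direction = rng.choice(["rightward", "leftward", "both"])
        cells.append(
            PlaceCellSpec(
                field_center=float(centre),
                field_sigma=float(rng.uniform(*sigma_range)),
                peak_rate=float(rng.uniform(*peak_rate_range)),
                direction=str(direction),
                ripple_participation_prob=float(rng.uniform(*participation_range)),
            )
        )
    return cells


def flat_cells(n_cells: int, rate: float = 2.0) -> list:
    """Spatially flat units (the pure-CS-cell premise): an effectively
    infinite field width makes the rate uniform over the apparatus."""
    return [
        PlaceCellSpec(field_center=90.0, field_sigma=1e6, peak_rate=rate,
                      direction="both", baseline_rate=0.0,
                      ripple_participation_prob=0.0)
        for _ in range(n_cells)
    ]


@dataclass
class SessionConfig:
    """Knobs for a full synthetic session; defaults are the study conditions."""

    duration: float = 600.0
    n_cells: int = 20
    non_spatial_cells: bool = False   # flat units for the cs_cell benchmark
    flat_rate: float = 2.0            # Hz, rate of flat units
    n_trials: int = 60
    min_trial_gap: float = 8.0
    model: ResponseModel = field(default_factory=ResponseModel)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    ripples: RippleParams = field(default_factory=RippleParams)
    theta: ThetaParams = field(default_factory=ThetaParams)
    env: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    n_lfp_channels: int = 4
    lfp_sample_rate: float = 1000.0
    emg_sample_rate: float = 2000.0
    cr_probability: float = 0.6
    include_lfp: bool = True
    include_emg: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        for key, sub in [("model", ResponseModel), ("trajectory", TrajectoryParams),
                         ("ripples", RippleParams), ("theta", ThetaParams),
                         ("env", EnvironmentSpec)]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass
class SyntheticSession:
    """A complete generated session plus its ground truth."""

    trajectory: Trajectory
    states: np.ndarray
    spikes: list
    trials: TrialTable
    lfp: TimeSeries | None
    emg: TimeSeries | None
    ground_truth: SessionGroundTruth
    config: SessionConfig


def _place_trials(rng: np.random.Generator, config: SessionConfig,
                  traj: Trajectory) -> TrialTable:
    """CS onsets at random times with a minimum gap, anywhere in the session.

    Uses the slack construction (sorted uniforms plus fixed gaps), which
    yields exactly ``n_trials`` onsets whenever the session is long enough.
    """
    lo = traj.start_time + 2.0
    hi = traj.end_time - 3.0
    n = config.n_trials
    slack = (hi - lo) - (n - 1) * config.min_trial_gap
    if slack <= 0:
        raise ValueError(
            f"session too short for {n} trials with a "
            f"{config.min_trial_gap} s minimum gap"
        )
    u = np.sort(rng.uniform(0, slack, n))
    onsets = lo + u + config.min_trial_gap * np.arange(n)
    x, y = traj.position_at(onsets)
    return TrialTable.from_onsets(onsets, x=x, y=y)


def simulate_session(config: SessionConfig | None = None, seed: int = 0) -> SyntheticSession:
    """Generate a full session under the configured response model."""
    config = config or SessionConfig()
    root = np.random.default_rng(seed)
    seeds = {k: int(root.integers(2**31))
             for k in ("traj", "cells", "trials", "lfp", "spikes", "emg")}

    traj, states = simulate_trajectory(
        config.env, config.duration, config.trajectory, seed=seeds["traj"]
    )
    if config.non_spatial_cells:
        cells = flat_cells(config.n_cells, config.flat_rate)
    else:
        cells = random_cells(config.n_cells, config.env, seed=seeds["cells"])
    trial_rng = np.random.default_rng(seeds["trials"])
    trials = _place_trials(trial_rng, config, traj)

    lfp, ripple_events, theta_log = (None, [], {})
    if config.include_lfp:
        lfp, ripple_events, theta_log = simulate_lfp(
            traj, states, trials, config.ripples, config.theta,
            seed=seeds["lfp"], n_channels=config.n_lfp_channels,
            sample_rate=config.lfp_sample_rate, model=config.model,
        )
    spikes, membership = simulate_spikes(
        cells, traj, states, trials, config.model,
        seed=seeds["spikes"], ripple_events=ripple_events,
    )
    emg, blink_log = (None, [])
    if config.include_emg:
        emg, blink_log = simulate_emg(
            trials, config.cr_probability, seed=seeds["emg"],
            duration=config.duration, sample_rate=config.emg_sample_rate,
        )

    # ground-truth state at delivery: the state at the sample covering CS onset
    idx = np.clip(np.searchsorted(traj.times, trials.cs_onsets), 0, len(states) - 1)
    trial_states = [str(s) for s in states[idx]]
    trials = trials.with_column("true_state", trial_states)

    gt = SessionGroundTruth(
        seed=seed,
        cells=[asdict(c) for c in cells],
        model=asdict(config.model),
        state_epochs=state_epochs(traj.times, states),
        trial_states=trial_states,
        ripple_events=ripple_events,
        ripple_membership=membership,
        theta={k: v for k, v in theta_log.items() if k in ("frequency", "phase0")},
        blink_log=blink_log,
    )
    return SyntheticSession(traj, states, spikes, trials, lfp, emg, gt, config)
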