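"""Ripple detection on multi-channel LFP and peri-stimulus ripple rates.

Ripples are brief 120–250 Hz oscillations of quiet wakefulness.  Detection
follows the classic recipe: band-pass each channel to 80–250 Hz, compute a
sliding RMS envelope, and mark candidate peaks above a per-channel
threshold (mean + k·SD of the envelope).  Each candidate's centre frequency
is measured with a short STFT frame centred on the event, and a candidate
survives only if that frequency lies within 120–250 Hz and the event is
seen on at least ``min_channels`` channels within a coincidence window.
Overlapping multi-channel detections are merged and the longest-duration
event in each cluster is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import TrialTable
from .signal_core import bandpass, stft_frames
from .timeseries import TimeSeries

__all__ = ["RippleDetectionParams", "RippleEvent", "detect_ripples",
           "ripple_rate", "split_trials_by_ripple"]


@dataclass
class RippleDetectionParams:
    band: tuple = (80.0, 250.0)         # Hz, detection band-pass
    freq_range: tuple = (120.0, 250.0)  # Hz, accepted centre frequency
    rms_window: float = 0.010           # s, sliding-RMS window
    threshold_sd: float = 5.0           # peak criterion: mean + k·SD
    edge_sd: float = 2.0                # event extent: envelope above mean + k·SD
    min_channels: int = 3
    coincidence: float = 0.015          # s, cross-channel peak matching
    min_duration: float = 0.020         # s
    max_duration: float = 0.200
    stft_window: float = 0.100          # s, frame for frequency estimation


@dataclass
class RippleEvent:
    time: float          # s, envelope peak
    duration: float      # s
    frequency: float     # Hz, STFT centre frequency
    n_channels: int      # channels supporting the detection
    amplitude: float     # peak envelope, µV
    channels: list = field(default_factory=list)


def _sliding_rms(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n) / n
    return np.sqrt(np.convolve(x**2, kernel, mode="same"))


def _channel_candidates(ch: TimeSeries, params: RippleDetectionParams,
                        baseline_mask: np.ndarray | None) -> list[dict]:
    filt = bandpass(ch, *params.band)
    env = _sliding_rms(filt.samples, max(int(params.rms_window * ch.sample_rate), 1))
    ref = env if baseline_mask is None else env[baseline_mask]
    mu, sd = float(np.mean(ref)), float(np.std(ref))
    if sd == 0:
        return []
    peak_th = mu + params.threshold_sd * sd
    edge_th = mu + params.edge_sd * sd

    idx, props = sps.find_peaks(env, height=peak_th,
                                distance=int(0.020 * ch.sample_rate))
    out = []
    above = env > edge_th
    for i, pk in enumerate(idx):
        a = pk
        while a > 0 and above[a - 1]:
            a -= 1
        b = pk
        while b < len(env) - 1 and above[b + 1]:
            b += 1
        dur = (b - a + 1) / ch.sample_rate
        if not (params.min_duration <= dur <= params.max_duration):
            continue
        t_peak = ch.start_time + pk / ch.sample_rate
        frame = stft_frames(ch, np.array([t_peak]),
                            window_length=params.stft_window, zero_pad=4)
        if not frame.valid[0]:
            continue
        sel = (frame.frequencies >= params.band[0]) & (frame.frequencies <= params.band[1])
        f_peak = float(frame.frequencies[sel][np.argmax(frame.power[0, sel])])
        out.append({"time": t_peak, "duration": dur, "frequency": f_peak,
                    "amplitude": float(props["peak_heights"][i])})
    return out


def detect_ripples(
    lfp: TimeSeries,
    params: RippleDetectionParams | None = None,
    baseline_mask: np.ndarray | None = None,
) -> list[RippleEvent]:
    """Detect ripple events on a multi-channel LFP.

    ``baseline_mask`` optionally restricts the envelope statistics used for
    thresholding (e.g. to sitting epochs); default is the whole trace.
    Requires at least ``params.min_channels`` channels and a sample rate
    that resolves the ripple band.
    """
    params = params or RippleDetectionParams()
    if lfp.n_channels < params.min_channels:
        raise ValueError(
            f"ripple detection needs >= {params.min_channels} channels, "
            f"got {lfp.n_channels}"
        )
    if lfp.sample_rate < 600:
        raise ValueError("sample rate must be >= 600 Hz to resolve ripples")

    per_channel = [
        _channel_candidates(lfp.channel(c), params, baseline_mask)
        for c in range(lfp.n_channels)
    ]

    # cluster candidates across channels by peak-time coincidence
    flat = [
        dict(c, channel=ci) for ci, cands in enumerate(per_channel) for c in cands
    ]
    flat.sort(key=lambda c: c["time"])
    events: list[RippleEvent] = []
    used = np.zeros(len(flat), dtype=bool)
    for i, c in enumerate(flat):
        if used[i]:
            continue
        cluster = [i]
        for j in range(i + 1, len(flat)):
            if flat[j]["time"] - flat[cluster[-1]]["time"] > params.coincidence:
                break
            cluster.append(j)
        used[cluster] = True
        members = [flat[k] for k in cluster]
        chans = sorted({m["channel"] for m in members})
        in_band = [m for m in members
                   if params.freq_range[0] <= m["frequency"] <= params.freq_range[1]]
        if len(chans) < params.min_channels or not in_band:
            continue
        best = max(in_band, key=lambda m: m["duration"])  # longest per cluster
        events.append(RippleEvent(
            time=best["time"], duration=best["duration"],
            frequency=best["frequency"], n_channels=len(chans),
            amplitude=max(m["amplitude"] for m in members), channels=chans,
        ))
    return events


def ripple_rate(
    events: list,
    trials: TrialTable,
    states: np.ndarray | None = None,
    t_before: float = 2.0,
    t_after: float = 2.0,
    binwidth: float = 0.25,
) -> dict:
    """Peri-CS ripple occurrence rate (events/s per trial), per state.

    Returns ``{"time": centres, "rates": {state: trace}, "n_trials": {...}}``.
    """
    times = np.array([ev.time if hasattr(ev, "time") else ev["time"] for ev in events])
    edges = np.arange(-t_before, t_after + binwidth / 2, binwidth)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if states is None:
        states = trials.states
    states = np.asarray(states, dtype=object)

    rates, n_trials = {}, {}
    for st in pd.unique(states):
        idx = np.flatnonzero(states == st)
        hist = np.zeros(len(centres))
        for i in idx:
            cs = trials.cs_onsets[i]
            rel = times[(times >= cs - t_before) & (times < cs + t_after)] - cs
            hist += np.histogram(rel, bins=edges)[0]
        if idx.size:
            rates[st] = hist / idx.size / binwidth
            n_trials[st] = int(idx.size)
    return {"time": centres, "rates": rates, "n_trials": n_trials}


def split_trials_by_ripple(
    events: list,
    trials: TrialTable,
    pre_window: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition trials by ripple presence in the pre-CS window [−w, 0).

    Returns boolean masks ``(ripple_trials, non_ripple_trials)`` over the
    trial table.  The window is half-open: an event exactly at the CS onset
    does not count.
    """
    times = np.array([ev.time if hasattr(ev, "time") else ev["time"] for ev in events])
    has = np.zeros(len(trials), dtype=bool)
    for i, cs in enumerate(trials.cs_onsets):
        has[i] = bool(np.any((times >= cs - pre_window) & (times < cs)))
    return has, ~has
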