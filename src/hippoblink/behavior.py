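"""Behavioural analysis: conditioned-response detection and trial state.

The conditioned response (CR) is an anticipatory eyelid-EMG burst before the
US.  Detection band-passes the differential EMG to 120–960 Hz and compares
RMS amplitude in three 100 ms windows per trial:

* baseline — the 100 ms ending at CS onset,
* CR       — 380 to 480 ms after CS onset (the US arrives at 500 ms),
* control  — 580 to 480 ms *before* the CS onset.

A trial is a blink iff [CR − baseline] exceeds the session's 95th percentile
of [control − baseline]; by construction the detector's false-positive floor
on stationary EMG is 5%.

Trials are classified run / sit / ambiguous from the mean speed in a pre-CS
window, with separate thresholds so that mid-speed trials are excluded from
state-split analyses rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import Trajectory, TrialTable
from .signal_core import bandpass, windowed_rms
from .timeseries import TimeSeries

__all__ = ["CRResult", "detect_crs", "classify_trial_state", "moving_mask"]

EMG_BAND = (120.0, 960.0)
# (start, end) in seconds relative to CS onset
BASELINE_WINDOW = (-0.100, 0.000)
CR_WINDOW = (0.380, 0.480)
CONTROL_WINDOW = (-0.580, -0.480)
STARTLE_WINDOW = (0.000, 0.080)  # diagnostic only


@dataclass
class CRResult:
    """Per-trial RMS values and blink calls plus the session CR rate."""

    table: pd.DataFrame       # trial, baseline_rms, cr_rms, control_rms, is_blink, valid
    cr_rate: float
    cr_rate_ci: tuple         # 95% Bernoulli (Wald) interval
    threshold: float          # 95th percentile of [control − baseline]

    @property
    def is_blink(self) -> np.ndarray:
        return self.table["is_blink"].to_numpy()


def detect_crs(
    emg: TimeSeries,
    trials: TrialTable,
    percentile: float = 95.0,
    include_startle: bool = False,
) -> CRResult:
    """Detect conditioned responses on eyelid EMG.

    Requires the EMG to cover every trial's control-to-CR span; trials it
    does not cover are flagged invalid and excluded from both the percentile
    and the CR rate.
    """
    if len(trials) < 20:
        raise ValueError("need at least 20 trials for a stable percentile")
    filtered = bandpass(emg, *EMG_BAND)

    rows = []
    for i, cs in enumerate(trials.cs_onsets):
        row = {"trial": i}
        windows = {
            "baseline_rms": BASELINE_WINDOW,
            "cr_rms": CR_WINDOW,
            "control_rms": CONTROL_WINDOW,
        }
        if include_startle:
            windows["startle_rms"] = STARTLE_WINDOW
        valid = True
        for name, (a, b) in windows.items():
            try:
                row[name] = windowed_rms(filtered, cs + a, cs + b)
            except ValueError:
                row[name] = np.nan
                valid = False
        row["valid"] = valid
        rows.append(row)
    table = pd.DataFrame(rows)

    ok = table["valid"].to_numpy()
    if not ok.any():
        raise ValueError("EMG covers no trial windows")
    null_diff = (table["control_rms"] - table["baseline_rms"]).to_numpy()[ok]
    threshold = float(np.percentile(null_diff, percentile))
    cr_diff = (table["cr_rms"] - table["baseline_rms"]).to_numpy()
    table["is_blink"] = ok & (cr_diff > threshold)

    n = int(ok.sum())
    rate = float(table.loc[ok, "is_blink"].mean())
    se = np.sqrt(rate * (1 - rate) / n)
    ci = (max(rate - 1.96 * se, 0.0), min(rate + 1.96 * se, 1.0))
    return CRResult(table=table, cr_rate=rate, cr_rate_ci=ci, threshold=threshold)


def classify_trial_state(
    traj: Trajectory,
    trials: TrialTable,
    run_thresh: float = 8.0,
    sit_thresh: float = 2.0,
    window: float = 0.5,
) -> TrialTable:
    """Label each trial run / sit / ambiguous from pre-CS speed.

    Speed is averaged over ``window`` seconds ending at the CS onset;
    ``>= run_thresh`` → run, ``<= sit_thresh`` → sit, otherwise ambiguous.
    Trials whose window leaves the trajectory span are labelled 'invalid'.
    """
    if sit_thresh > run_thresh:
        raise ValueError("sit_thresh must not exceed run_thresh")
    labels = []
    velocities = []
    dt = 1.0 / traj.sample_rate
    for cs in trials.cs_onsets:
        if cs - window < traj.start_time or cs > traj.end_time:
            labels.append("invalid")
            velocities.append(np.nan)
            continue
        tt = np.arange(cs - window, cs, dt)
        v = float(np.mean(traj.speed_at(tt)))
        velocities.append(v)
        if v >= run_thresh:
            labels.append("run")
        elif v <= sit_thresh:
            labels.append("sit")
        else:
            labels.append("ambiguous")
    return trials.with_column("velocity", velocities).with_column("state", labels)


def moving_mask(traj: Trajectory, v_thresh: float = 2.0) -> np.ndarray:
    """Per-sample boolean mask: True where speed exceeds ``v_thresh`` cm/s."""
    return traj.speed > v_thresh
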