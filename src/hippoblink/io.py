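"""Session-directory container format.

A session lives in one directory of plain tables plus an HDF5 LFP store:

* ``trajectory.csv`` — time, x, y, speed, direction, state
* ``spikes.csv``     — unit, time (+ per-unit features in ``units.csv``)
* ``trials.csv``     — the trial table
* ``emg.csv``        — time, emg
* ``lfp.h5``         — float32 array (channels × samples) with a JSON
  header (``lfp.json``) giving sample rate, start time and channel map
* ``ground_truth.json`` — only for synthetic sessions
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import EnvironmentSpec, SpikeTrain, Trajectory, TrialTable
from .synthetic import SyntheticSession
from .timeseries import TimeSeries

__all__ = ["write_session", "read_session", "Session"]


class Session:
    """A loaded session directory (real or synthetic)."""

    def __init__(self, trajectory, states, spikes, trials, lfp=None, emg=None,
                 ground_truth=None, path=None):
        self.trajectory = trajectory
        self.states = states
        self.spikes = spikes
        self.trials = trials
        self.lfp = lfp
        self.emg = emg
        self.ground_truth = ground_truth
        self.path = path


def write_session(session: SyntheticSession | Session, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tdf = session.trajectory.to_frame()
    if getattr(session, "states", None) is not None:
        tdf["state"] = session.states
    tdf.to_csv(out / "trajectory.csv", index=False)

    rows = [(st.unit_id, t) for st in session.spikes for t in st.times]
    pd.DataFrame(rows, columns=["unit", "time"]).to_csv(out / "spikes.csv", index=False)
    pd.DataFrame(
        [{"unit": st.unit_id, "mean_rate": st.mean_rate,
          "spike_width": st.spike_width, "burst_fraction": st.burst_fraction}
         for st in session.spikes]
    ).to_csv(out / "units.csv", index=False)

    session.trials.df.to_csv(out / "trials.csv", index=False)

    if session.emg is not None:
        pd.DataFrame({"time": session.emg.times, "emg": session.emg.samples}).to_csv(
            out / "emg.csv", index=False)

    if session.lfp is not None:
        with h5py.File(out / "lfp.h5", "w") as f:
            d = f.create_dataset("lfp", data=session.lfp.samples.astype(np.float32))
            d.attrs["sample_rate"] = session.lfp.sample_rate
            d.attrs["start_time"] = session.lfp.start_time
        with open(out / "lfp.json", "w") as f:
            json.dump({"sample_rate": session.lfp.sample_rate,
                       "start_time": session.lfp.start_time,
                       "n_channels": session.lfp.n_channels,
                       "channel_map": list(range(session.lfp.n_channels))}, f)

    gt = getattr(session, "ground_truth", None)
    if gt is not None:
        if hasattr(gt, "to_json"):
            gt.to_json(out / "ground_truth.json")
        else:
            with open(out / "ground_truth.json", "w") as f:
                json.dump(gt, f, indent=1)

    env = session.trajectory.env
    with open(out / "environment.json", "w") as f:
        json.dump({"track_length": env.track_length, "track_width": env.track_width,
                   "endbox_length": env.endbox_length,
                   "endbox_width": env.endbox_width}, f)
    return out


def read_session(path) -> Session:
    path = Path(path)
    env = EnvironmentSpec()
    if (path / "environment.json").exists():
        with open(path / "environment.json") as f:
            env = EnvironmentSpec(**json.load(f))

    tdf = pd.read_csv(path / "trajectory.csv")
    traj = Trajectory(tdf["time"].to_numpy(), tdf["x"].to_numpy(),
                      tdf["y"].to_numpy(), env=env)
    states = tdf["state"].to_numpy(dtype=object) if "state" in tdf else None

    sdf = pd.read_csv(path / "spikes.csv")
    feats = {}
    if (path / "units.csv").exists():
        udf = pd.read_csv(path / "units.csv")
        feats = {int(r.unit): r for r in udf.itertuples()}
    spikes = []
    unit_ids = sorted(feats) if feats else sorted(sdf["unit"].unique())
    for uid in unit_ids:
        f = feats.get(uid)
        spikes.append(SpikeTrain(
            sdf.loc[sdf["unit"] == uid, "time"].to_numpy(), unit_id=int(uid),
            mean_rate=getattr(f, "mean_rate", None),
            spike_width=getattr(f, "spike_width", None),
            burst_fraction=getattr(f, "burst_fraction", None)))

    trials = TrialTable(pd.read_csv(path / "trials.csv"))

    emg = None
    if (path / "emg.csv").exists():
        edf = pd.read_csv(path / "emg.csv")
        et = edf["time"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(et)))
        emg = TimeSeries(edf["emg"].to_numpy(), fs, float(et[0]))

    lfp = None
    if (path / "lfp.h5").exists():
        with h5py.File(path / "lfp.h5", "r") as f:
            d = f["lfp"]
            lfp = TimeSeries(d[()].astype(float), float(d.attrs["sample_rate"]),
                             float(d.attrs["start_time"]))

    gt = None
    if (path / "ground_truth.json").exists():
        with open(path / "ground_truth.json") as f:
            gt = json.load(f)
    return Session(traj, states, spikes, trials, lfp=lfp, emg=emg,
                   ground_truth=gt, path=path)
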