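"""End-to-end orchestration: simulate → behavior → place fields →
CS response → ripples → theta, with a manifest and a figure-level report.

Each stage reads the session directory, writes its output tables next to
it, and records status plus content hashes in ``manifest.json``.  Stages
degrade gracefully: a session without LFP skips the ripple and theta
stages with an explicit status rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import classify_trial_state, detect_crs
from .cs_response import (
    peri_event_rates,
    predicted_vs_observed,
    response_summary,
)
from .io import Session, read_session, write_session
from .place_fields import (
    RateMapParams,
    build_rate_map,
    classify_pyramidal,
    classify_spatial,
    place_field_intensity,
)
from .ripples import RippleDetectionParams, detect_ripples, ripple_rate, split_trials_by_ripple
from .session import US_DELAY
from .synthetic import SessionConfig, simulate_session
from .theta import (
    classify_trial_lfp_state,
    extract_theta,
    mean_resultant,
    phase_transition,
    run_theta_reference,
)

__all__ = ["run_all", "make_report", "analyze_session", "check_arousal_signatures"]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _intensity_table(session: Session, maps: dict, window=(0.0, 0.5)) -> pd.DataFrame:
    """Per (unit, trial) place-field intensity over the post-CS window."""
    rows = []
    for uid, m in maps.items():
        for i, cs in enumerate(session.trials.cs_onsets):
            try:
                ip = place_field_intensity(m, session.trajectory,
                                           cs + window[0], cs + window[1])
            except ValueError:
                ip = np.nan
            rows.append({"unit": uid, "trial": i, "i_place": ip})
    return pd.DataFrame(rows)


def analyze_session(session: Session, theta_channel: int = 0,
                    rate_map_params: RateMapParams | None = None) -> dict:
    """Run every analysis stage in memory; returns a results dict.

    Keys: trials (state-labelled), cr (or None), maps, spatial_class,
    intensity, cs (per-cell summary DataFrame), ripple_events, ripple_rates,
    theta (transition + coherence) — stages without inputs are None.
    """
    results: dict = {}
    trials = classify_trial_state(session.trajectory, session.trials)
    results["trials"] = trials

    results["cr"] = None
    if session.emg is not None and len(trials) >= 20:
        results["cr"] = detect_crs(session.emg, trials)

    rmp = rate_map_params or RateMapParams()
    maps, spat_rows = {}, []
    pyramidal = {}
    for st in session.spikes:
        pyramidal[st.unit_id] = classify_pyramidal(
            st.mean_rate, st.spike_width, st.burst_fraction)
        m = build_rate_map(st, session.trajectory, trials, rmp)
        maps[st.unit_id] = m
        for thresh in (2.0, 5.0):
            sc = classify_spatial(m, peak_thresh=thresh)
            spat_rows.append({"unit": st.unit_id, "peak_thresh": thresh,
                              "label": sc.label, "peak_rate": sc.peak_rate})
    results["maps"] = maps
    results["pyramidal"] = pyramidal
    results["spatial_class"] = pd.DataFrame(spat_rows)

    itab = _intensity_table(session, maps)
    results["intensity"] = itab
    rows = []
    for st in session.spikes:
        ip = itab.loc[itab["unit"] == st.unit_id, "i_place"].to_numpy()
        rs = response_summary(st, trials, i_place=ip)
        rows.append({
            "unit": st.unit_id, "pre_rate": rs.pre_rate, "post_rate": rs.post_rate,
            "p_signed_rank": rs.p_signed_rank, "direction": rs.direction,
            "observed_reliability": rs.observed_reliability,
            "expected_reliability": rs.expected_reliability,
            "rho_place": rs.rho_place,
            "total_post_spikes": int(rs.post_counts.sum()),
            "total_pre_spikes": int(rs.pre_counts.sum()),
        })
    results["cs"] = pd.DataFrame(rows)
    results["summaries"] = None  # populated lazily by callers that need traces

    results["ripple_events"] = None
    results["ripple_rates"] = None
    results["theta"] = None
    if session.lfp is not None and session.lfp.n_channels >= 3:
        sit_mask = None
        if session.states is not None:
            idx = np.clip(np.searchsorted(session.trajectory.times,
                                          session.lfp.times),
                          0, len(session.states) - 1)
            sit_mask = session.states[idx] == "sit"
        events = detect_ripples(session.lfp, RippleDetectionParams(),
                                baseline_mask=sit_mask)
        results["ripple_events"] = events
        results["ripple_rates"] = ripple_rate(events, trials,
                                              states=trials.states)
        results["ripple_split"] = split_trials_by_ripple(events, trials)

    if session.lfp is not None:
        chan = session.lfp.channel(theta_channel)
        run_trials = trials.select(trials.states == "run")
        theta_res = {}
        if len(run_trials) >= 3:
            theta_res["transition_cs"] = phase_transition(chan, run_trials, "CS")
            ens = extract_theta(chan, run_trials, t_before=0.5, t_after=1.0)
            theta_res["coherence"] = mean_resultant(ens)
        if session.states is not None:
            ref = run_theta_reference(chan, session.trajectory, session.states)
            theta_res["lfp_state"] = classify_trial_lfp_state(chan, trials, ref)
        results["theta"] = theta_res or None
    return results


def _write_stage_outputs(out: Path, results: dict) -> dict:
    status = {}
    results["trials"].df.to_csv(out / "trials_classified.csv", index=False)
    status["behavior_state"] = "complete"

    if results["cr"] is not None:
        cr = results["cr"]
        tab = cr.table.copy()
        tab["state"] = results["trials"].states[: len(tab)]
        tab.to_csv(out / "cr_results.csv", index=False)
        status["cr_detection"] = "complete"
    else:
        status["cr_detection"] = "skipped: no EMG"

    results["spatial_class"].to_csv(out / "spatial_class.csv", index=False)
    results["intensity"].to_csv(out / "place_field_intensity.csv", index=False)
    results["cs"].to_csv(out / "cs_response.csv", index=False)
    status["place_fields"] = status["cs_response"] = "complete"

    if results["ripple_events"] is not None:
        pd.DataFrame(
            [{"time": e.time, "duration": e.duration, "frequency": e.frequency,
              "n_channels": e.n_channels, "amplitude": e.amplitude}
             for e in results["ripple_events"]]
        ).to_csv(out / "ripples.csv", index=False)
        status["ripples"] = "complete"
    else:
        status["ripples"] = "skipped: no LFP (or < 3 channels)"

    if results["theta"] and "transition_cs" in results["theta"]:
        results["theta"]["transition_cs"].table.to_csv(
            out / "phase_transition.csv", index=False)
        status["theta"] = "complete"
    elif results["theta"] and "lfp_state" in results["theta"]:
        results["theta"]["lfp_state"].to_csv(out / "trial_lfp_state.csv", index=False)
        status["theta"] = "partial: too few run trials for the transition analysis"
    else:
        status["theta"] = "skipped: no LFP"
    if results["theta"] and "lfp_state" in results["theta"]:
        results["theta"]["lfp_state"].to_csv(out / "trial_lfp_state.csv", index=False)
    return status


def run_all(session_dir=None, config: SessionConfig | None = None,
            seed: int = 0, out_dir=None) -> dict:
    """Run the full pipeline on an existing or freshly simulated session.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    if session_dir is None:
        if out_dir is None:
            raise ValueError("need out_dir when simulating")
        session = simulate_session(config or SessionConfig(), seed=seed)
        session_dir = write_session(session, out_dir)
        loaded = read_session(session_dir)
    else:
        session_dir = Path(session_dir)
        loaded = read_session(session_dir)
    results = analyze_session(loaded)
    status = _write_stage_outputs(session_dir, results)

    manifest = {
        "version": __version__,
        "seed": seed,
        "session_dir": str(session_dir),
        "stages": status,
        "hashes": {p.name: _hash_file(p)
                   for p in sorted(session_dir.glob("*.csv"))},
    }
    with open(session_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def check_arousal_signatures(session: Session, results: dict,
                             min_post_spikes: int = 20) -> dict:
    """Programmatic check of the three signatures of arousal-gated place
    firing on an analyzed session.

    (a) cells with enough post-CS spikes have positive spatial-tuning ρ;
    (b) run-trial pre/post rate change is non-significant (pooled);
    (c) sit-trial ripple rate collapses after the CS.
    """
    from .cs_response import signed_rank_change, window_counts

    cs = results["cs"]
    active = cs[cs["total_post_spikes"] >= min_post_spikes]
    frac_pos = float((active["rho_place"] > 0).mean()) if len(active) else np.nan

    trials = results["trials"]
    run = trials.select(trials.states == "run")
    pooled_pre = np.zeros(len(run), dtype=int)
    pooled_post = np.zeros(len(run), dtype=int)
    for st in session.spikes:
        pooled_pre += window_counts(st, run, "pre_cs")
        pooled_post += window_counts(st, run, "post_cs")
    run_p = signed_rank_change(pooled_pre, pooled_post)["p"]

    pre_rate = post_rate = np.nan
    if results["ripple_rates"] is not None and "sit" in results["ripple_rates"]["rates"]:
        rr = results["ripple_rates"]
        trace = rr["rates"]["sit"]
        tt = rr["time"]
        pre_rate = float(np.mean(trace[(tt >= -2.0) & (tt < 0.0)]))
        post_rate = float(np.mean(trace[(tt >= 0.5) & (tt < 2.0)]))

    return {
        "frac_positive_rho": frac_pos,
        "n_active_cells": int(len(active)),
        "run_pooled_p": float(run_p),
        "sit_ripple_rate_pre": pre_rate,
        "sit_ripple_rate_post": post_rate,
    }


def make_report(session_dir, out_subdir: str = "report") -> Path:
    """Regenerate figure-level summaries from an analyzed session directory.

    Produces reliability, tuning-correlation, peri-event, ripple-rate and
    phase-transition panels plus ``summary.json``; panels without inputs
    state "no data" instead of failing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    session_dir = Path(session_dir)
    out = session_dir / out_subdir
    out.mkdir(exist_ok=True)
    session = read_session(session_dir)
    results = analyze_session(session)
    summary: dict = {"n_trials": len(session.trials),
                     "n_units": len(session.spikes)}

    cs = results["cs"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    if len(cs):
        axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
        axes[0].scatter(cs["expected_reliability"], cs["observed_reliability"], s=12)
        axes[0].set(xlabel="expected reliability", ylabel="observed reliability",
                    xlim=(0, 1), ylim=(0, 1))
        axes[1].hist(cs["rho_place"].dropna(), bins=21, range=(-1, 1))
        axes[1].set(xlabel="Spearman ρ (counts vs I_place)", ylabel="cells")
        summary["mean_observed_reliability"] = float(cs["observed_reliability"].mean())
        summary["mean_expected_reliability"] = float(cs["expected_reliability"].mean())
    else:
        axes[0].text(0.5, 0.5, "no data", ha="center")
    fig.tight_layout()
    fig.savefig(out / "reliability.png", dpi=120)
    plt.close(fig)

    rr = results["ripple_rates"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if rr and rr["rates"]:
        for st, trace in rr["rates"].items():
            ax.plot(rr["time"], trace, label=f"{st} (n={rr['n_trials'][st]})")
        ax.axvline(0, color="k", lw=0.8)
        ax.axvline(US_DELAY, color="r", lw=0.8)
        ax.legend()
        ax.set(xlabel="time from CS onset (s)", ylabel="ripple rate (events/s)")
    else:
        ax.text(0.5, 0.5, "no data", ha="center")
    fig.tight_layout()
    fig.savefig(out / "ripple_rate.png", dpi=120)
    plt.close(fig)

    th = results["theta"]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    if th and "transition_cs" in th:
        pt = th["transition_cs"]
        ax.scatter(pt.table["pre_phase"], pt.table["post_phase"], s=10)
        ax.set(xlabel="pre-CS phase (rad)", ylabel="post-CS phase (rad)",
               xlim=(-np.pi, np.pi), ylim=(-np.pi, np.pi))
        summary["theta_circular_correlation"] = pt.circular_correlation
        summary["theta_mean_shift"] = pt.mean_shift
    else:
        ax.text(0.5, 0.5, "no data", ha="center")
    fig.tight_layout()
    fig.savefig(out / "phase_transition.png", dpi=120)
    plt.close(fig)

    if results["cr"] is not None:
        summary["cr_rate"] = results["cr"].cr_rate
    summary["signatures"] = check_arousal_signatures(session, results)
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, default=float)
    return out
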