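"""Occupancy-normalised spatial rate maps and place-field statistics.

Rate maps divide the spike count in each spatial bin by the time spent
there.  Track maps are one-dimensional and directional (one map per
direction of traversal, σ = 3 cm Gaussian smoothing); endbox maps are
two-dimensional and non-directional (σ = 1 cm).  Only moving samples
(speed > 2 cm/s) contribute, the 2 s window after every CS onset is
excluded so that evoked firing cannot contaminate the maps, and bins
occupied less than 50 ms/cm² are marked indeterminate.

The per-trial *place-field intensity* I_place is the trajectory average of
the map over a trial window:

    I_place = 1/(t2−t1) ∫ M(x(t), y(t)) dt,

using the direction-appropriate track map while the animal is on the track
and the endbox map while it is in a box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .session import EnvironmentSpec, SpikeTrain, Trajectory, TrialTable
from .behavior import moving_mask

__all__ = [
    "RateMapParams",
    "RateMap",
    "SpatialClass",
    "build_rate_map",
    "classify_spatial",
    "place_field_intensity",
    "classify_pyramidal",
]


@dataclass
class RateMapParams:
    bin_size: float = 1.0            # cm (track bins and endbox pixels)
    sigma_track: float = 3.0         # cm
    sigma_box: float = 1.0           # cm
    speed_thresh: float = 2.0        # cm/s moving criterion
    cs_exclusion: float = 2.0        # s excluded after every CS onset
    occupancy_thresh: float = 0.050  # s/cm² below which a bin is invalid
    kernel_truncate: float = 4.0     # kernel half-width in sigmas


@dataclass
class SpatialClass:
    label: str            # no_field | endbox_only | track_only | track_and_endbox
    peak_rate: float      # Hz, max over all valid bins


@dataclass
class RateMap:
    """Directional track maps plus per-endbox 2-D maps.

    ``track[d]`` (d in 'rightward'/'leftward') are smoothed rate vectors on
    ``track_centers``; ``boxes[b]`` (b in 'left_box'/'right_box') are
    smoothed 2-D rate arrays.  Raw (unsmoothed) maps and occupancy are kept
    for the conservation invariant Σ raw_rate × occupancy = spikes used.
    """

    env: EnvironmentSpec
    params: RateMapParams
    track_centers: np.ndarray
    track: dict
    track_raw: dict
    track_counts: dict          # raw spike counts per bin
    track_occupancy: dict       # seconds per bin
    track_valid: dict
    boxes: dict
    boxes_raw: dict
    boxes_counts: dict
    boxes_occupancy: dict
    boxes_valid: dict
    box_edges: dict             # (x_edges, y_edges) per box
    n_spikes_used: int = 0
    all_invalid: bool = False

    @property
    def peak_rate(self) -> float:
        vals = []
        for d, m in self.track.items():
            v = m[self.track_valid[d]]
            if v.size:
                vals.append(v.max())
        for b, m in self.boxes.items():
            v = m[self.boxes_valid[b]]
            if v.size:
                vals.append(v.max())
        return float(max(vals)) if vals else 0.0

    def lookup(self, x: np.ndarray, y: np.ndarray, direction: np.ndarray) -> np.ndarray:
        """Map value at each position; NaN on invalid or out-of-range bins.

        Uses the direction-appropriate track map on the track (direction
        +1 → rightward) and the 2-D box map in an endbox.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        direction = np.atleast_1d(np.asarray(direction, float))
        out = np.full(x.shape, np.nan)
        region = self.env.region(x, y)
        bs = self.params.bin_size

        on_track = region == "track"
        if on_track.any():
            bins = np.clip((x[on_track] / bs).astype(int), 0, len(self.track_centers) - 1)
            dname = np.where(direction[on_track] >= 0, "rightward", "leftward")
            vals = np.full(bins.shape, np.nan)
            for d in ("rightward", "leftward"):
                sel = dname == d
                if sel.any():
                    m = np.where(self.track_valid[d], self.track[d], np.nan)
                    vals[sel] = m[bins[sel]]
            out[on_track] = vals

        for b in ("left_box", "right_box"):
            sel = region == b
            if not sel.any():
                continue
            xe, ye = self.box_edges[b]
            ix = np.clip(((x[sel] - xe[0]) / bs).astype(int), 0, len(xe) - 2)
            iy = np.clip(((y[sel] - ye[0]) / bs).astype(int), 0, len(ye) - 2)
            m = np.where(self.boxes_valid[b], self.boxes[b], np.nan)
            out[sel] = m[ix, iy]
        return out


def _masked_smooth(counts: np.ndarray, occupancy: np.ndarray, valid: np.ndarray,
                   sigma_bins: float, truncate: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth numerator and denominator separately, honouring the mask."""
    if sigma_bins <= 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(valid & (occupancy > 0), counts / np.where(occupancy > 0, occupancy, 1), 0.0)
        return rate, occupancy
    c = np.where(valid, counts, 0.0)
    o = np.where(valid, occupancy, 0.0)
    cs = ndimage.gaussian_filter(c, sigma_bins, truncate=truncate, mode="constant")
    os_ = ndimage.gaussian_filter(o, sigma_bins, truncate=truncate, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(os_ > 0, cs / np.where(os_ > 0, os_, 1), 0.0)
    return rate, os_


def build_rate_map(
    spikes: SpikeTrain,
    traj: Trajectory,
    trials: TrialTable | None = None,
    params: RateMapParams | None = None,
) -> RateMap:
    """Occupancy-normalised rate maps for one unit.

    Moving samples only; the 2 s post-CS window of every trial is excluded
    from both spike and occupancy counts; Gaussian smoothing is applied to
    spike-count and occupancy maps before the division, respecting the
    low-occupancy validity mask.
    """
    params = params or RateMapParams()
    env = traj.env
    bs = params.bin_size

    include = moving_mask(traj, params.speed_thresh)
    spike_ok = traj.speed_at(spikes.times) > params.speed_thresh
    if trials is not None:
        for cs in trials.cs_onsets:
            include &= ~((traj.times >= cs) & (traj.times < cs + params.cs_exclusion))
            spike_ok &= ~((spikes.times >= cs) & (spikes.times < cs + params.cs_exclusion))

    dt = 1.0 / traj.sample_rate
    region = env.region(traj.x, traj.y)
    sx, sy = traj.position_at(spikes.times)
    sdir = traj.direction_at(spikes.times)
    sregion = env.region(sx, sy)

    n_track_bins = int(np.ceil(env.track_length / bs))
    track_edges = np.arange(n_track_bins + 1) * bs
    track_centers = 0.5 * (track_edges[:-1] + track_edges[1:])

    track, track_raw, track_occ, track_valid = {}, {}, {}, {}
    track_cnt: dict = {}
    n_used = 0
    for d, sign in (("rightward", 1.0), ("leftward", -1.0)):
        sel = include & (region == "track") & (traj.direction == sign)
        occ = np.histogram(traj.x[sel], bins=track_edges)[0] * dt
        ssel = spike_ok & (sregion == "track") & (sdir == sign)
        cnt = np.histogram(sx[ssel], bins=track_edges)[0].astype(float)
        n_used += int(ssel.sum())
        valid = occ / (bs * env.track_width) >= params.occupancy_thresh
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(valid, cnt / np.where(occ > 0, occ, 1), np.nan)
        rate, _ = _masked_smooth(cnt, occ, valid, params.sigma_track / bs,
                                 params.kernel_truncate)
        track[d], track_raw[d] = rate, raw
        track_cnt[d] = cnt
        track_occ[d], track_valid[d] = occ, valid

    boxes, boxes_raw, boxes_occ, boxes_valid, box_edges = {}, {}, {}, {}, {}
    boxes_cnt: dict = {}
    spans = {
        "left_box": (np.arange(-env.endbox_length, bs / 2, bs),
                     np.arange(-env.endbox_width / 2, env.endbox_width / 2 + bs / 2, bs)),
        "right_box": (np.arange(env.track_length, env.track_length + env.endbox_length + bs / 2, bs),
                      np.arange(-env.endbox_width / 2, env.endbox_width / 2 + bs / 2, bs)),
    }
    for b, (xe, ye) in spans.items():
        sel = include & (region == b)
        occ = np.histogram2d(traj.x[sel], traj.y[sel], bins=(xe, ye))[0] * dt
        ssel = spike_ok & (sregion == b)
        cnt = np.histogram2d(sx[ssel], sy[ssel], bins=(xe, ye))[0]
        n_used += int(ssel.sum())
        valid = occ / (bs * bs) >= params.occupancy_thresh
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(valid, cnt / np.where(occ > 0, occ, 1), np.nan)
        rate, _ = _masked_smooth(cnt, occ, valid, params.sigma_box / bs,
                                 params.kernel_truncate)
        boxes[b], boxes_raw[b] = rate, raw
        boxes_cnt[b] = cnt
        boxes_occ[b], boxes_valid[b] = occ, valid
        box_edges[b] = (xe, ye)

    all_invalid = not (
        any(v.any() for v in track_valid.values())
        or any(v.any() for v in boxes_valid.values())
    )
    if all_invalid:
        import warnings

        warnings.warn("no bins meet the occupancy criterion; map is all-invalid",
                      stacklevel=2)
    return RateMap(
        env=env, params=params, track_centers=track_centers,
        track=track, track_raw=track_raw, track_counts=track_cnt,
        track_occupancy=track_occ,
        track_valid=track_valid, boxes=boxes, boxes_raw=boxes_raw,
        boxes_counts=boxes_cnt, boxes_occupancy=boxes_occ,
        boxes_valid=boxes_valid,
        box_edges=box_edges, n_spikes_used=n_used, all_invalid=all_invalid,
    )


def _has_contiguous_field(values: np.ndarray, valid: np.ndarray,
                          thresh: float, min_bins: int = 3) -> bool:
    above = valid & (values > thresh)
    if not above.any():
        return False
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(values, dtype=int), labels,
                               index=np.arange(1, n + 1))
    return bool(np.any(sizes >= min_bins))


def classify_spatial(rate_map: RateMap, peak_thresh: float = 2.0,
                     min_bins: int = 3) -> SpatialClass:
    """Classify a cell's spatial tuning from where suprathreshold fields lie.

    A field is a contiguous region of at least ``min_bins`` valid bins above
    ``peak_thresh`` Hz (single suprathreshold bins are treated as noise).
    """
    on_track = any(
        _has_contiguous_field(rate_map.track[d], rate_map.track_valid[d],
                              peak_thresh, min_bins)
        for d in rate_map.track
    )
    in_box = any(
        _has_contiguous_field(rate_map.boxes[b], rate_map.boxes_valid[b],
                              peak_thresh, min_bins)
        for b in rate_map.boxes
    )
    if on_track and in_box:
        label = "track_and_endbox"
    elif on_track:
        label = "track_only"
    elif in_box:
        label = "endbox_only"
    else:
        label = "no_field"
    return SpatialClass(label=label, peak_rate=rate_map.peak_rate)


def place_field_intensity(rate_map: RateMap, traj: Trajectory,
                          t1: float, t2: float) -> float:
    """Trajectory-averaged map value over [t1, t2]; NaN if nothing valid."""
    if t2 <= t1:
        raise ValueError("need t2 > t1")
    if not traj.covers(t1, t2):
        raise ValueError(f"window [{t1}, {t2}] outside trajectory span")
    dt = 1.0 / traj.sample_rate
    tt = np.arange(t1, t2, min(dt, (t2 - t1) / 4))
    x, y = traj.position_at(tt)
    d = traj.direction_at(tt)
    vals = rate_map.lookup(x, y, d)
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def classify_pyramidal(
    mean_rate: float | None,
    spike_width: float | None,
    burst_fraction: float | None,
) -> bool | None:
    """Putative pyramidal cell iff rate < 4 Hz, spike width > 0.25 ms and
    more than 5% of inter-spike intervals are < 10 ms (all strict).

    Returns None (undetermined) when any feature is missing.
    """
    feats = (mean_rate, spike_width, burst_fraction)
    if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in feats):
        return None
    return bool(mean_rate < 4.0 and spike_width > 0.25 and burst_fraction > 0.05)
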