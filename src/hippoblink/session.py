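"""Session-level domain objects.

A recording session consists of an animal trajectory, sorted spike trains,
multi-channel LFP, an eyelid EMG trace, and a table of eyeblink trials.
This module defines the geometry of the environment (a linear track with an
endbox at each end) and the containers the analysis stages consume.

Coordinate convention: x runs along the long axis of the apparatus with the
track occupying [0, track_length]; the left endbox occupies negative x and
the right endbox x > track_length.  y is centred on the track midline.
All positions in cm, times in s, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import ndimage

__all__ = ["EnvironmentSpec", "Trajectory", "SpikeTrain", "TrialTable", "estimate_speed"]

# trial structure: 250 ms tone, 250 ms stimulus-free trace, 10 ms eyelid
# stimulation — so US onset is always CS onset + 500 ms
CS_DURATION = 0.250
TRACE_DURATION = 0.250
US_DURATION = 0.010
US_DELAY = CS_DURATION + TRACE_DURATION


@dataclass(frozen=True)
class EnvironmentSpec:
    """Linear track with an endbox at each end.

    Defaults follow the apparatus the analyses assume: a 180 × 7.5 cm track
    terminating in 22 × 16 cm endboxes containing the reward ports.
    """

    track_length: float = 180.0
    track_width: float = 7.5
    endbox_length: float = 22.0   # along the track axis
    endbox_width: float = 16.0    # across the track axis

    def __post_init__(self) -> None:
        for name in ("track_length", "track_width", "endbox_length", "endbox_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.endbox_width < self.track_width:
            raise ValueError("endboxes must be at least as wide as the track")

    @property
    def x_min(self) -> float:
        return -self.endbox_length

    @property
    def x_max(self) -> float:
        return self.track_length + self.endbox_length

    def region(self, x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        """Label positions 'track', 'left_box' or 'right_box'.

        A position is on the track iff its x lies within the track span;
        endboxes are exclusive of the track.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.full(x.shape, "track", dtype=object)
        out[x < 0] = "left_box"
        out[x > self.track_length] = "right_box"
        return out


def estimate_speed(
    times: np.ndarray, x: np.ndarray, y: np.ndarray, smooth_window: float = 0.2
) -> np.ndarray:
    """Speed (cm/s) from central differences of boxcar-smoothed position.

    ``smooth_window`` is the boxcar width in seconds (default 200 ms).
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        return np.zeros_like(times)
    dt = float(np.median(np.diff(times)))
    n = max(int(round(smooth_window / dt)), 1)
    kernel = np.ones(n) / n
    xs = ndimage.convolve1d(np.asarray(x, float), kernel, mode="nearest")
    ys = ndimage.convolve1d(np.asarray(y, float), kernel, mode="nearest")
    vx = np.gradient(xs, times)
    vy = np.gradient(ys, times)
    return np.hypot(vx, vy)


@dataclass
class Trajectory:
    """Time-stamped animal position with derived speed and heading.

    ``direction`` is +1 while heading toward larger x, −1 toward smaller x,
    determined from the sign of the smoothed x-velocity.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    env: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    speed: np.ndarray = None
    direction: np.ndarray = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")
        if self.speed is None:
            self.speed = estimate_speed(self.times, self.x, self.y)
        if self.direction is None:
            dt = np.median(np.diff(self.times)) if len(self.times) > 1 else 1.0
            n = max(int(round(0.2 / dt)), 1)
            xs = ndimage.convolve1d(self.x, np.ones(n) / n, mode="nearest")
            grad = np.gradient(xs, self.times, edge_order=1)
            # ties break rightward so every sample has a definite heading
            self.direction = np.where(grad >= 0, 1.0, -1.0)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def start_time(self) -> float:
        return float(self.times[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    def covers(self, t0: float, t1: float) -> bool:
        return self.start_time <= t0 and t1 <= self.end_time

    def position_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.x), np.interp(t, self.times, self.y)

    def speed_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, float), self.times, self.speed)

    def direction_at(self, t: np.ndarray) -> np.ndarray:
        # nearest-sample heading (interpolating a sign is meaningless)
        idx = np.clip(
            np.searchsorted(self.times, np.asarray(t, float)), 0, len(self.times) - 1
        )
        return self.direction[idx]

    def region_at(self, t: np.ndarray) -> np.ndarray:
        xs, ys = self.position_at(t)
        return self.env.region(xs, ys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "x": self.x, "y": self.y,
             "speed": self.speed, "direction": self.direction}
        )


@dataclass
class SpikeTrain:
    """A sorted unit's spike times plus the summary features used for
    pyramidal-cell classification."""

    times: np.ndarray
    unit_id: int = 0
    mean_rate: float | None = None        # Hz over the whole session
    spike_width: float | None = None      # ms
    burst_fraction: float | None = None   # fraction of ISIs < 10 ms

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def count_in(self, t0: float, t1: float) -> int:
        """Spike count in the half-open window [t0, t1)."""
        return int(
            np.searchsorted(self.times, t1, "left")
            - np.searchsorted(self.times, t0, "left")
        )

    @staticmethod
    def summary_features(times: np.ndarray, duration: float,
                         spike_width: float | None = None) -> dict:
        times = np.sort(np.asarray(times, float))
        isis = np.diff(times)
        return {
            "mean_rate": len(times) / duration if duration > 0 else np.nan,
            "spike_width": spike_width,
            "burst_fraction": float(np.mean(isis < 0.010)) if len(isis) else 0.0,
        }


class TrialTable:
    """Table of eyeblink trials.

    Wraps a DataFrame with one row per trial: ``cs_onset`` (s), delivery
    location (``x``, ``y`` in cm), mean pre-CS ``velocity`` (cm/s) and a
    locomotor ``state`` label in {run, sit, ambiguous} once classified.
    """

    def __init__(self, df: pd.DataFrame):
        if "cs_onset" not in df.columns:
            raise ValueError("trial table requires a cs_onset column")
        df = df.sort_values("cs_onset").reset_index(drop=True)
        onsets = df["cs_onset"].to_numpy()
        if len(onsets) > 1 and np.any(np.diff(onsets) <= US_DELAY + US_DURATION):
            raise ValueError("trials overlap: CS onsets closer than one trial span")
        self.df = df
        if "trial" not in df.columns:
            self.df.insert(0, "trial", np.arange(len(df)))

    @classmethod
    def from_onsets(cls, cs_onsets: np.ndarray, x: np.ndarray | None = None,
                    y: np.ndarray | None = None) -> "TrialTable":
        cs_onsets = np.asarray(cs_onsets, dtype=float)
        df = pd.DataFrame({"cs_onset": cs_onsets})
        if x is not None:
            df["x"] = np.asarray(x, float)
        if y is not None:
            df["y"] = np.asarray(y, float)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cs_onsets(self) -> np.ndarray:
        return self.df["cs_onset"].to_numpy()

    @property
    def us_onsets(self) -> np.ndarray:
        return self.cs_onsets + US_DELAY

    @property
    def us_offsets(self) -> np.ndarray:
        return self.us_onsets + US_DURATION

    @property
    def states(self) -> np.ndarray:
        if "state" not in self.df.columns:
            return np.full(len(self), "unclassified", dtype=object)
        return self.df["state"].to_numpy()

    def with_column(self, name: str, values) -> "TrialTable":
        df = self.df.copy()
        df[name] = values
        out = TrialTable.__new__(TrialTable)
        out.df = df
        return out

    def select(self, mask: np.ndarray) -> "TrialTable":
        out = TrialTable.__new__(TrialTable)
        out.df = self.df.loc[np.asarray(mask, bool)].reset_index(drop=True)
        return out
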