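"""Uniformly sampled time-series containers shared across the package.

LFP and EMG traces are represented as :class:`TimeSeries` (amplitude in µV
by convention, though nothing enforces units), and short-time Fourier
transforms as :class:`STFTResult`.  Both are thin, immutable-by-convention
dataclasses around numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "STFTResult"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Signal samples.  1-D for a single channel, ``(n_channels, n_samples)``
        for multi-channel data.
    sample_rate : float
        Samples per second (Hz), strictly positive.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.samples.shape[-1] < 1:
            raise ValueError("TimeSeries needs at least one sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        """Time just past the last sample (half-open extent)."""
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def index_at(self, t: float) -> int:
        """Index of the sample covering time ``t`` (floor convention)."""
        return int(np.floor((t - self.start_time) * self.sample_rate))

    def slice(self, t_start: float, t_end: float) -> "TimeSeries":
        """Samples in the half-open window ``[t_start, t_end)``."""
        i0 = int(np.ceil((t_start - self.start_time) * self.sample_rate - 1e-9))
        i1 = int(np.ceil((t_end - self.start_time) * self.sample_rate - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError(f"empty window [{t_start}, {t_end})")
        return TimeSeries(
            self.samples[..., i0:i1],
            self.sample_rate,
            self.start_time + i0 / self.sample_rate,
        )

    def channel(self, i: int) -> "TimeSeries":
        if self.samples.ndim == 1:
            if i != 0:
                raise IndexError("single-channel series")
            return self
        return TimeSeries(self.samples[i], self.sample_rate, self.start_time)


@dataclass
class STFTResult:
    """Short-time Fourier transform with an explicit locality contract.

    The coefficient at frame time ``times[j]`` and frequency ``frequencies[k]``
    is computed from samples within ``times[j] ± window_length / 2`` only —
    frames that would extend past the data are marked invalid rather than
    padded, so the guarantee is never silently violated.
    """

    times: np.ndarray            # frame-centre times, s
    frequencies: np.ndarray      # Hz
    coefficients: np.ndarray     # complex, shape (n_frames, n_freqs)
    window_length: float         # s
    window: str = "kaiser"
    valid: np.ndarray = field(default=None)  # bool per frame

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def frame_at(self, t: float) -> int:
        """Index of the frame whose centre is nearest ``t``."""
        return int(np.argmin(np.abs(self.times - t)))
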