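"""Deterministic signal-processing primitives.

Three operations shared by the EMG, ripple and theta stages:

* :func:`bandpass` — zero-phase FIR band-pass (forward–backward, so no group
  delay and ≥ 40 dB stop-band attenuation after the two passes).
* :func:`windowed_rms` — root-mean-square amplitude over a half-open window.
* :func:`stft` — short-time Fourier transform computed frame by frame from
  explicit sample slices, which is what makes the locality guarantee of the
  theta analysis checkable: the coefficient at time ``t`` depends only on
  samples within ``t ± window_length/2``, bit for bit.

The STFT deliberately does not delegate to ``scipy.signal.stft``: that
implementation pads and overlaps in ways that would make the per-frame
locality contract an accident of implementation rather than a guarantee.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .timeseries import STFTResult, TimeSeries

__all__ = ["bandpass", "windowed_rms", "stft", "band_power"]

# Kaiser shape: alpha-convention, beta = pi * alpha.  alpha = 1 is the
# default used for theta phase estimation (400 ms window).
KAISER_ALPHA = 1.0


def _fir_taps(low: float, high: float, fs: float) -> np.ndarray:
    """Window-method FIR band-pass taps.

    The transition band is half the low edge (capped at 40 Hz) — a rule of
    thumb that keeps the filter short while separating e.g. 50 Hz line noise
    from an 80 Hz band edge.
    """
    transition = min(max(low / 2.0, 4.0), 40.0)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd for a type-I linear-phase filter
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def bandpass(x: TimeSeries, low: float, high: float) -> TimeSeries:
    """Zero-phase band-pass filter.

    Parameters
    ----------
    x : TimeSeries
        Input, single- or multi-channel.
    low, high : float
        Band edges in Hz; ``0 < low < high < sample_rate / 2``.

    Returns
    -------
    TimeSeries
        Filtered signal, same length and start time as the input.
    """
    nyq = x.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < {nyq:g} Hz; "
            f"got ({low}, {high})"
        )
    taps = _fir_taps(low, high, x.sample_rate)
    padlen = min(3 * len(taps), x.n_samples - 1)
    y = sps.filtfilt(taps, [1.0], x.samples, axis=-1, padlen=padlen)
    return TimeSeries(y, x.sample_rate, x.start_time)


def windowed_rms(x: TimeSeries, t_start: float, t_end: float) -> float:
    """RMS amplitude of ``x`` over the half-open window ``[t_start, t_end)``."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if t_start < x.start_time - 0.5 / x.sample_rate or t_end > x.end_time + 0.5 / x.sample_rate:
        raise ValueError(
            f"window [{t_start}, {t_end}) outside series extent "
            f"[{x.start_time}, {x.end_time})"
        )
    seg = x.slice(t_start, t_end)
    return float(np.sqrt(np.mean(np.square(seg.samples))))


def get_window(name: str, n: int) -> np.ndarray:
    if name == "kaiser":
        return sps.windows.kaiser(n, np.pi * KAISER_ALPHA)
    return sps.get_window(name, n)


def stft(
    x: TimeSeries,
    window_length: float = 0.4,
    window: str = "kaiser",
    hop: float = 0.01,
    zero_pad: int = 4,
) -> STFTResult:
    """Short-time Fourier transform with per-frame locality.

    Each frame is an explicit slice of ``window_length`` seconds of data
    centred on the frame time; the FFT of the windowed slice is phase-rotated
    so that the argument of a coefficient is the instantaneous phase of the
    corresponding cosine *at the frame centre*.  Frames whose window would
    extend past the data are marked invalid (``valid[j] = False``) and their
    coefficients set to NaN — never padded.

    Parameters
    ----------
    window_length : float
        Analysis window in seconds (default 400 ms).
    window : str
        Window shape; ``"kaiser"`` (α = 1) by default.
    hop : float
        Frame step in seconds (default 10 ms); must be positive.
    zero_pad : int
        FFT length multiplier for frequency interpolation (default 4).
    """
    if hop <= 0:
        raise ValueError("hop must be positive")
    n_win = int(round(window_length * x.sample_rate))
    if n_win > x.n_samples:
        raise ValueError("window_length exceeds series length")
    if n_win < 2:
        raise ValueError("window too short for the sample rate")
    w = get_window(window, n_win)
    nfft = int(zero_pad) * n_win
    freqs = np.fft.rfftfreq(nfft, d=1.0 / x.sample_rate)

    hop_n = max(int(round(hop * x.sample_rate)), 1)
    starts = np.arange(0, x.n_samples - n_win + 1, hop_n)
    # frame centre: midpoint of the n_win samples
    centre_offset = (n_win - 1) / 2.0 / x.sample_rate
    times = x.start_time + starts / x.sample_rate + centre_offset

    coeffs = np.empty((len(starts), len(freqs)), dtype=complex)
    # phase reference at frame centre: rotate FFT phase forward by the
    # centre offset so arg(coeff) is the cosine phase at the frame centre
    rot = np.exp(2j * np.pi * freqs * centre_offset)
    for j, s in enumerate(starts):
        seg = x.samples[s : s + n_win] * w
        coeffs[j] = np.fft.rfft(seg, n=nfft) * rot
    # normalise so a unit cosine in-band has |coeff| ~ 1
    coeffs *= 2.0 / w.sum()
    return STFTResult(
        times=times,
        frequencies=freqs,
        coefficients=coeffs,
        window_length=window_length,
        window=window,
        valid=np.ones(len(starts), dtype=bool),
    )


def stft_frames(
    x: TimeSeries,
    centres: np.ndarray,
    window_length: float = 0.4,
    window: str = "kaiser",
    zero_pad: int = 4,
) -> STFTResult:
    """STFT coefficients at explicitly requested frame-centre times.

    Same per-frame computation as :func:`stft`, but the caller chooses the
    frame centres.  Frames whose window would extend past the data are
    marked invalid and filled with NaN (never padded), preserving locality.
    """
    centres = np.atleast_1d(np.asarray(centres, dtype=float))
    n_win = int(round(window_length * x.sample_rate))
    if n_win < 2:
        raise ValueError("window too short for the sample rate")
    w = get_window(window, n_win)
    nfft = int(zero_pad) * n_win
    freqs = np.fft.rfftfreq(nfft, d=1.0 / x.sample_rate)
    centre_offset = (n_win - 1) / 2.0 / x.sample_rate
    rot = np.exp(2j * np.pi * freqs * centre_offset)

    coeffs = np.full((len(centres), len(freqs)), np.nan, dtype=complex)
    valid = np.zeros(len(centres), dtype=bool)
    actual = np.array(centres, dtype=float)
    for j, t in enumerate(centres):
        s = int(round((t - centre_offset - x.start_time) * x.sample_rate))
        if s < 0 or s + n_win > x.n_samples:
            continue
        seg = x.samples[s : s + n_win] * w
        coeffs[j] = np.fft.rfft(seg, n=nfft) * rot
        valid[j] = True
        actual[j] = x.start_time + s / x.sample_rate + centre_offset
    coeffs *= 2.0 / w.sum()
    return STFTResult(
        times=actual,
        frequencies=freqs,
        coefficients=coeffs,
        window_length=window_length,
        window=window,
        valid=valid,
    )


def band_power(x: TimeSeries, low: float, high: float) -> float:
    """Mean spectral power of ``x`` in ``[low, high]`` Hz (periodogram)."""
    f, p = sps.periodogram(x.samples, fs=x.sample_rate)
    sel = (f >= low) & (f <= high)
    if not np.any(sel):
        raise ValueError("band contains no frequency bins at this length")
    return float(np.mean(p[sel]))
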