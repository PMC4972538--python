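"""Circular statistics for theta-phase analysis.

Implements the small set of directional statistics the phase analyses need:
the mean resultant length R (the modulus of the average unit phasor), the
Rayleigh test for non-uniformity, the Fisher–Lee circular–circular
correlation, and a circular–linear correlation for phase precession.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_phase",
    "mean_resultant_length",
    "circular_mean",
    "rayleigh_test",
    "fisher_lee_correlation",
    "circ_linear_correlation",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (−π, π]."""
    phi = np.asarray(phi, dtype=float)
    return np.pi - np.mod(np.pi - phi, 2 * np.pi)


def mean_resultant_length(phases: np.ndarray, weights: np.ndarray | None = None) -> float:
    """R = |mean of unit phasors| ∈ [0, 1].

    With ``weights`` (e.g. theta amplitudes) the phasor average is weighted;
    the default is the unweighted estimator.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    z = np.exp(1j * phases)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        return float(np.abs(np.sum(weights * z) / np.sum(weights)))
    return float(np.abs(np.mean(z)))


def circular_mean(phases: np.ndarray) -> float:
    """Mean direction, in (−π, π]."""
    phases = np.asarray(phases, dtype=float)
    return float(np.angle(np.mean(np.exp(1j * phases))))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for circular non-uniformity.

    Returns ``(R, p)``.  Uses the standard finite-sample approximation
    p = exp(sqrt(1 + 4n + 4(n² − Rn²)) − (1 + 2n)) where Rn = n·R, accurate
    to ~1e-3 for n ≥ 10 and conservative below.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least two phases")
    r = mean_resultant_length(phases)
    rn = n * r
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - rn**2)) - (1 + 2 * n))
    return r, float(min(p, 1.0))


def fisher_lee_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher–Lee circular–circular correlation coefficient.

    ρ = Σ_{i<j} sin(aᵢ−aⱼ) sin(bᵢ−bⱼ)
        / sqrt(Σ_{i<j} sin²(aᵢ−aⱼ) · Σ_{i<j} sin²(bᵢ−bⱼ)),

    which is 1 when b = a + const and −1 when b = −a + const.  O(n²) in the
    number of trials, fine at session scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three phase pairs")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    iu = np.triu_indices(a.size, k=1)
    num = np.sum(da[iu] * db[iu])
    den = np.sqrt(np.sum(da[iu] ** 2) * np.sum(db[iu] ** 2))
    if den == 0:
        return 0.0
    return float(num / den)


def circ_linear_correlation(x: np.ndarray, phi: np.ndarray) -> tuple[float, float]:
    """Mardia's correlation between a linear variable and an angle.

    Returns ``(r, slope_sign)`` where r ∈ [0, 1] and ``slope_sign`` is the
    sign of the fitted phase-vs-x trend (−1 for precession: phase decreases
    as x advances).  The sign comes from a resultant-maximising linear fit
    φ ≈ 2π·s·x + φ₀ over a slope grid.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if x.size != phi.size or x.size < 4:
        raise ValueError("need at least four (x, phase) pairs")
    rxc = np.corrcoef(x, np.cos(phi))[0, 1]
    rxs = np.corrcoef(x, np.sin(phi))[0, 1]
    rcs = np.corrcoef(np.cos(phi), np.sin(phi))[0, 1]
    r2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2)
    r = float(np.sqrt(max(r2, 0.0)))

    span = np.ptp(x)
    if span == 0:
        return r, 0.0
    # up to ±2 cycles of phase change across the x range
    slopes = np.linspace(-2.0 / span, 2.0 / span, 401)
    resultants = [
        np.abs(np.mean(np.exp(1j * (phi - 2 * np.pi * s * x)))) for s in slopes
    ]
    best = slopes[int(np.argmax(resultants))]
    return r, float(np.sign(best))
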