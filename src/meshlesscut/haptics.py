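"""Haptic force-feedback modelling.

Biomechanical cutting forces do not decay monotonically: they vibrate
around a trend as tissue repeatedly accumulates and releases energy.  The
computed elastic force is therefore modulated by a decaying oscillation
Gamma(t, d) = exp(-a t) sin(b t) * Upsilon(d) with a linear depth gain
Upsilon(d) = k d.  A printed double-Gaussian fit of measured porcine-liver
cutting force versus blade displacement serves as the empirical reference
curve, and RMSE is the error measure between force series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError


@dataclass
class OscillationParams:
    """Decay rate a (1/s), angular frequency b (rad/s), depth gain k (N/mm)."""

    a: float = 1.0
    b: float = 2.0 * np.pi
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise InvalidParameterError("decay rate a must be >= 0")
        if self.b <= 0:
            raise InvalidParameterError("angular frequency b must be > 0")
        if self.k < 0:
            raise InvalidParameterError("depth gain k must be >= 0")


@dataclass
class ForceFitCoeffs:
    """Double-Gaussian cutting-force fit coefficients (empirical defaults
    from a porcine-liver cutting experiment)."""

    a1: float = 15.29
    b1: float = 3.164
    c1: float = 0.2933
    a2: float = 27.69
    b2: float = 3.288
    c2: float = 1.746

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise InvalidParameterError("Gaussian widths c1, c2 must be > 0")


def oscillation(t, d, p: OscillationParams):
    """Gamma(t, d) = exp(-a t) sin(b t) * k d; |Gamma| <= exp(-a t) k d."""
    t = np.asarray(t, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    out = np.exp(-p.a * t) * np.sin(p.b * t) * (p.k * d)
    return out if out.ndim else float(out)


def feedback_force(i: int, forces: np.ndarray, gamma: float) -> np.ndarray:
    """Modulated feedback force for point i: the accumulated pairwise force
    f_i scaled by the oscillation value Gamma(t, d)."""
    return np.asarray(forces, dtype=np.float64)[i] * float(gamma)


def empirical_force(x, coeffs: ForceFitCoeffs = None):
    """Fitted cutting force f(x) = a1 e^{-((x-b1)/c1)^2} + a2 e^{-((x-b2)/c2)^2}
    as a function of blade displacement x (mm)."""
    if coeffs is None:
        coeffs = ForceFitCoeffs()
    x = np.asarray(x, dtype=np.float64)
    out = (coeffs.a1 * np.exp(-(((x - coeffs.b1) / coeffs.c1) ** 2)) +
           coeffs.a2 * np.exp(-(((x - coeffs.b2) / coeffs.c2) ** 2)))
    return out if out.ndim else float(out)


def rmse(f, f_star) -> float:
    """Root-mean-square error sqrt(sum (f_i - f*_i)^2 / N)."""
    f = np.asarray(f, dtype=np.float64)
    f_star = np.asarray(f_star, dtype=np.float64)
    if f.shape != f_star.shape or f.size == 0:
        raise InvalidInputError("series must be non-empty and equal length")
    return float(np.sqrt(np.mean((f - f_star) ** 2)))


def peak_amplitudes(series: np.ndarray) -> np.ndarray:
    """Local maxima of |series| (strictly greater than both neighbors);
    used to check the decaying-envelope property of modulated force series."""
    s = np.abs(np.asarray(series, dtype=np.float64))
    if len(s) < 3:
        return np.empty(0)
    mid = s[1:-1]
    peaks = (mid > s[:-2]) & (mid > s[2:])
    return mid[peaks]
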