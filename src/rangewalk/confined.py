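"""Analytic MSD of a persistent walker inside a fixed rectangular territory.

The walker runs at speed ``v`` and keeps its direction for an exponential
time of mean ``T`` (telegrapher memory phi(t) = (v²/D) e^{-t/T} with
D = v²T).  Inside a territory of widths (λx, λy) with reflecting edges and
a uniform start, the MSD along each axis is an eigenmode series

    MSD_z(t) = λz² { 1/6 - (16/π⁴) Σ_n m^{-4}
                     [cos(Θ_m t) + sin(Θ_m t)/(2TΘ_m)] e^{-t/2T} },

over odd mode numbers m = 2n-1, with Θ_m = (2T)^{-1} sqrt(4 m²π²ζz² - 1)
and ζz = vT/λz the relative persistence.  When the radicand is negative
Θ_m is imaginary and the cos/sin pair continues analytically to cosh/sinh;
the lowest mode turns oscillatory — and humps appear in the MSD — exactly
when ζz exceeds 1/(2π).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

__all__ = [
    "ConfinedWalkerParams",
    "confined_msd",
    "confined_msd_axis",
    "oscillation_threshold",
    "effective_persistence",
    "ArenaPersistence",
]


@dataclass
class ConfinedWalkerParams:
    """Persistent walker in a rectangular territory.

    v : speed (length/time);  T : mean persistence time;
    lambda_x, lambda_y : territory widths (lambda_y=None for 1d).
    """

    v: float
    T: float
    lambda_x: float
    lambda_y: float | None = None

    def __post_init__(self):
        if self.v <= 0 or self.T <= 0 or self.lambda_x <= 0:
            raise ValueError("v, T and lambda_x must be positive")
        if self.lambda_y is not None and self.lambda_y <= 0:
            raise ValueError("lambda_y must be positive")

    @property
    def D(self) -> float:
        """Diffusivity consistent with the exponential memory: D = v²T."""
        return self.v**2 * self.T

    def zeta(self, width: float) -> float:
        return self.v * self.T / width

    @property
    def widths(self) -> tuple[float, ...]:
        if self.lambda_y is None:
            return (self.lambda_x,)
        return (self.lambda_x, self.lambda_y)


def oscillation_threshold() -> float:
    """Critical ζ above which the slowest MSD mode is oscillatory: 1/(2π)."""
    return 1.0 / (2.0 * np.pi)


def _mode_factor(m: int, zeta: float, t: np.ndarray, T: float) -> np.ndarray:
    """e^{-t/2T} [cos(Θ_m t) + sin(Θ_m t)/(2TΘ_m)], continued analytically.

    Written in overflow-safe form: in the cosh/sinh regime the product with
    e^{-t/2T} is assembled from decaying exponentials only.
    """
    radicand = 4.0 * m * m * np.pi * np.pi * zeta * zeta - 1.0
    if radicand > 0:
        theta = np.sqrt(radicand) / (2.0 * T)
        return np.exp(-t / (2 * T)) * (
            np.cos(theta * t) + np.sin(theta * t) / (2.0 * T * theta))
    if radicand == 0:
        return np.exp(-t / (2 * T)) * (1.0 + t / (2.0 * T))
    mu = np.sqrt(-radicand) / (2.0 * T)        # mu < 1/(2T): net decay
    ep = np.exp((mu - 0.5 / T) * t)
    em = np.exp(-(mu + 0.5 / T) * t)
    return 0.5 * (ep + em) + 0.5 * (ep - em) / (2.0 * T * mu)


def confined_msd_axis(width: float, v: float, T: float, t,
                      rtol: float = 1e-12, max_terms: int = 100_000) -> np.ndarray:
    """Single-axis MSD series; ``t`` may be scalar or array (time units of T)."""
    if width <= 0:
        raise ValueError("territory width must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    zeta = v * T / width
    total = np.zeros_like(t)
    for n in range(1, max_terms + 1):
        m = 2 * n - 1
        coeff = 1.0 / m**4
        total += coeff * _mode_factor(m, zeta, t, T)
        # amplitude envelope: remaining tail of sum m^{-4} is < coeff/3
        if coeff < rtol * (np.pi**4 / 96.0):
            break
    msd = width**2 * (1.0 / 6.0 - (16.0 / np.pi**4) * total)
    return msd


def confined_msd(params: ConfinedWalkerParams, t,
                 rtol: float = 1e-12) -> np.ndarray:
    """Total MSD (sum over axes) of the confined persistent walker.

    At t=0 the series sums to zero displacement; at long times it plateaus
    at (λx² + λy²)/6 (uniform stationary occupation).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for width in params.widths:
        out += confined_msd_axis(width, params.v, params.T, t_arr, rtol=rtol)
    return out if np.ndim(t) else float(out[0])


@dataclass
class ArenaPersistence:
    """Effective persistence of a correlated walk in a circular arena."""

    mean_step: float
    radius: float
    mean_cos: float
    xi: float


def effective_persistence(mean_step: float, radius: float,
                          mean_cos: float) -> ArenaPersistence:
    """ξ = -ℒ / [R ln(<cos θ>)].

    ξ = 0 for a uniform turning-angle distribution (<cos θ> = 0, Brownian)
    and ξ → +∞ in the ballistic limit <cos θ> → 1 (returned as inf, not an
    error).  Negative <cos θ> (anti-persistent) is accepted via |ln|.
    """
    if mean_step <= 0 or radius <= 0:
        raise ValueError("mean_step and radius must be positive")
    if mean_cos >= 1.0:
        xi = np.inf
    elif mean_cos == 0.0:
        xi = 0.0
    else:
        xi = -mean_step / (radius * np.log(abs(mean_cos)))
    return ArenaPersistence(mean_step=mean_step, radius=radius,
                            mean_cos=mean_cos, xi=float(xi))
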