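"""Confining potentials and their Boltzmann steady states.

A home range is modelled as the stationary state of an overdamped walker
tethered to a burrow/den by a confining potential.  Only the dimensionless
ratio ``U(x)/D`` matters for the stationary density, which is proportional
to ``exp(-U(x)/D)``; the diffusivity ``D`` enters separately only in the
dynamical modules.  Each built-in family carries an intrinsic length scale
``L`` that sets the spatial extent of the home range.

The intrinsic home-range length functional is

    L_hr = sqrt( 2 * <x^2>_half ),   <x^2>_half = E[x^2] over x >= 0

under the Boltzmann weight, which for the harmonic family ``U/D = x^2/L^2``
returns exactly ``L``.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from typing import Callable

from scipy.integrate import quad
from scipy.special import erf

__all__ = [
    "Potential",
    "HarmonicPotential",
    "LogarithmicPotential",
    "BoxErfPotential",
    "HardBoxPotential",
    "MultiHarmonicPotential",
    "TabulatedPotential",
    "CustomPotential",
    "make_potential",
    "Density1D",
    "boltzmann_density",
    "self_convolution",
    "home_range_length",
    "home_range_length_kspace",
]


class NormalizationError(ValueError):
    """The Boltzmann weight exp(-U/D) is not integrable."""


class DivergentMomentError(ValueError):
    """A required moment of exp(-U/D) diverges."""


@dataclass
class Potential:
    """A dimensionless confining potential ``U(x)/D``.

    Parameters
    ----------
    length_scale : float
        Intrinsic length ``L`` of the family, in user length units.

    Subclasses implement :meth:`u_over_d` (vectorised, even in ``x``) and
    may restrict ``support`` to a finite interval (hard walls).
    """

    length_scale: float = 1.0
    family: str = field(default="custom", init=False)
    #: finite support (half-width) or None for the whole line
    support: float | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        if not self.length_scale > 0:
            raise ValueError("length_scale must be positive")

    def u_over_d(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def boltzmann_weight(self, x):
        """exp(-U(x)/D), zero outside a finite support."""
        x = np.asarray(x, dtype=float)
        w = np.exp(-self.u_over_d(x))
        if self.support is not None:
            w = np.where(np.abs(x) <= self.support, w, 0.0)
        return w

    # -- quadrature helpers -------------------------------------------------
    def _upper(self) -> float:
        return self.support if self.support is not None else np.inf

    def _weight_integral(self, integrand: Callable[[float], float]) -> float:
        a = self._upper()
        scale = self.length_scale
        if np.isfinite(a):
            val, _ = quad(integrand, 0.0, a, limit=400)
            return val
        # convergence probe: the integral must stop growing as the cutoff
        # quadruples (catches flat potentials and divergent moments); the
        # core is integrated separately so narrow weights stay resolved
        big = 1000.0 * scale
        core, _ = quad(integrand, 0.0, 50.0 * scale, limit=400)
        t1, _ = quad(integrand, 50.0 * scale, big, limit=400)
        t2, _ = quad(integrand, big, 4.0 * big, limit=400)
        v2 = core + t1 + t2
        if (not np.isfinite(v2)
                or abs(t2) > 1e-3 * max(abs(v2), 1e-300)):
            raise NormalizationError(
                "integral of the Boltzmann weight does not converge "
                "(tail does not decay)")
        tail, _ = quad(integrand, 4.0 * big, np.inf, limit=400)
        if not np.isfinite(tail):
            tail = 0.0
        return v2 + tail


class HarmonicPotential(Potential):
    """U(x)/D = x^2 / L^2 — Gaussian home range, variance L^2/2."""

    def __post_init__(self):
        super().__post_init__()
        self.family = "harmonic"

    def u_over_d(self, x):
        x = np.asarray(x, dtype=float)
        return (x / self.length_scale) ** 2


class LogarithmicPotential(Potential):
    """U(x)/D = ln(1 + x^2/L^2) — Cauchy (heavy-tailed) home range.

    This is the form whose windowed steady-state MSD is the arctan closed
    form used by the saturation-curve inversion.  Its second moment
    diverges, so the intrinsic length functional is undefined for it.
    """

    def __post_init__(self):
        super().__post_init__()
        self.family = "logarithmic"

    def u_over_d(self, x):
        x = np.asarray(x, dtype=float)
        return np.log1p((x / self.length_scale) ** 2)


class BoxErfPotential(Potential):
    """Smoothed-box potential: exp(-U/D) is an erf-regularised box profile.

    ``exp(-U(x)/D) ∝ erf[a (x/L + 1/2)] - erf[a (x/L - 1/2)]`` with
    ``a = sqrt(6π/11)``, i.e. a box of width ``L`` convolved with a
    Gaussian of width ``L/(a√2)``.
    """

    _A = np.sqrt(6.0 * np.pi / 11.0)

    def __post_init__(self):
        super().__post_init__()
        self.family = "box_erf"

    def boltzmann_weight(self, x):
        x = np.asarray(x, dtype=float) / self.length_scale
        w = 0.5 * (erf(self._A * (x + 0.5)) - erf(self._A * (x - 0.5)))
        return np.maximum(w, 0.0)

    def u_over_d(self, x):
        w = BoxErfPotential.boltzmann_weight(self, x)
        with np.errstate(divide="ignore"):
            return -np.log(w)


class HardBoxPotential(Potential):
    """U = 0 on (-a/2, a/2), infinite outside; ``length_scale`` is ``a``."""

    def __post_init__(self):
        super().__post_init__()
        self.family = "hard_box"
        self.support = 0.5 * self.length_scale

    def u_over_d(self, x):
        x = np.asarray(x, dtype=float)
        return np.where(np.abs(x) <= self.support, 0.0, np.inf)


@dataclass
class MultiHarmonicPotential(Potential):
    """Two harmonic regimes with different strengths (C1-matched).

    ``U/D = x^2/L^2`` for ``|x| <= r0`` and a quadratic of curvature
    ``outer_ratio / L^2`` matched in value and slope at ``r0`` beyond.
    A reconstruction of a two-stiffness home range (steeper or softer far
    from the burrow); not a unique functional form.
    """

    crossover: float = 1.0          # r0, in units of length_scale
    outer_ratio: float = 4.0        # outer curvature / inner curvature

    def __post_init__(self):
        super().__post_init__()
        if self.crossover <= 0 or self.outer_ratio <= 0:
            raise ValueError("crossover and outer_ratio must be positive")
        self.family = "multi_harmonic"

    def u_over_d(self, x):
        L = self.length_scale
        r0 = self.crossover * L
        k1 = 1.0 / L**2
        k2 = self.outer_ratio * k1
        ax = np.abs(np.asarray(x, dtype=float))
        inner = k1 * ax**2
        # value + slope continuity at r0
        outer = k1 * r0**2 + 2 * k1 * r0 * (ax - r0) + k2 * (ax - r0) ** 2
        return np.where(ax <= r0, inner, outer)


class TabulatedPotential(Potential):
    """Potential given as (offset, U/D) pairs; linear interpolation inside
    the tabulated range, quadratic growth matched at the last point outside.
    """

    def __init__(self, offsets, values):
        offsets = np.asarray(offsets, dtype=float)
        values = np.asarray(values, dtype=float)
        if offsets.ndim != 1 or offsets.shape != values.shape or offsets.size < 3:
            raise ValueError("need >= 3 (offset, U/D) pairs of equal length")
        order = np.argsort(offsets)
        self._x = offsets[order]
        self._u = values[order]
        xmax = float(np.max(np.abs(self._x)))
        super().__init__(length_scale=xmax if xmax > 0 else 1.0)
        self.family = "custom"
        # quadratic extrapolation coefficient, value-matched at the edge
        edge = self._u[-1]
        self._c = edge / xmax**2 if edge > 0 else 1.0 / xmax**2

    def u_over_d(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.interp(x, self._x, self._u)
        xmax = float(np.max(np.abs(self._x)))
        return np.where(np.abs(x) <= xmax, inside, self._c * x**2)

    @classmethod
    def from_text(cls, path) -> "TabulatedPotential":
        arr = np.loadtxt(path)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected two-column text: offset, U/D")
        return cls(arr[:, 0], arr[:, 1])


class CustomPotential(Potential):
    """Wrap an arbitrary even callable U(x)/D."""

    def __init__(self, func: Callable, length_scale: float = 1.0):
        self._func = func
        super().__init__(length_scale=length_scale)
        self.family = "custom"

    def u_over_d(self, x):
        return np.asarray(self._func(np.asarray(x, dtype=float)), dtype=float)


_FAMILIES = {
    "harmonic": HarmonicPotential,
    "logarithmic": LogarithmicPotential,
    "box_erf": BoxErfPotential,
    "hard_box": HardBoxPotential,
    "multi_harmonic": MultiHarmonicPotential,
}


def make_potential(family: str, length_scale: float, **extra) -> Potential:
    """Build a built-in potential by family name."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    return cls(length_scale=length_scale, **extra)


@dataclass
class Density1D:
    """A normalised 1d probability density sampled on a grid."""

    x: np.ndarray
    pdf: np.ndarray

    def __call__(self, xq):
        return np.interp(np.asarray(xq, dtype=float), self.x, self.pdf,
                         left=0.0, right=0.0)

    def integral(self) -> float:
        return float(np.trapezoid(self.pdf, self.x))

    def variance(self) -> float:
        m = np.trapezoid(self.x * self.pdf, self.x)
        return float(np.trapezoid((self.x - m) ** 2 * self.pdf, self.x))


def _grid_halfwidth(potential: Potential) -> float:
    """Half-width beyond which exp(-U/D) is negligible."""
    if potential.support is not None:
        return potential.support
    L = potential.length_scale
    h = 5.0 * L
    w0 = float(potential.boltzmann_weight(0.0))
    for _ in range(60):
        if float(potential.boltzmann_weight(h)) < 1e-14 * w0:
            return h
        h *= 1.6
    raise NormalizationError(
        "exp(-U/D) does not decay within 5e12 length scales; "
        "normalization integral diverges")


def boltzmann_density(potential: Potential, centre: float = 0.0,
                      n_grid: int = 4001) -> Density1D:
    """Stationary density ∝ exp(-U(x - centre)/D), normalised on a grid.

    Raises
    ------
    NormalizationError
        if the Boltzmann weight is not integrable (e.g. a flat potential
        on the infinite line).
    """
    h = _grid_halfwidth(potential)
    L = potential.length_scale
    if h <= 40.0 * L:
        x = np.linspace(-h, h, n_grid)
    else:
        # heavy tails: dense core plus geometric tails so the peak stays
        # resolved even when the weight decays over many length scales
        n_core = int(0.8 * n_grid) | 1
        n_tail = (n_grid - n_core) // 2
        core = np.linspace(-20.0 * L, 20.0 * L, n_core)
        tail = np.geomspace(20.0 * L, h, n_tail + 1)[1:]
        x = np.unique(np.concatenate([-tail[::-1], core, tail]))
    w = potential.boltzmann_weight(x)
    norm = np.trapezoid(w, x)
    if not np.isfinite(norm) or norm <= 0:
        raise NormalizationError("non-finite normalization integral")
    return Density1D(x=x + centre, pdf=w / norm)


def self_convolution(potential: Potential) -> Callable:
    """Return f(y) = ∫ dz exp{-[U(z) + U(z-y)]/D}  (even in y).

    For finite-support potentials the integral is truncated to the
    overlap of the two supports.
    """

    weight = potential.boltzmann_weight
    a = potential._upper()

    def f(y):
        y = float(y)
        if np.isfinite(a):
            lo, hi = max(-a, y - a), min(a, y + a)
            if hi <= lo:
                return 0.0
            val, err = quad(lambda z: float(weight(z) * weight(z - y)),
                            lo, hi, limit=400)
        else:
            # split at the likely peaks so narrow weights are resolved
            brk = sorted({0.0, 0.5 * y, y})
            g = lambda z: float(weight(z) * weight(z - y))
            val = 0.0
            val += quad(g, -np.inf, brk[0], limit=400)[0]
            for a_, b_ in zip(brk[:-1], brk[1:]):
                val += quad(g, a_, b_, limit=400)[0]
            val += quad(g, brk[-1], np.inf, limit=400)[0]
        if not np.isfinite(val):
            raise NormalizationError(
                f"self-convolution quadrature diverged at offset y={y}")
        return val

    return f


def _half_line_moment(potential: Potential, power: int) -> float:
    weight = potential.boltzmann_weight
    return potential._weight_integral(lambda x: float(weight(x)) * x**power)


def home_range_length(potential: Potential) -> float:
    """Intrinsic home-range length  L = sqrt(2 ∫x² w dx / ∫ w dx)  (x ≥ 0).

    Equals the stored ``length_scale`` for the harmonic family and
    ``a/sqrt(6)`` for a hard box of width ``a``.

    Raises
    ------
    DivergentMomentError
        when the second moment of exp(-U/D) diverges (heavy tails).
    """
    norm = _half_line_moment(potential, 0)
    try:
        m2 = _half_line_moment(potential, 2)
    except NormalizationError as exc:
        raise DivergentMomentError(
            "second moment of exp(-U/D) diverges "
            f"(tail of family {potential.family!r} too heavy)") from exc
    # heavy-tail guard: the x^2-weighted integrand must itself decay
    if potential.support is None:
        L = potential.length_scale
        w = potential.boltzmann_weight
        t1 = float(w(100 * L)) * (100 * L) ** 2
        t2 = float(w(1000 * L)) * (1000 * L) ** 2
        if t2 > 1e-12 * m2 and t2 >= 0.5 * t1:
            raise DivergentMomentError(
                f"second moment of exp(-U/D) diverges for family "
                f"{potential.family!r}: x^2 exp(-U/D) does not decay")
    return float(np.sqrt(2.0 * m2 / norm))


def home_range_length_kspace(potential: Potential, dk: float | None = None) -> float:
    """Reciprocal-space twin of :func:`home_range_length`.

    Evaluates L = sqrt(-2 [P''(k)/P(k)]_{k=0}) with P(k) the Fourier
    transform of exp(-U/D), via a central finite difference in k.
    """
    if dk is None:
        dk = 1e-3 / potential.length_scale
    weight = potential.boltzmann_weight
    a = potential._upper()
    hi = a if np.isfinite(a) else _grid_halfwidth(potential)

    def phat(k):
        val, _ = quad(lambda x: float(weight(x)) * np.cos(k * x),
                      0.0, hi, limit=400)
        return 2.0 * val

    p0 = phat(0.0)
    d2 = (phat(dk) - 2.0 * p0 + phat(-dk)) / dk**2
    val = -2.0 * d2 / p0
    if val <= 0:
        raise DivergentMomentError("non-positive curvature at k=0")
    return float(np.sqrt(val))
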