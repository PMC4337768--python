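"""Home-range size from the saturation of mark-recapture MSD.

When relocations are collected inside a finite trapping window of side
``G``, the steady-state mean-square displacement between capture and
recapture saturates at a value controlled jointly by the window and by the
intrinsic home-range length ``L`` of the confining potential.  With burrow
centres uniformly scattered, the saturation MSD in 1d is

    <Δx²>_ss = ∫₀^G y² (G - y) f(y) dy / ∫₀^G (G - y) f(y) dy ,

where ``f`` is the self-convolution of the Boltzmann weight exp(-U/D).
Normalised by G²/6 it is a monotone sigmoid in ζ = L/G that rises from 0
to 1, so a measured saturation value can be inverted for ζ and hence
L = ζ·G.  Closed forms exist for the harmonic (sinh/erf) and logarithmic
(arctan) families; other families go through quadrature.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .potentials import Potential, make_potential, self_convolution

__all__ = [
    "ObservationWindow",
    "SaturationCurve",
    "HomeRangeEstimate",
    "msd_ss_numeric",
    "msd_ss_nonuniform",
    "msd_ss_harmonic",
    "msd_ss_logarithmic",
    "build_saturation_curve",
    "invert_msd",
    "HomeRangeEstimator",
]


@dataclass
class ObservationWindow:
    """Square or rectangular trapping window centred at the origin."""

    G: float
    dimension: int = 1
    Gy: float | None = None    # rectangular 2d windows

    def __post_init__(self):
        if self.G <= 0:
            raise ValueError("window side G must be positive")
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if self.Gy is not None and self.Gy <= 0:
            raise ValueError("Gy must be positive")

    @property
    def sides(self) -> tuple[float, ...]:
        if self.dimension == 1:
            return (self.G,)
        return (self.G, self.Gy if self.Gy is not None else self.G)

    def contains(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ok = np.ones(xy.shape[0], dtype=bool)
        for axis, side in enumerate(self.sides):
            ok &= np.abs(xy[:, axis]) <= 0.5 * side
        return ok


class SaturationOutOfRangeError(ValueError):
    """Observed normalised saturation outside the open interval (0, 1)."""


def msd_ss_harmonic(zeta) -> np.ndarray:
    """Normalised saturation MSD for the harmonic family (closed form).

    Stable at both ends: the sinh and the exp·erf term share a factor
    e^{1/(4ζ²)} which is cancelled analytically before evaluation.
    """
    z = np.asarray(zeta, dtype=float)
    if np.any(z <= 0):
        raise ValueError("zeta must be positive")
    b = 1.0 / (4.0 * z * z)
    A = 0.5 * (-np.expm1(-2.0 * b))             # e^{-b} sinh(b)
    from scipy.special import erf
    B = (0.5 / z) * np.sqrt(np.pi / 2.0) * erf(1.0 / (np.sqrt(2.0) * z))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 6.0 * z * z * (1.0 + A / (A - B))
    # far plateau: direct evaluation cancels catastrophically; large-ζ
    # series  1 - (7/15)b + (44/315)b²  with b = 1/(4ζ²)
    b_ = 1.0 / (4.0 * z * z)
    out = np.where(z > 30.0,
                   1.0 - (7.0 / 15.0) * b_ + (44.0 / 315.0) * b_ * b_, out)
    return out if out.ndim else float(out)


def msd_ss_logarithmic(zeta) -> np.ndarray:
    """Normalised saturation MSD for the logarithmic (Cauchy) family."""
    z = np.asarray(zeta, dtype=float)
    if np.any(z <= 0):
        raise ValueError("zeta must be positive")
    den = np.arctan(0.5 / z) - z * np.log1p(0.25 / (z * z))
    out = 6.0 * (z / den - 4.0 * z * z)
    return out if out.ndim else float(out)


def msd_ss_numeric(potential: Potential, window: ObservationWindow,
                   potential_y: Potential | None = None) -> float:
    """Steady-state mark-recapture MSD (m²) by quadrature.

    1d: the single-axis value.  2d: sum of per-axis values; a different
    potential may act along y (separable potentials only).
    """
    axes = window.sides
    pots = [potential, potential_y if potential_y is not None else potential]
    total = 0.0
    for side, pot in zip(axes, pots):
        total += _msd_axis(pot, side)
    return total


def _msd_axis(potential: Potential, G: float) -> float:
    f = self_convolution(potential)
    scale = min(potential.length_scale, G)
    pts = sorted({min(scale, G), min(5 * scale, G)})
    num, _ = quad(lambda y: y * y * (G - y) * f(y), 0.0, G,
                  limit=400, points=pts)
    den, _ = quad(lambda y: (G - y) * f(y), 0.0, G, limit=400, points=pts)
    if den <= 0 or not np.isfinite(num / den):
        raise ArithmeticError("saturation-MSD quadrature failed")
    return num / den


def msd_ss_nonuniform(potential: Potential, window: ObservationWindow,
                      burrow_density, half_range: float | None = None) -> float:
    """Steady-state windowed MSD with a non-uniform burrow density
    (1d, direct triple quadrature).  Experimental: the inversion sigmoid
    assumes uniform burrows; use this only to gauge the effect of known
    non-uniformity.

    ``burrow_density(xc)`` need not be normalised.
    """
    from scipy.integrate import tplquad

    if window.dimension != 1:
        raise ValueError("non-uniform burrow density is 1d-only")
    G = window.G
    w = potential.boltzmann_weight
    if half_range is None:
        half_range = 0.5 * G + 10.0 * potential.length_scale

    def num(x, x0, xc):
        return (x - x0) ** 2 * burrow_density(xc) * float(w(x0 - xc) * w(x - xc))

    def den(x, x0, xc):
        return burrow_density(xc) * float(w(x0 - xc) * w(x - xc))

    a, b = -half_range, half_range
    kw = dict(epsabs=1e-10, epsrel=1e-8)
    n_val, _ = tplquad(num, a, b, -G / 2, G / 2, -G / 2, G / 2, **kw)
    d_val, _ = tplquad(den, a, b, -G / 2, G / 2, -G / 2, G / 2, **kw)
    if d_val <= 0:
        raise ArithmeticError("non-uniform quadrature failed")
    return n_val / d_val


def _normalizer(window: ObservationWindow) -> float:
    """Normalisation making the flat-potential limit equal 1."""
    return sum(s * s / 6.0 for s in window.sides)


_CLOSED_FORMS = {"harmonic": msd_ss_harmonic, "logarithmic": msd_ss_logarithmic}


@dataclass
class SaturationCurve:
    """Normalised saturation MSD versus ζ = L/G for one potential family."""

    zeta: np.ndarray
    msd_norm: np.ndarray
    family: str

    def __post_init__(self):
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.msd_norm = np.asarray(self.msd_norm, dtype=float)
        # monotone up to float roundoff near the saturated plateau
        if self.zeta.size > 1 and np.any(np.diff(self.msd_norm) < -1e-12):
            raise ArithmeticError(
                "computed saturation curve is not strictly increasing; "
                "quadrature failure for family " + self.family)

    def __call__(self, zeta):
        if self.family in _CLOSED_FORMS:
            return _CLOSED_FORMS[self.family](zeta)
        interp = PchipInterpolator(np.log(self.zeta), self.msd_norm)
        return interp(np.log(np.asarray(zeta, dtype=float)))

    def invert(self, value: float, lo: float = 1e-3, hi: float = 1e3) -> float:
        """Root-find ζ with curve(ζ) = value (bisection in log ζ)."""
        if not 0.0 < value < 1.0:
            raise SaturationOutOfRangeError(
                f"normalised saturation {value} outside (0, 1): "
                "saturation exceeds flat-potential bound" if value >= 1.0
                else f"normalised saturation {value} outside (0, 1)")
        g = lambda u: float(self(np.exp(u))) - value
        a, b = np.log(lo), np.log(hi)
        ga, gb = g(a), g(b)
        # widen if the value sits outside the tabulated range
        while ga > 0 and a > np.log(1e-8):
            a -= 2.0
            ga = g(a)
        while gb < 0 and b < np.log(1e8):
            b += 2.0
            gb = g(b)
        if ga > 0 or gb < 0:
            raise SaturationOutOfRangeError(
                f"no ζ in [{np.exp(a):g}, {np.exp(b):g}] reaches {value}")
        return float(np.exp(brentq(g, a, b, xtol=1e-10, rtol=1e-12)))


def build_saturation_curve(family: str, zeta_grid,
                           **potential_extra) -> SaturationCurve:
    """Tabulate the normalised saturation sigmoid on a ζ grid.

    Closed forms for ``harmonic`` and ``logarithmic``; quadrature through
    the self-convolution pipeline for the other families.
    """
    zeta = np.asarray(zeta_grid, dtype=float)
    if zeta.ndim != 1 or np.any(zeta <= 0):
        raise ValueError("zeta grid must be 1d and positive")
    if np.any(np.diff(zeta) <= 0):
        raise ValueError("zeta grid must be sorted increasing")
    if family in _CLOSED_FORMS:
        vals = np.asarray(_CLOSED_FORMS[family](zeta), dtype=float)
    else:
        window = ObservationWindow(G=1.0, dimension=1)
        vals = np.array([
            _msd_axis(make_potential(family, z, **potential_extra), 1.0) / (1.0 / 6.0)
            for z in zeta])
    return SaturationCurve(zeta=zeta, msd_norm=vals, family=family)


@dataclass
class HomeRangeEstimate:
    """Point estimate and interval for the home-range length L (and ζ)."""

    L: float
    L_lo: float
    L_hi: float
    zeta: float
    zeta_lo: float
    zeta_hi: float
    family: str
    G: float
    msd_observed: float
    msd_err: float

    def as_dict(self) -> dict:
        return {
            "L": self.L, "L_lo": self.L_lo, "L_hi": self.L_hi,
            "zeta": self.zeta, "zeta_lo": self.zeta_lo, "zeta_hi": self.zeta_hi,
            "family": self.family, "G": self.G,
            "msd_observed": self.msd_observed, "msd_err": self.msd_err,
        }


def invert_msd(observed_msd: float, window: ObservationWindow,
               curve: SaturationCurve, err: float = 0.0) -> HomeRangeEstimate:
    """Invert an observed saturation MSD (m², with symmetric error) for L.

    The point estimate and the two ends of ``observed_msd ± err`` are each
    root-found on the monotone sigmoid; the resulting interval in ζ (and in
    L = ζ·G) is asymmetric.
    """
    norm = _normalizer(window)
    v = observed_msd / norm
    z = curve.invert(v)
    z_lo = z_hi = z
    if err > 0:
        v_lo = (observed_msd - err) / norm
        v_hi = (observed_msd + err) / norm
        # error bands may cross the sigmoid's range: clamp to the open ends
        z_lo = curve.invert(v_lo) if v_lo > 0.0 else float(curve.zeta[0])
        z_hi = curve.invert(v_hi) if v_hi < 1.0 else float(curve.zeta[-1])
    G = window.G
    return HomeRangeEstimate(
        L=z * G, L_lo=z_lo * G, L_hi=z_hi * G,
        zeta=z, zeta_lo=z_lo, zeta_hi=z_hi,
        family=curve.family, G=G,
        msd_observed=observed_msd, msd_err=err)


def saturated_msd_from_pairs(pairs) -> tuple[float, tuple[float, float]]:
    """Pooled saturation MSD with a 95% interval from capture pairs.

    ``pairs`` is a DataFrame with columns ``id, dx2`` (squared displacement
    per pair).  All pairs are pooled with equal weight.  Pairs sharing an
    animal are correlated, so the error comes from a delete-one-animal
    jackknife of the pooled mean on the log scale (squared displacements
    are right-skewed), with a Student-t critical value at (animals - 1)
    degrees of freedom.  Returns ``(msd, (msd_lo, msd_hi))``.
    """
    import pandas as pd
    from scipy.stats import t as t_dist

    pairs = pd.DataFrame(pairs)
    d = pairs["dx2"].to_numpy(dtype=float)
    ids = pairs["id"].to_numpy()
    if d.size == 0:
        raise ValueError("no capture-recapture pairs")
    msd = float(d.mean())
    uniq = np.unique(ids)
    g = len(uniq)
    if g < 2:
        return msd, (msd, msd)
    tot, ntot = d.sum(), d.size
    jk = np.array([(tot - d[ids == u].sum()) / (ntot - (ids == u).sum())
                   for u in uniq])
    logjk = np.log(np.maximum(jk, 1e-300))
    se_log = float(np.sqrt((g - 1) / g * np.sum((logjk - logjk.mean()) ** 2)))
    crit = float(t_dist.ppf(0.975, g - 1))
    return msd, (msd * np.exp(-crit * se_log), msd * np.exp(crit * se_log))


class HomeRangeEstimator(BaseEstimator):
    """Estimate home-range length L from relocation fixes (sklearn-style).

    Pools all capture-recapture pairs observed inside the trapping window
    whose time lag exceeds ``stationarity_lag``, computes the saturated
    MSD with a cluster-robust 95% error, and inverts it on the saturation
    sigmoid of the chosen potential family.

    Parameters
    ----------
    G : float
        Side of the (square) observation window, user length units.
    family : str
        Potential family of the saturation curve.
    dimension : int
        1 or 2; fixes are (x,) or (x, y).
    stationarity_lag : float
        Minimum capture-recapture lag for a pair to count as stationary.

    Attributes
    ----------
    L_ : float
        Estimated home-range length.
    interval_ : tuple (L_lo, L_hi)
    zeta_ : float
    estimate_ : HomeRangeEstimate
    """

    def __init__(self, G: float = 1.0, family: str = "harmonic",
                 dimension: int = 2, stationarity_lag: float = 0.0):
        self.G = G
        self.family = family
        self.dimension = dimension
        self.stationarity_lag = stationarity_lag

    def fit(self, X, y=None):
        from .synthetic import mark_recapture_sample
        from .trajstats import TrajectorySet

        traj = X if isinstance(X, TrajectorySet) else TrajectorySet(X)
        window = ObservationWindow(G=self.G, dimension=self.dimension)
        pairs = mark_recapture_sample(traj, window,
                                      stationarity_lag=self.stationarity_lag)
        msd, (msd_lo, msd_hi) = saturated_msd_from_pairs(pairs)
        curve = build_saturation_curve(self.family,
                                       np.geomspace(1e-3, 1e3, 121))
        norm = _normalizer(window)
        z = curve.invert(msd / norm)
        v_lo, v_hi = msd_lo / norm, msd_hi / norm
        z_lo = curve.invert(v_lo) if v_lo > 0 else float(curve.zeta[0])
        z_hi = curve.invert(v_hi) if v_hi < 1 else float(curve.zeta[-1])
        est = HomeRangeEstimate(
            L=z * self.G, L_lo=z_lo * self.G, L_hi=z_hi * self.G,
            zeta=z, zeta_lo=z_lo, zeta_hi=z_hi, family=self.family,
            G=self.G, msd_observed=msd, msd_err=0.5 * (msd_hi - msd_lo))
        self.estimate_ = est
        self.L_ = est.L
        self.interval_ = (est.L_lo, est.L_hi)
        self.zeta_ = est.zeta
        return self

    def predict(self, X=None):
        """Return the fitted home-range length."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "L_")
        return self.L_
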