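"""Estimators operating on relocation trajectories.

Covers the trajectory-level inference toolkit: q-th displacement moments
and multifractal Hurst exponents, steady-state (Boltzmann) potential
fitting, and maximum-likelihood estimation of movement parameters with
bootstrap intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "TrajectorySet",
    "MomentCurve",
    "empirical_moment",
    "hurst_exponent",
    "windowed_gaussian_moment",
    "HurstExponentEstimator",
    "SteadyStatePotentialEstimator",
    "SmoluchowskiMLE",
    "LikelihoodFit",
]

_COLUMNS = ("id", "t", "x", "y")


class TrajectorySet:
    """Time-stamped positions of one or more animals.

    Wraps a DataFrame with columns ``id, t, x, y``; times must be strictly
    increasing per animal with no duplicate (id, t).
    """

    def __init__(self, records):
        df = pd.DataFrame(records)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.loc[:, list(_COLUMNS)].copy()
        for c in ("t", "x", "y"):
            df[c] = pd.to_numeric(df[c], errors="raise")
        df = df.sort_values(["id", "t"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["id", "t"])
        if dup.any():
            raise ValueError(
                f"duplicate (id, t) records at rows {list(df.index[dup][:5])}")
        self.df = df

    @property
    def animals(self):
        return self.df["id"].unique()

    def positions(self, animal) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["id"] == animal]
        return sub["t"].to_numpy(float), sub[["x", "y"]].to_numpy(float)

    def __len__(self):
        return len(self.df)

    def __iter__(self):
        for a in self.animals:
            yield a, *self.positions(a)


@dataclass
class MomentCurve:
    """Empirical q-th absolute displacement moment versus lag."""

    q: float
    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None


def _displacements_at_lag(traj: TrajectorySet, lag: float, rtol: float = 1e-6):
    """All displacement magnitudes at (approximately) the requested lag.

    Regularly sampled trajectories take an O(F) shifted-difference path;
    irregular sampling falls back to the all-pairs search.
    """
    out = []
    ids = []
    atol = rtol * max(lag, 1.0)
    for animal, t, xy in traj:
        if len(t) < 2:
            continue
        steps = np.diff(t)
        dt0 = steps[0]
        regular = dt0 > 0 and np.allclose(steps, dt0, rtol=1e-9, atol=0.0)
        if regular:
            k = lag / dt0
            ki = int(round(k))
            if ki < 1 or ki >= len(t) or abs(k - ki) * dt0 > atol:
                continue
            d = np.linalg.norm(xy[ki:] - xy[:-ki], axis=1)
        else:
            dt = t[:, None] - t[None, :]
            ii, jj = np.nonzero(np.isclose(dt, -lag, rtol=rtol, atol=atol))
            if ii.size == 0:
                continue
            d = np.linalg.norm(xy[jj] - xy[ii], axis=1)
        out.append(d)
        ids.append(np.full(d.size, animal))
    if not out:
        return np.empty(0), np.empty(0)
    return np.concatenate(out), np.concatenate(ids)


def empirical_moment(traj: TrajectorySet, q: float, lags,
                     n_boot: int = 0, seed: int = 0) -> MomentCurve:
    """Ensemble/time-window estimate of <|Δx|^q> at each lag.

    Every displacement pair gets equal weight (animals pooled).  Empty
    lag bins are reported as NaN with a zero count, never dropped
    silently.  With ``n_boot > 0`` percentile bootstrap bands over
    animals are attached.
    """
    if q < 0:
        raise ValueError("moment order q must be non-negative")
    lags = np.asarray(lags, dtype=float)
    vals = np.full(lags.shape, np.nan)
    cnts = np.zeros(lags.shape, dtype=int)
    lo = np.full(lags.shape, np.nan)
    hi = np.full(lags.shape, np.nan)
    rng = np.random.default_rng(seed)
    for k, lag in enumerate(lags):
        if lag == 0:
            vals[k] = 0.0
            cnts[k] = 1
            lo[k] = hi[k] = 0.0
            continue
        d, ids = _displacements_at_lag(traj, lag)
        cnts[k] = d.size
        if d.size == 0:
            continue
        vals[k] = float(np.mean(d**q))
        if n_boot > 0:
            uniq = np.unique(ids)
            groups = [d[ids == u] ** q for u in uniq]
            reps = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.integers(0, len(groups), len(groups))
                reps[b] = np.mean(np.concatenate([groups[p] for p in pick]))
            lo[k], hi[k] = np.percentile(reps, [2.5, 97.5])
    return MomentCurve(q=q, lags=lags, values=vals, counts=cnts,
                       lo=lo if n_boot else None, hi=hi if n_boot else None)


def hurst_exponent(moment_t1: float, moment_t2: float,
                   t1: float, t2: float, q: float) -> float:
    """H(q) = ln[ <|Δx|^q>(t1) / <|Δx|^q>(t2) ] / (q ln(t1/t2)).

    Exact under power-law scaling of the q-th moment; q-dependence of the
    result flags multifractality.
    """
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    if q == 0:
        raise ValueError("q must be non-zero")
    if moment_t1 <= 0 or moment_t2 <= 0:
        raise ValueError("moments must be positive for a defined H")
    return float(np.log(moment_t1 / moment_t2) / (q * np.log(t1 / t2)))


def windowed_gaussian_moment(q: float, sigma: float, G: float,
                             n_grid: int = 201) -> float:
    """<|Δx|^q> of an isotropic Gaussian walk observed through a square
    window of side G with a uniform initial density (the special case in
    which the finite observation limits can be integrated explicitly).

    Both endpoints are restricted to the window, which suppresses the
    high-q moments relative to the unwindowed value; ``sigma`` is the
    per-axis displacement scale sqrt(2Dt).  Quadrature on a grid.
    """
    if q < 0 or sigma <= 0 or G <= 0:
        raise ValueError("q >= 0, sigma > 0 and G > 0 required")
    u = np.linspace(-G / 2, G / 2, n_grid)
    x0x, x0y = np.meshgrid(u, u, indexing="ij")
    # displacement distribution for each start, truncated to the window
    num = 0.0
    den = 0.0
    for ax0 in u[:: max(n_grid // 51, 1)]:
        for ay0 in u[:: max(n_grid // 51, 1)]:
            px = np.exp(-((u - ax0) ** 2) / (2 * sigma**2))
            py = np.exp(-((u - ay0) ** 2) / (2 * sigma**2))
            w2 = np.outer(px, py)
            r = np.hypot(x0x - ax0, x0y - ay0)
            num += float((r**q * w2).sum())
            den += float(w2.sum())
    return num / den


class HurstExponentEstimator(BaseEstimator):
    """Multifractal Hurst spectrum H(q) from trajectory moments.

    For each moment order in ``q_values`` the empirical moment is
    evaluated at the two lags ``t1 < t2`` and H(q) extracted from the
    log-ratio.  Bootstrap (over animals) percentile bands feed the
    multifractality flag: the set is called monofractal when a single
    constant H lies inside every band.

    Attributes
    ----------
    H_ : ndarray
        H(q) per moment order.
    bands_ : ndarray of shape (len(q), 2)
        Percentile bootstrap intervals.
    fractal_dimension_ : ndarray
        δ = 2 - H(q).
    monofractal_ : bool
    """

    def __init__(self, q_values=(0.5, 1.0, 2.0, 3.0), t1: float = 1.0,
                 t2: float = 10.0, n_boot: int = 100, seed: int = 0):
        self.q_values = q_values
        self.t1 = t1
        self.t2 = t2
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None):
        traj = X if isinstance(X, TrajectorySet) else TrajectorySet(X)
        qs = np.asarray(self.q_values, dtype=float)
        H = np.empty(qs.size)
        bands = np.full((qs.size, 2), np.nan)
        rng = np.random.default_rng(self.seed)
        d1, id1 = _displacements_at_lag(traj, self.t1)
        d2, id2 = _displacements_at_lag(traj, self.t2)
        if d1.size == 0 or d2.size == 0:
            raise ValueError("no displacement pairs at the requested lags")
        for k, q in enumerate(qs):
            H[k] = hurst_exponent(float(np.mean(d1**q)), float(np.mean(d2**q)),
                                  self.t1, self.t2, q)
            if self.n_boot > 0:
                uniq = np.unique(np.concatenate([id1, id2]))
                g1 = {u: d1[id1 == u] ** q for u in uniq}
                g2 = {u: d2[id2 == u] ** q for u in uniq}
                reps = np.empty(self.n_boot)
                for b in range(self.n_boot):
                    pick = rng.choice(uniq, size=uniq.size, replace=True)
                    m1 = np.concatenate([g1[u] for u in pick if g1[u].size])
                    m2 = np.concatenate([g2[u] for u in pick if g2[u].size])
                    if m1.size == 0 or m2.size == 0:
                        reps[b] = np.nan
                        continue
                    reps[b] = hurst_exponent(float(m1.mean()), float(m2.mean()),
                                             self.t1, self.t2, q)
                bands[k] = np.nanpercentile(reps, [2.5, 97.5])
        self.H_ = H
        self.bands_ = bands
        self.fractal_dimension_ = 2.0 - H
        if self.n_boot > 0:
            self.monofractal_ = bool(np.max(bands[:, 0]) <= np.min(bands[:, 1]))
        else:
            self.monofractal_ = bool(np.ptp(H) < 0.05)
        return self


class SteadyStatePotentialEstimator(BaseEstimator):
    """Fit a separable Boltzmann steady state to long-time fixes.

    Maximises the likelihood of the fixes under the stationary density
    exp{-[U(x-xc) + V(y-yc)]/D} of the chosen family; only the *shape*
    U/D is identified (an independent measurement of the diffusivity D
    is needed to split the ratio).

    Attributes
    ----------
    length_scale_ : float
        Fitted L of the family.
    centre_ : ndarray of shape (2,)
        Fitted den location (xc, yc).
    """

    def __init__(self, family: str = "harmonic", thin: int = 1):
        self.family = family
        self.thin = thin

    def fit(self, X, y=None):
        from .potentials import make_potential, boltzmann_density

        traj = X if isinstance(X, TrajectorySet) else TrajectorySet(X)
        xy = traj.df[["x", "y"]].to_numpy(float)[:: max(self.thin, 1)]
        if len(xy) < 10:
            raise ValueError("too few fixes to fit a steady state")
        if self.family == "harmonic":
            # closed-form MLE: Gaussian with per-axis variance L²/2
            centre = xy.mean(axis=0)
            var = float(np.mean((xy - centre) ** 2))
            self.centre_ = centre
            self.length_scale_ = float(np.sqrt(2.0 * var))
            return self

        def nll(theta):
            logL, cx, cy = theta
            pot = make_potential(self.family, float(np.exp(logL)))
            dens = boltzmann_density(pot)
            px = dens(xy[:, 0] - cx)
            py = dens(xy[:, 1] - cy)
            if np.any(px <= 0) or np.any(py <= 0):
                return 1e12
            return -float(np.sum(np.log(px)) + np.sum(np.log(py)))

        centre0 = np.median(xy, axis=0)
        scale0 = np.log(np.std(xy - centre0) + 1e-12)
        res = minimize(nll, x0=[scale0, centre0[0], centre0[1]],
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        self.length_scale_ = float(np.exp(res.x[0]))
        self.centre_ = res.x[1:3].copy()
        self.optimizer_result_ = res
        return self


@dataclass
class LikelihoodFit:
    """Result of a maximum-likelihood movement fit."""

    params: dict
    log_likelihood: float
    intervals: dict = field(default_factory=dict)
    n_obs: int = 0
    converged: bool = True


def _stack_blocks(blocks):
    """Concatenate per-animal fixes into flat transition arrays."""
    x0_list, x1_list, dt_list, starts = [], [], [], []
    for t, xy in blocks:
        starts.append(xy[0])
        if len(t) > 1:
            dt_list.append(np.diff(t))
            x0_list.append(xy[:-1])
            x1_list.append(xy[1:])
    starts = np.asarray(starts)
    if dt_list:
        dt = np.concatenate(dt_list)
        x0 = np.concatenate(x0_list)
        x1 = np.concatenate(x1_list)
    else:
        dt = np.empty(0)
        x0 = x1 = np.empty((0, 2))
    return starts, dt, x0, x1


def _ou_nll(theta, starts, dt, x0, x1):
    """Exact negative log-likelihood of tethered (harmonic) diffusion.

    The overdamped walker in U/D = r²/L² is an Ornstein-Uhlenbeck process
    with relaxation rate 2D/L² and stationary per-axis variance L²/2;
    transitions over arbitrary spacings have Gaussian closed form.  Each
    animal's first fix contributes its stationary density.
    """
    logD, logL, cx, cy = theta
    D, L = np.exp(logD), np.exp(logL)
    th = 2.0 * D / L**2
    var_inf = 0.5 * L**2
    c = np.array([cx, cy])
    z0 = starts - c
    nll = float(np.sum(z0**2) / (2 * var_inf)
                + len(starts) * np.log(2 * np.pi * var_inf))
    if dt.size:
        a = np.exp(-th * dt)
        v = var_inf * (1.0 - a**2)
        resid = (x1 - c) - a[:, None] * (x0 - c)
        nll += float(np.sum(resid**2 / (2 * v[:, None]))
                     + np.sum(np.log(2 * np.pi * v)))
    return nll


class SmoluchowskiMLE(BaseEstimator):
    """Maximum-likelihood fit of the tethered home-range walk (sklearn-style).

    ``model='homerange_smoluchowski'`` fits (D, L, xc, yc) of harmonic
    tethered diffusion by exact transition likelihood, maximised by
    Nelder-Mead from a moment-based start (optionally multi-started);
    percentile bootstrap over per-animal blocks provides the intervals.
    ``model='trw_adiabatic'`` fits the boundary-averaged occupation
    profile of a territorial walker (L̄, γ effective) to independent
    fixes.

    Attributes
    ----------
    params_ : dict of point estimates.
    intervals_ : dict of (lo, hi) 95% bootstrap intervals.
    log_likelihood_ : float
    fit_ : LikelihoodFit
    """

    def __init__(self, model: str = "homerange_smoluchowski",
                 n_boot: int = 200, n_restarts: int = 2, seed: int = 0,
                 resample: str = "two_stage"):
        self.model = model
        self.n_boot = n_boot
        self.n_restarts = n_restarts
        self.seed = seed
        self.resample = resample

    @staticmethod
    def _blocks(traj: TrajectorySet):
        """Per-animal (t, xy) arrays with at least two fixes each."""
        blocks = [(t, xy) for _, t, xy in traj if len(t) >= 2]
        if not blocks:
            raise ValueError("degenerate input: need animals with >= 2 fixes")
        return blocks

    def _fit_ou(self, blocks, rng, n_restarts=None):
        starts, dt, x0, x1 = _stack_blocks(blocks)

        def total_nll(theta):
            return _ou_nll(theta, starts, dt, x0, x1)

        xy_all = np.concatenate([xy for _, xy in blocks])
        centre0 = xy_all.mean(axis=0)
        var0 = max(float(np.mean((xy_all - centre0) ** 2)), 1e-12)
        L0 = np.sqrt(2 * var0)
        # AR(1) moment start for D
        z0, z1 = x0 - centre0, x1 - centre0
        num = float(np.sum(z0 * z1))
        den = max(float(np.sum(z0 * z0)), 1e-12)
        a = min(max(num / den, 1e-3), 0.999)
        dt_med = float(np.median(dt)) if dt.size else 1.0
        th0 = -np.log(a) / dt_med
        D0 = max(th0 * L0**2 / 2.0, 1e-12)
        if n_restarts is None:
            n_restarts = self.n_restarts
        best = None
        x_starts = [np.array([np.log(D0), np.log(L0), centre0[0], centre0[1]])]
        for _ in range(max(n_restarts - 1, 0)):
            jitter = rng.normal(0, [0.5, 0.25, 0.1 * L0, 0.1 * L0])
            x_starts.append(x_starts[0] + jitter)
        for xs in x_starts:
            res = minimize(total_nll, x0=xs, method="Nelder-Mead",
                           options={"xatol": 1e-7, "fatol": 1e-9,
                                    "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        D, L = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
        params = {"D": D, "L": L, "xc": float(best.x[2]), "yc": float(best.x[3])}
        return params, -float(best.fun), best

    @staticmethod
    def _fit_arrays(starts, dt, x0, x1, x_init):
        res = minimize(lambda th: _ou_nll(th, starts, dt, x0, x1),
                       x0=x_init, method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
        return {"D": float(np.exp(res.x[0])), "L": float(np.exp(res.x[1])),
                "xc": float(res.x[2]), "yc": float(res.x[3])}

    def fit(self, X, y=None):
        traj = X if isinstance(X, TrajectorySet) else TrajectorySet(X)
        rng = np.random.default_rng(self.seed)
        if self.model == "homerange_smoluchowski":
            blocks = self._blocks(traj)
            params, ll, res = self._fit_ou(blocks, rng)
            boot = {k: [] for k in params}
            starts, dt, x0, x1 = _stack_blocks(blocks)
            per_block = [_stack_blocks([b]) for b in blocks]
            M, S = dt.size, len(starts)
            A = len(blocks)
            warm = res.x
            for _ in range(self.n_boot):
                try:
                    if self.resample == "two_stage":
                        # animals with replacement, then the conditionally
                        # independent transition pairs within each animal —
                        # captures both between- and within-animal variation
                        ss, dts, xs0, xs1 = [], [], [], []
                        for a in rng.integers(0, A, A):
                            s_a, dt_a, x0_a, x1_a = per_block[a]
                            ss.append(s_a)
                            m = dt_a.size
                            if m:
                                im = rng.integers(0, m, m)
                                dts.append(dt_a[im])
                                xs0.append(x0_a[im])
                                xs1.append(x1_a[im])
                        p_b = self._fit_arrays(
                            np.concatenate(ss),
                            np.concatenate(dts) if dts else np.empty(0),
                            np.concatenate(xs0) if xs0 else np.empty((0, 2)),
                            np.concatenate(xs1) if xs1 else np.empty((0, 2)),
                            warm)
                    elif self.resample == "transitions":
                        im = rng.integers(0, M, M) if M else np.empty(0, int)
                        js = rng.integers(0, S, S)
                        p_b = self._fit_arrays(starts[js], dt[im], x0[im],
                                               x1[im], warm)
                    elif self.resample == "animals":
                        pick = [blocks[i] for i in
                                rng.integers(0, len(blocks), len(blocks))]
                        p_b, _, _ = self._fit_ou(pick, rng, n_restarts=1)
                    else:
                        raise ValueError(
                            f"unknown resample scheme {self.resample!r}")
                except ValueError:
                    raise
                except Exception:
                    continue
                for k in boot:
                    boot[k].append(p_b[k])
            intervals = {
                k: tuple(np.percentile(v, [2.5, 97.5])) if v else (np.nan, np.nan)
                for k, v in boot.items()}
        elif self.model == "trw_adiabatic":
            params, ll, intervals = self._fit_trw(traj, rng)
        else:
            raise ValueError(f"unknown model {self.model!r}")
        self.params_ = params
        self.intervals_ = intervals
        self.log_likelihood_ = ll
        self.fit_ = LikelihoodFit(params=params, log_likelihood=ll,
                                  intervals=intervals, n_obs=len(traj))
        return self

    def _fit_trw(self, traj: TrajectorySet, rng):
        """Likelihood fit of the boundary-averaged territorial profile.

        The fast walker is uniform between slowly fluctuating edges, so
        the marginal density of independent fixes along each axis is a
        Monte-Carlo average of box indicators over the stationary edge
        distribution (separation ~ |Normal(L̄, 2/γ)|, centroid at the
        fitted centre).  Fitted parameters: L̄, γ, centre.
        """
        xy = traj.df[["x", "y"]].to_numpy(float)
        if len(xy) < 2:
            raise ValueError("degenerate input: need at least two fixes")
        n_mc = 400
        zs = rng.standard_normal(n_mc)

        def axis_density(u, Lbar, gamma):
            sep = np.abs(Lbar + np.sqrt(2.0 / gamma) * zs)
            half = 0.5 * sep
            inside = np.abs(u[:, None]) <= half[None, :]
            return np.mean(inside / np.maximum(sep, 1e-12)[None, :], axis=1)

        def nll(theta):
            logLbar, loggamma, cx, cy = theta
            Lbar, gamma = np.exp(logLbar), np.exp(loggamma)
            px = axis_density(xy[:, 0] - cx, Lbar, gamma)
            py = axis_density(xy[:, 1] - cy, Lbar, gamma)
            if np.any(px <= 0) or np.any(py <= 0):
                return 1e12
            return -float(np.sum(np.log(px)) + np.sum(np.log(py)))

        c0 = np.median(xy, axis=0)
        span = np.percentile(np.abs(xy - c0), 95)
        x0 = np.array([np.log(2 * span + 1e-9), 0.0, c0[0], c0[1]])
        res = minimize(nll, x0=x0, method="Nelder-Mead",
                       options={"maxiter": 3000})
        params = {"Lbar": float(np.exp(res.x[0])),
                  "gamma": float(np.exp(res.x[1])),
                  "xc": float(res.x[2]), "yc": float(res.x[3])}
        return params, -float(res.fun), {}
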