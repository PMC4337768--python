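"""Territorial random walkers: scent-mediated exclusion on a lattice.

Walkers hop between nearest-neighbour sites of a periodic lattice and
deposit a scent mark at every visited site; a mark stays *active* for
``T_A`` hops after deposition.  Landing on a site holding an active
foreign mark is an encounter, and the walker responds from its next hop:

* ``full_exclusion`` — certain retreat: the next hop is drawn uniformly
  among neighbour sites free of active foreign marks (the walker stays put
  if there are none).  Depositing a mark claims the site, erasing other
  owners' marks there, so actively marked areas are pairwise disjoint at
  all times.
* ``alpha_family`` — graded avoidance: the next hop is biased toward the
  centroid of the walker's own active marked area with retreat bias
  p(τ) = ½[1 + sqrt(1 - (τ/T_A)^α)] for mark age τ ≤ T_A (p = ½ beyond),
  and marks of different owners coexist (overlapping territories).

The strength of territorial confinement is summarised by the spatial
competition parameter Z = 4 D ρ T_A — the area a lone diffusing walker
covers while its marks stay active, over the per-capita share of terrain.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from numba import njit

__all__ = [
    "TRWConfig",
    "TRWResult",
    "retreat_bias",
    "step_probabilities",
    "spatial_competition",
    "simulate",
    "boundary_msd_1d",
    "edge_mobility",
    "plot_utilization",
    "mean_return_time",
    "lattice_diffusivity",
]

_NEVER = -(1 << 60)


@dataclass
class TRWConfig:
    """Configuration of a territorial random walk run.

    ``ny=1`` gives the 1d (ring) model with two hop directions.
    ``respond_on`` selects whether the avoidance response is triggered by
    the mark on the landing site ("land", default: land then respond from
    the next hop) or checked on the target site before hopping ("target").
    """

    nx: int
    ny: int
    n_walkers: int
    T_A: int
    steps: int
    seed: int
    alpha: float = np.inf
    mode: str = "full_exclusion"
    respond_on: str = "land"
    record_interval: int = 100
    hop_time: float = 1.0

    def __post_init__(self):
        if self.n_walkers > self.nx * self.ny:
            raise ValueError("more walkers than lattice sites")
        if self.n_walkers < 1 or self.nx < 1 or self.ny < 1:
            raise ValueError("lattice and walker counts must be positive")
        if self.T_A <= 0:
            raise ValueError("active scent time T_A must be positive")
        if self.mode not in ("full_exclusion", "alpha_family"):
            raise ValueError("mode must be full_exclusion or alpha_family")
        if self.respond_on not in ("land", "target"):
            raise ValueError("respond_on must be 'land' or 'target'")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive (np.inf = full retreat)")

    @property
    def density(self) -> float:
        return self.n_walkers / (self.nx * self.ny)

    @property
    def Z(self) -> float:
        return spatial_competition(lattice_diffusivity(self.ny > 1, self.hop_time),
                                   self.density, self.T_A)


def lattice_diffusivity(two_d: bool = True, hop_time: float = 1.0) -> float:
    """Nearest-neighbour lattice diffusivity: a²/(4τ̄) in 2d, a²/(2τ̄) in 1d."""
    return 1.0 / ((4.0 if two_d else 2.0) * hop_time)


def spatial_competition(D: float, rho: float, T_A: float) -> float:
    """Spatial competition parameter Z = 4 D ρ T_A."""
    if D < 0 or rho < 0 or T_A < 0:
        raise ValueError("inputs must be non-negative")
    return 4.0 * D * rho * T_A


def retreat_bias(tau, T_A: float, alpha: float = np.inf):
    """Avoidance response p(τ) to a foreign mark of age τ.

    p(0) = 1, p(T_A) = 1/2, p = 1/2 beyond T_A; α → ∞ gives the step
    response of the original full-retreat model.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("mark age must be non-negative")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    with np.errstate(invalid="ignore"):
        frac = np.clip(tau / T_A, 0.0, None)
        if np.isinf(alpha):
            inner = np.where(frac < 1.0, 0.0, 1.0)
        else:
            inner = frac**alpha
        p = np.where(tau <= T_A,
                     0.5 * (1.0 + np.sqrt(np.clip(1.0 - inner, 0.0, 1.0))),
                     0.5)
    return p if p.ndim else float(p)


def step_probabilities(position, centroid, p: float):
    """Hop probabilities (l+, l-, u+, u-) of the graded-avoidance walk.

    l± bias motion along the horizontal axis toward/away from the marked
    area's centroid and u∓ do the same vertically:
    l± = ¼{1 ± (2p-1) κ_l}, u± = ¼{1 ∓ (2p-1) κ_u} with κ the direction
    cosines of (position - centroid).  They always sum to 1.  l+ is the
    probability of decreasing m (moving left), u+ of increasing n.
    """
    if not 0.5 <= p <= 1.0:
        raise ValueError("retreat bias p must lie in [1/2, 1]")
    m, n = position
    mc, nc = centroid
    dm, dn = m - mc, n - nc
    dist = np.hypot(dm, dn)
    if dist == 0.0:
        kl = ku = 0.0
    else:
        kl, ku = dm / dist, dn / dist
    b = 2.0 * p - 1.0
    lp = 0.25 * (1.0 + b * kl)
    lm = 0.25 * (1.0 - b * kl)
    up = 0.25 * (1.0 - b * ku)
    um = 0.25 * (1.0 + b * ku)
    return lp, lm, up, um


# --------------------------------------------------------------------------
# numba core
# --------------------------------------------------------------------------

@njit(cache=True)
def _p_of_age(age, T_A, alpha):
    if age > T_A:
        return 0.5
    frac = age / T_A
    if alpha < 0.0:                       # sentinel: alpha = +inf
        inner = 0.0 if frac < 1.0 else 1.0
    else:
        inner = frac**alpha
    if inner > 1.0:
        inner = 1.0
    return 0.5 * (1.0 + np.sqrt(1.0 - inner))


@njit(cache=True)
def _foreign_active(marks, i, site, t, T_A, N):
    """Youngest active foreign mark age at `site`, or -1 if none."""
    best = -1
    for j in range(N):
        if j == i:
            continue
        dep = marks[j, site]
        if dep > _NEVER:
            age = t - dep
            if age <= T_A and (best < 0 or age < best):
                best = age
    return best


@njit(cache=True)
def _own_centroid_offset(marks, i, pos_m, pos_n, t, T_A, nx, ny):
    """Mean minimal-image offset of walker i's active marks from (pos_m,pos_n)."""
    sm = 0.0
    sn = 0.0
    cnt = 0
    for m in range(nx):
        for n in range(ny):
            dep = marks[i, m * ny + n]
            if dep > _NEVER and t - dep <= T_A:
                dm = (m - pos_m + nx // 2) % nx - nx // 2
                dn = (n - pos_n + ny // 2) % ny - ny // 2
                sm += dm
                sn += dn
                cnt += 1
    if cnt == 0:
        return 0.0, 0.0
    return sm / cnt, sn / cnt


@njit(cache=True)
def _trw_core(nx, ny, N, T_A, alpha, full_excl, respond_on_land,
              steps, pos0, u_dir, u_alt, orders, record_interval):
    n_sites = nx * ny
    n_dirs = 4 if ny > 1 else 2
    # direction table: 0 left (m-1), 1 right (m+1), 2 up (n+1), 3 down (n-1)
    marks = np.full((N, n_sites), _NEVER, dtype=np.int64)
    pos = pos0.copy()               # wrapped (m, n)
    upos = pos0.astype(np.float64).copy()   # unwrapped
    enc = np.zeros(N, dtype=np.bool_)
    enc_age = np.zeros(N, dtype=np.int64)

    traj = np.zeros((steps + 1, N, 2), dtype=np.float64)
    traj[0] = upos
    n_snap = steps // record_interval
    snaps = np.zeros((n_snap, N, n_sites), dtype=np.bool_)
    snap_times = np.zeros(n_snap, dtype=np.int64)

    # initial deposits at t = 0
    for i in range(N):
        s = pos[i, 0] * ny + pos[i, 1]
        if full_excl:
            for j in range(N):
                if marks[j, s] > _NEVER:
                    marks[j, s] = _NEVER
        marks[i, s] = 0

    probs = np.empty(4, dtype=np.float64)
    for k in range(steps):
        t = k + 1
        for oi in range(N):
            i = orders[k, oi]
            m0, n0 = pos[i, 0], pos[i, 1]
            # ---- choose a direction ----
            d = -1
            if enc[i]:
                if full_excl:
                    # uniform among neighbours free of active foreign marks
                    free = np.empty(4, dtype=np.int64)
                    nfree = 0
                    for dd in range(n_dirs):
                        mm, nn = m0, n0
                        if dd == 0:
                            mm = (m0 - 1) % nx
                        elif dd == 1:
                            mm = (m0 + 1) % nx
                        elif dd == 2:
                            nn = (n0 + 1) % ny
                        else:
                            nn = (n0 - 1) % ny
                        if _foreign_active(marks, i, mm * ny + nn, t, T_A, N) < 0:
                            free[nfree] = dd
                            nfree += 1
                    if nfree == 0:
                        d = -1                      # stay put
                    else:
                        d = free[int(u_alt[k, i] * nfree)]
                else:
                    p = _p_of_age(float(enc_age[i]), float(T_A), alpha)
                    cm, cn = _own_centroid_offset(marks, i, m0, n0, t, T_A, nx, ny)
                    # position minus centroid = -offset
                    dm, dn = -cm, -cn
                    dist = np.sqrt(dm * dm + dn * dn)
                    if dist > 0.0:
                        kl = dm / dist
                        ku = dn / dist
                    else:
                        kl = 0.0
                        ku = 0.0
                    b = 2.0 * p - 1.0
                    if n_dirs == 2:
                        probs[0] = 0.5 * (1.0 + b * kl)
                        probs[1] = 0.5 * (1.0 - b * kl)
                        probs[2] = 0.0
                        probs[3] = 0.0
                    else:
                        probs[0] = 0.25 * (1.0 + b * kl)
                        probs[1] = 0.25 * (1.0 - b * kl)
                        probs[2] = 0.25 * (1.0 - b * ku)
                        probs[3] = 0.25 * (1.0 + b * ku)
                    u = u_dir[k, i]
                    acc = 0.0
                    d = n_dirs - 1
                    for dd in range(n_dirs):
                        acc += probs[dd]
                        if u < acc:
                            d = dd
                            break
            else:
                d = int(u_dir[k, i] * n_dirs)

            # ---- carry out the hop ----
            mm, nn = m0, n0
            um, un = 0.0, 0.0
            if d == 0:
                mm = (m0 - 1) % nx
                um = -1.0
            elif d == 1:
                mm = (m0 + 1) % nx
                um = 1.0
            elif d == 2:
                nn = (n0 + 1) % ny
                un = 1.0
            elif d == 3:
                nn = (n0 - 1) % ny
                un = -1.0
            s = mm * ny + nn
            if d >= 0 and (not respond_on_land):
                # check the target before hopping: refuse + retreat instead
                if _foreign_active(marks, i, s, t, T_A, N) >= 0:
                    free = np.empty(4, dtype=np.int64)
                    nfree = 0
                    for dd in range(n_dirs):
                        m2, n2 = m0, n0
                        if dd == 0:
                            m2 = (m0 - 1) % nx
                        elif dd == 1:
                            m2 = (m0 + 1) % nx
                        elif dd == 2:
                            n2 = (n0 + 1) % ny
                        else:
                            n2 = (n0 - 1) % ny
                        if _foreign_active(marks, i, m2 * ny + n2, t, T_A, N) < 0:
                            free[nfree] = dd
                            nfree += 1
                    if nfree == 0:
                        d = -1
                    else:
                        d = free[int(u_alt[k, i] * nfree)]
                        mm, nn = m0, n0
                        um, un = 0.0, 0.0
                        if d == 0:
                            mm = (m0 - 1) % nx
                            um = -1.0
                        elif d == 1:
                            mm = (m0 + 1) % nx
                            um = 1.0
                        elif d == 2:
                            nn = (n0 + 1) % ny
                            un = 1.0
                        else:
                            nn = (n0 - 1) % ny
                            un = -1.0
                    s = mm * ny + nn
            if d >= 0:
                pos[i, 0], pos[i, 1] = mm, nn
                upos[i, 0] += um
                upos[i, 1] += un
            s = pos[i, 0] * ny + pos[i, 1]
            # encounter bookkeeping at the occupied site
            age = _foreign_active(marks, i, s, t, T_A, N)
            if respond_on_land:
                enc[i] = age >= 0
                enc_age[i] = age if age >= 0 else 0
            # deposit / refresh own mark
            if full_excl:
                for j in range(N):
                    if j != i and marks[j, s] > _NEVER:
                        marks[j, s] = _NEVER
            marks[i, s] = t
        traj[t] = upos
        if record_interval > 0 and t % record_interval == 0:
            idx = t // record_interval - 1
            if idx < n_snap:
                snap_times[idx] = t
                for i in range(N):
                    for ssite in range(n_sites):
                        dep = marks[i, ssite]
                        snaps[idx, i, ssite] = (dep > _NEVER) and (t - dep <= T_A)
    return traj, snaps, snap_times


@dataclass
class TRWResult:
    """Output of a territorial random walk run."""

    config: TRWConfig
    trajectories: np.ndarray        # (steps+1, N, 2) unwrapped positions
    active_snapshots: np.ndarray    # (n_snap, N, nx*ny) bool active-mark masks
    snapshot_times: np.ndarray
    utilization: np.ndarray = field(default=None)   # (N, nx, ny)

    def wrapped(self) -> np.ndarray:
        """Trajectories folded back onto the lattice."""
        w = self.trajectories.astype(np.int64).copy()
        w[..., 0] %= self.config.nx
        w[..., 1] %= self.config.ny
        return w

    def territory_areas(self) -> np.ndarray:
        """(n_snap, N) active-mark counts per owner."""
        return self.active_snapshots.sum(axis=2)

    def territory_centroids(self) -> np.ndarray:
        """(n_snap, N, 2) minimal-image centroids of active marked areas."""
        cfg = self.config
        nx, ny = cfg.nx, cfg.ny
        wrapped = self.wrapped()
        out = np.full((len(self.snapshot_times), cfg.n_walkers, 2), np.nan)
        mgrid, ngrid = np.divmod(np.arange(nx * ny), ny)
        for si, t in enumerate(self.snapshot_times):
            for i in range(cfg.n_walkers):
                mask = self.active_snapshots[si, i]
                if not mask.any():
                    continue
                pm, pn = wrapped[t, i]
                dm = (mgrid[mask] - pm + nx // 2) % nx - nx // 2
                dn = (ngrid[mask] - pn + ny // 2) % ny - ny // 2
                out[si, i, 0] = (pm + dm.mean()) % nx
                out[si, i, 1] = (pn + dn.mean()) % ny
        return out

    def utilization_over(self, window: int) -> np.ndarray:
        """Site-occupancy frequency per owner over the trailing window."""
        return _utilization(self, window=window)

    def overlaps_disjoint(self) -> bool:
        """True iff active marked areas are pairwise disjoint in every snapshot."""
        return bool((self.active_snapshots.sum(axis=1) <= 1).all())


def simulate(config: TRWConfig) -> TRWResult:
    """Run the territorial random walk model (reproducible under seed)."""
    rng = np.random.default_rng(config.seed)
    N, steps = config.n_walkers, config.steps
    # scatter walkers on distinct sites
    sites = rng.choice(config.nx * config.ny, size=N, replace=False)
    pos0 = np.stack(np.divmod(sites, config.ny), axis=1).astype(np.int64)
    u_dir = rng.random((steps, N))
    u_alt = rng.random((steps, N))
    orders = np.argsort(rng.random((steps, N)), axis=1).astype(np.int64)
    alpha = -1.0 if np.isinf(config.alpha) else float(config.alpha)
    ri = config.record_interval if config.record_interval > 0 else steps
    traj, snaps, snap_times = _trw_core(
        config.nx, config.ny, N, config.T_A, alpha,
        config.mode == "full_exclusion", config.respond_on == "land",
        steps, pos0, u_dir, u_alt, orders, ri)
    result = TRWResult(config=config, trajectories=traj,
                       active_snapshots=snaps, snapshot_times=snap_times)
    result.utilization = _utilization(result)
    return result


def _utilization(result: TRWResult, window: int | None = None) -> np.ndarray:
    """Site-occupancy frequency per owner over the trailing time window.

    Default window: 2.5 active-scent times (the span over which emerging
    home ranges are conventionally accumulated).
    """
    cfg = result.config
    if window is None:
        window = min(int(round(2.5 * cfg.T_A)), cfg.steps)
    wrapped = result.wrapped()[-window:]
    out = np.zeros((cfg.n_walkers, cfg.nx, cfg.ny))
    for i in range(cfg.n_walkers):
        np.add.at(out[i], (wrapped[:, i, 0], wrapped[:, i, 1]), 1.0)
        out[i] /= out[i].sum()
    return out


def mean_return_time(nx: int, ny: int, n_steps: int, seed: int = 0) -> float:
    """Monte-Carlo mean recurrence time of a lone walker to its start site.

    By the Kac lemma this equals the number of lattice sites for an
    ergodic walk on a periodic nx × ny lattice.
    """
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 4, size=n_steps)
    dm = np.where(d == 0, -1, np.where(d == 1, 1, 0))
    dn = np.where(d == 2, 1, np.where(d == 3, -1, 0))
    m = np.cumsum(dm) % nx
    n = np.cumsum(dn) % ny
    at_origin = np.flatnonzero((m == 0) & (n == 0))
    if at_origin.size < 2:
        raise RuntimeError("too few returns; increase n_steps")
    first = at_origin[0] + 1
    gaps = np.diff(at_origin)
    times = np.concatenate(([first], gaps))
    return float(times.mean())


def boundary_msd_1d(config: TRWConfig, lags=None):
    """Time-averaged MSD of territory edges in the 1d (ring) model.

    An edge is the midpoint between the rightmost active mark of one
    owner and the leftmost active mark of the spatially next owner.
    Snapshots in which an owner holds no active marks (territory
    collapse) are excluded.  Returns ``(lags, msd, n_valid_snapshots)``
    with lags in units of hops.
    """
    if config.ny != 1:
        raise ValueError("boundary_msd_1d needs a 1d (ny=1) lattice")
    if config.n_walkers < 3:
        raise ValueError("need at least 3 walkers to track interior edges")
    result = simulate(config)
    edges, valid = _edges_from_snapshots(result)
    if lags is None:
        lags = np.unique(np.geomspace(1, max(2, edges.shape[0] // 4), 24).astype(int))
    dt = config.record_interval
    msd = np.full(len(lags), np.nan)
    for li, lag in enumerate(lags):
        if lag >= edges.shape[0]:
            continue
        d = edges[lag:] - edges[:-lag]
        ok = valid[lag:] & valid[:-lag]
        if ok.sum() == 0:
            continue
        msd[li] = float(np.nanmean((d[ok]) ** 2))
    return np.asarray(lags) * dt, msd, result


def edge_mobility(config: TRWConfig, lag: int = 20) -> float:
    """Effective diffusivity of territory edges: edge MSD at one lag / lag.

    Measured on the 1d ring model; with full exclusion this decays
    exponentially with the active-scent time (edges move only when marks
    expire before the resident returns).
    """
    result = simulate(config)
    edges, valid = _edges_from_snapshots(result)
    if lag >= edges.shape[0]:
        raise ValueError("lag exceeds the number of recorded snapshots")
    d = edges[lag:] - edges[:-lag]
    ok = valid[lag:] & valid[:-lag]
    if ok.sum() == 0:
        raise RuntimeError("no valid snapshot pairs (territory collapse)")
    return float(np.nanmean(d[ok] ** 2) / (lag * config.record_interval))


def plot_utilization(result: TRWResult, owners=None, ax=None, levels=None):
    """Contour map of utilization distributions (one colour per owner).

    Default contour levels are 1e-4 times (1, 2, 4, 6, 8, 10, 12, 14, 20,
    40, 80).  Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if levels is None:
        levels = 1e-4 * np.array([1, 2, 4, 6, 8, 10, 12, 14, 20, 40, 80])
    cfg = result.config
    if owners is None:
        owners = range(cfg.n_walkers)
    X, Y = np.meshgrid(np.arange(cfg.nx), np.arange(cfg.ny), indexing="ij")
    cmap = plt.get_cmap("tab20")
    for i in owners:
        u = result.utilization[i]
        use = levels[levels <= u.max()]
        if use.size == 0:
            continue
        ax.contour(X, Y, u, levels=use, colors=[cmap(i % 20)],
                   linewidths=0.8)
    ax.set_xlim(0, cfg.nx - 1)
    ax.set_ylim(0, cfg.ny - 1)
    ax.set_aspect("equal")
    return ax


def _edges_from_snapshots(result: TRWResult):
    """Unwrapped edge positions per snapshot; invalid rows flagged.

    For each pair of walkers adjacent on the ring the edge is the midpoint
    between the forward-most active mark of the left owner and the
    rearmost active mark of the right owner within the gap separating the
    walkers.  Snapshots where an owner holds no active marks (collapse)
    are invalid; edges are unwrapped by nearest matching across snapshots.
    """
    cfg = result.config
    nx, N = cfg.nx, cfg.n_walkers
    snaps = result.active_snapshots       # (S, N, nx)
    S = snaps.shape[0]
    wrapped = result.wrapped()
    edges = np.full((S, N), np.nan)
    valid = np.zeros(S, dtype=bool)
    prev_unwrapped = None
    for si in range(S):
        t = result.snapshot_times[si]
        sites = [np.flatnonzero(snaps[si, i]) for i in range(N)]
        if any(s.size == 0 for s in sites):
            continue                       # territory collapse
        w = wrapped[t, :, 0]
        order = np.argsort(w, kind="mergesort")
        bpos = np.empty(N)
        for k in range(N):
            a, b = order[k], order[(k + 1) % N]
            wa = w[a]
            gap = (w[b] - wa) % nx
            if gap == 0:
                gap = nx
            off_a = (sites[a] - wa) % nx
            off_b = (sites[b] - wa) % nx
            in_a = off_a[off_a <= gap]
            in_b = off_b[off_b <= gap]
            right_a = in_a.max() if in_a.size else 0
            left_b = in_b.min() if in_b.size else gap
            bpos[k] = (wa + 0.5 * (right_a + left_b)) % nx
        bpos = np.sort(bpos)
        if prev_unwrapped is None:
            edges[si] = bpos
        else:
            prev_w = prev_unwrapped % nx
            cur = np.empty(N)
            for j in range(N):
                diff = (bpos - prev_w[j] + nx / 2) % nx - nx / 2
                cur[j] = prev_unwrapped[j] + diff[int(np.argmin(np.abs(diff)))]
            edges[si] = cur
        prev_unwrapped = edges[si]
        valid[si] = True
    return edges, valid
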