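"""Seeded generators of synthetic relocation data.

These produce every input the estimators consume: tethered (Smoluchowski)
walkers with burrows scattered on the terrain, mark-recapture samples
through a finite trapping window, persistent (run-and-turn) walks in
boxes and circular arenas, and free / ballistic / anomalous walks.
All generators are deterministic under their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from typing import Callable

from .homerange import ObservationWindow
from .potentials import Potential
from .trajstats import TrajectorySet

__all__ = [
    "PopulationSpec",
    "generate_tethered",
    "mark_recapture_sample",
    "generate_persistent",
    "generate_persistent_arena",
    "generate_free",
    "generate_ballistic",
    "generate_anomalous",
]


@dataclass
class PopulationSpec:
    """Tethered population: burrows uniform on a square extent.

    ``extent`` should be much larger than any observation window so the
    uniform burrow-density assumption of the inversion holds (default
    choice elsewhere: 10 windows).
    """

    n_animals: int
    potential: Potential
    D: float
    extent: float
    fix_interval: float
    n_fixes: int
    seed: int = 0
    warmup_relaxations: float = 20.0
    #: integration steps per relaxation time L²/(2D); finer values shrink
    #: the O(dt) Euler-Maruyama bias in the sampled transition statistics
    dt_divisor: float = 100.0

    def __post_init__(self):
        if self.n_animals < 1 or self.D <= 0 or self.extent <= 0:
            raise ValueError("n_animals, D and extent must be positive")
        if self.fix_interval <= 0 or self.n_fixes < 1:
            raise ValueError("fix_interval and n_fixes must be positive")


def _drift_force(potential: Potential, D: float):
    """-D d(U/D)/dx by central difference (vectorised)."""
    h = 1e-5 * potential.length_scale

    def force(x):
        return -D * (potential.u_over_d(x + h) - potential.u_over_d(x - h)) / (2 * h)

    return force


def generate_tethered(spec: PopulationSpec) -> TrajectorySet:
    """Euler-Maruyama integration of burrow-tethered diffusion (2d separable).

    Each animal relaxes for ``warmup_relaxations`` home-range relaxation
    times L²/(2D) before the first fix is emitted, so the emitted fixes
    are stationary Boltzmann samples around the (uniformly scattered)
    burrow centres.  D → 0 pins every fix at its burrow.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.potential.length_scale
    centres = rng.uniform(-0.5 * spec.extent, 0.5 * spec.extent,
                          size=(spec.n_animals, 2))
    if spec.D == 0.0:
        frames = _frames_from_positions(
            np.repeat(centres[None], spec.n_fixes, axis=0),
            np.arange(spec.n_fixes) * spec.fix_interval)
        return TrajectorySet(frames)
    tau = L**2 / (2.0 * spec.D)
    dt = tau / spec.dt_divisor
    force = _drift_force(spec.potential, spec.D)
    # stability: explicit Euler needs dt * max-rate << 1
    if dt * 2.0 * spec.D / L**2 > 0.5:
        raise ValueError("integration step violates stability bound")
    x = centres.copy()
    sig = np.sqrt(2.0 * spec.D * dt)

    def advance(x, n_steps):
        for _ in range(n_steps):
            x = x + force(x - centres) * dt + sig * rng.standard_normal(x.shape)
        return x

    x = advance(x, int(np.ceil(spec.warmup_relaxations * tau / dt)))
    steps_per_fix = max(int(round(spec.fix_interval / dt)), 1)
    snaps = np.empty((spec.n_fixes, spec.n_animals, 2))
    snaps[0] = x
    for k in range(1, spec.n_fixes):
        x = advance(x, steps_per_fix)
        snaps[k] = x
    times = np.arange(spec.n_fixes) * steps_per_fix * dt
    return TrajectorySet(_frames_from_positions(snaps, times))


def _frames_from_positions(snaps: np.ndarray, times: np.ndarray) -> pd.DataFrame:
    n_fix, n_animal, _ = snaps.shape
    return pd.DataFrame({
        "id": np.tile(np.arange(n_animal), n_fix),
        "t": np.repeat(times, n_animal),
        "x": snaps[:, :, 0].ravel(),
        "y": snaps[:, :, 1].ravel(),
    })


def mark_recapture_sample(traj: TrajectorySet, window: ObservationWindow,
                          stationarity_lag: float = 0.0) -> pd.DataFrame:
    """Capture-recapture pairs observed inside the trapping window.

    Keeps only fixes inside the window and emits every ordered pair of
    same-animal fixes whose lag exceeds ``stationarity_lag``; columns
    ``id, t0, t1, dx2`` with ``dx2`` the squared displacement (summed
    over the window's axes).
    """
    rows = []
    dim = window.dimension
    for animal, t, xy in traj:
        inside = window.contains(xy if dim == 2 else xy[:, :1])
        t_in, xy_in = t[inside], xy[inside]
        if len(t_in) < 2:
            continue
        dt = t_in[None, :] - t_in[:, None]
        ii, jj = np.nonzero(dt > stationarity_lag)
        if ii.size == 0:
            continue
        d = xy_in[jj, :dim] - xy_in[ii, :dim]
        rows.append(pd.DataFrame({
            "id": animal, "t0": t_in[ii], "t1": t_in[jj],
            "dx2": np.sum(d * d, axis=1)}))
    if not rows:
        raise ValueError("empty sample: no in-window capture-recapture pairs")
    return pd.concat(rows, ignore_index=True)


def generate_persistent(v: float, T: float, lambda_x: float,
                        lambda_y: float | None, duration: float, dt: float,
                        n_walkers: int = 1, seed: int = 0) -> TrajectorySet:
    """Run-and-turn walk in a reflecting rectangle.

    Velocity components are independent telegraph processes along each
    axis: direction reversals arrive as a Poisson process of rate 1/(2T),
    so the velocity autocorrelation decays as e^{-t/T} and the walk matches
    the exponential-memory (persistence time T) walker axis by axis; walls
    reflect specularly.  Walkers start uniformly with random headings.
    """
    if v <= 0 or T <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("v, T, duration, dt must be positive")
    rng = np.random.default_rng(seed)
    widths = [lambda_x] + ([lambda_y] if lambda_y is not None else [])
    n_axis = len(widths)
    n_steps = int(np.ceil(duration / dt))
    x = np.stack([rng.uniform(0, w, n_walkers) for w in widths], axis=1)
    s = rng.choice([-1.0, 1.0], size=(n_walkers, n_axis))
    flip_p = dt / (2.0 * T)
    out = np.empty((n_steps + 1, n_walkers, n_axis))
    out[0] = x
    for k in range(n_steps):
        flips = rng.random((n_walkers, n_axis)) < flip_p
        s = np.where(flips, -s, s)
        x = x + v * s * dt
        for ax, w in enumerate(widths):
            over = x[:, ax] > w
            x[over, ax] = 2 * w - x[over, ax]
            s[over, ax] *= -1
            under = x[:, ax] < 0
            x[under, ax] = -x[under, ax]
            s[under, ax] *= -1
        out[k + 1] = x
    times = np.arange(n_steps + 1) * dt
    if n_axis == 1:
        out = np.concatenate([out, np.zeros_like(out)], axis=2)
    return TrajectorySet(_frames_from_positions(out, times))


def generate_persistent_arena(step: float, radius: float,
                              turning_kernel: Callable | None,
                              n_steps: int, n_walkers: int = 1,
                              seed: int = 0) -> TrajectorySet:
    """Fixed-step correlated walk in a circular arena with wall reflection.

    ``turning_kernel(rng, size)`` draws turning angles; ``None`` means a
    uniform kernel (Brownian limit, <cos θ> = 0); a kernel returning
    zeros gives straight-line (ballistic) segments between reflections.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_walkers, 2))
    heading = rng.uniform(0, 2 * np.pi, n_walkers)
    out = np.empty((n_steps + 1, n_walkers, 2))
    out[0] = pos
    for k in range(n_steps):
        if turning_kernel is None:
            theta = rng.uniform(-np.pi, np.pi, n_walkers)
        else:
            theta = np.asarray(turning_kernel(rng, n_walkers), dtype=float)
        heading = heading + theta
        prop = pos + step * np.stack([np.cos(heading), np.sin(heading)], axis=1)
        r = np.linalg.norm(prop, axis=1)
        hit = r > radius
        if hit.any():
            # specular reflection about the wall normal at the crossing
            n_hat = prop[hit] / r[hit, None]
            excess = (r[hit] - radius)[:, None]
            prop[hit] = prop[hit] - 2 * excess * n_hat
            vec = prop[hit] - pos[hit]
            heading[hit] = np.arctan2(vec[:, 1], vec[:, 0])
        pos = prop
        out[k + 1] = pos
    return TrajectorySet(_frames_from_positions(out, np.arange(n_steps + 1.0)))


def generate_free(D: float, duration: float, dt: float,
                  n_walkers: int = 1, seed: int = 0) -> TrajectorySet:
    """Free 2d Brownian motion with diffusivity D (Einstein MSD 4Dt)."""
    return generate_anomalous(lambda t: D, duration, dt, n_walkers, seed)


def generate_ballistic(v: float, duration: float, dt: float,
                       n_walkers: int = 1, seed: int = 0) -> TrajectorySet:
    """Straight-line motion at speed v with random fixed headings."""
    rng = np.random.default_rng(seed)
    heading = rng.uniform(0, 2 * np.pi, n_walkers)
    times = np.arange(int(np.ceil(duration / dt)) + 1) * dt
    out = times[:, None, None] * (
        v * np.stack([np.cos(heading), np.sin(heading)], axis=1)[None])
    return TrajectorySet(_frames_from_positions(out, times))


def generate_anomalous(D_of_t: Callable, duration: float, dt: float,
                       n_walkers: int = 1, seed: int = 0) -> TrajectorySet:
    """Gaussian walk with time-dependent diffusivity D(t) ≥ 0.

    Per-axis increments have variance 2 D(t) dt, so the ensemble MSD is
    2n ∫₀ᵗ D(s) ds; a power-law D(t) ∝ t^{2H-1} yields Hurst exponent H
    at every moment order (monofractal scaling).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(duration / dt))
    times = np.arange(n_steps + 1) * dt
    mid = 0.5 * (times[:-1] + times[1:])
    Dvals = np.asarray([D_of_t(t) for t in mid], dtype=float)
    if np.any(Dvals < 0):
        raise ValueError("D(t) must be non-negative")
    sig = np.sqrt(2.0 * Dvals * dt)
    incr = sig[:, None, None] * rng.standard_normal((n_steps, n_walkers, 2))
    out = np.concatenate([np.zeros((1, n_walkers, 2)), np.cumsum(incr, axis=0)])
    return TrajectorySet(_frames_from_positions(out, times))
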