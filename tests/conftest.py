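import numpy as np
import pandas as pd
import pytest

import rangewalk as rw


@pytest.fixture(scope="session")
def small_traj():
    """Three animals, regular 1-unit sampling, deterministic Brownian-ish."""
    rng = np.random.default_rng(42)
    frames = []
    for a in range(3):
        steps = rng.standard_normal((50, 2))
        xy = np.cumsum(steps, axis=0)
        frames.append(pd.DataFrame({
            "id": a, "t": np.arange(50.0), "x": xy[:, 0], "y": xy[:, 1]}))
    return rw.TrajectorySet(pd.concat(frames, ignore_index=True))


def box_diffusion_msd(t, D, lam, n_terms=400):
    """Reference MSD of pure diffusion in a reflecting interval of width lam,
    uniform start: lam²/6 - (16 lam²/π⁴) Σ_odd m^-4 exp(-m²π²Dt/lam²)."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, lam**2 / 6.0)
    for n in range(1, n_terms + 1):
        m = 2 * n - 1
        out = out - (16 * lam**2 / np.pi**4) / m**4 * np.exp(
            -D * m * m * np.pi**2 * t / lam**2)
    return out
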