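"""Trajectory containers, displacement moments, Hurst, likelihood fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gamma as gamma_fn

import rangewalk as rw
from rangewalk import synthetic


class TestTrajectorySet:
    def test_duplicate_time_rejected(self):
        df = pd.DataFrame({"id": [1, 1], "t": [0.0, 0.0],
                           "x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            rw.TrajectorySet(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rw.TrajectorySet(pd.DataFrame({"id": [1], "t": [0.0], "x": [0.0]}))

    def test_times_sorted_per_animal(self):
        df = pd.DataFrame({"id": [1, 1, 2], "t": [1.0, 0.0, 0.5],
                           "x": [1.0, 0.0, 2.0], "y": [0.0, 0.0, 0.0]})
        ts = rw.TrajectorySet(df)
        t, xy = ts.positions(1)
        assert list(t) == [0.0, 1.0]
        assert xy[0, 0] == 0.0


class TestEmpiricalMoment:
    def test_free_diffusion_einstein_slope(self):
        D = 0.7
        traj = synthetic.generate_free(D, duration=200.0, dt=1.0,
                                       n_walkers=60, seed=3)
        lags = np.array([5.0, 10.0, 20.0, 40.0])
        mc = rw.empirical_moment(traj, q=2.0, lags=lags)
        slope = np.polyfit(lags, mc.values, 1)[0]
        assert slope == pytest.approx(4 * D, rel=0.1)

    def test_zero_lag_moment_vanishes(self, small_traj):
        mc = rw.empirical_moment(small_traj, q=2.0, lags=[0.0, 5.0])
        assert mc.values[0] == 0.0

    def test_empty_lag_bins_reported_not_dropped(self, small_traj):
        mc = rw.empirical_moment(small_traj, q=2.0, lags=[5.0, 1000.0])
        assert mc.counts[1] == 0
        assert np.isnan(mc.values[1])

    def test_permutation_invariance_over_animals(self, small_traj):
        df = small_traj.df
        shuffled = df.sample(frac=1.0, random_state=0)
        mc1 = rw.empirical_moment(small_traj, 2.0, [3.0])
        mc2 = rw.empirical_moment(rw.TrajectorySet(shuffled), 2.0, [3.0])
        assert mc1.values[0] == pytest.approx(mc2.values[0], rel=1e-12)


class TestHurstExponent:
    def test_exact_gaussian_moments_give_half(self):
        # closed-form moments of 2d isotropic diffusion: <|dx|^q> =
        # (4Dt)^{q/2} Γ(1+q/2); the log-ratio returns H = 1/2 exactly
        D, t1, t2 = 0.3, 2.0, 17.0
        for q in (0.5, 1.0, 2.0, 3.0, 4.0):
            m1 = (4 * D * t1) ** (q / 2) * gamma_fn(1 + q / 2)
            m2 = (4 * D * t2) ** (q / 2) * gamma_fn(1 + q / 2)
            assert rw.hurst_exponent(m1, m2, t1, t2, q) == pytest.approx(
                0.5, abs=1e-14)

    def test_ballistic_moments_give_one(self):
        v, t1, t2 = 2.0, 1.0, 9.0
        for q in (0.5, 1.0, 2.0):
            assert rw.hurst_exponent((v * t1) ** q, (v * t2) ** q,
                                     t1, t2, q) == pytest.approx(1.0, abs=1e-14)

    def test_common_rescaling_leaves_H_unchanged(self):
        h0 = rw.hurst_exponent(2.0, 8.0, 1.0, 4.0, 2.0)
        assert rw.hurst_exponent(7 * 2.0, 7 * 8.0, 1.0, 4.0, 2.0) == pytest.approx(h0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rw.hurst_exponent(1.0, 1.0, 2.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            rw.hurst_exponent(0.0, 1.0, 1.0, 2.0, 2.0)

    def test_estimator_flags_brownian_as_monofractal(self):
        traj = synthetic.generate_free(0.5, duration=120.0, dt=1.0,
                                       n_walkers=40, seed=8)
        est = rw.HurstExponentEstimator(q_values=(1.0, 2.0, 3.0), t1=2.0,
                                        t2=20.0, n_boot=60, seed=1)
        est.fit(traj)
        assert est.monofractal_
        np.testing.assert_allclose(est.H_, 0.5, atol=0.1)
        np.testing.assert_allclose(est.fractal_dimension_, 2 - est.H_)


class TestSteadyStateFit:
    def test_recovers_harmonic_length_scale(self):
        L = 4.0
        spec = synthetic.PopulationSpec(
            n_animals=1, potential=rw.HarmonicPotential(L), D=20.0,
            extent=1e-6, fix_interval=2 * L * L / 40.0, n_fixes=2000, seed=5,
            dt_divisor=20)
        traj = synthetic.generate_tethered(spec)
        est = rw.SteadyStatePotentialEstimator(family="harmonic").fit(traj)
        assert est.length_scale_ == pytest.approx(L, rel=0.10)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        xy = rng.standard_normal((500, 2))
        df = pd.DataFrame({"id": 0, "t": np.arange(500.0),
                           "x": xy[:, 0], "y": xy[:, 1]})
        a = rw.SteadyStatePotentialEstimator("harmonic").fit(rw.TrajectorySet(df))
        df2 = df.assign(x=df.x + 10.0, y=df.y - 4.0)
        b = rw.SteadyStatePotentialEstimator("harmonic").fit(rw.TrajectorySet(df2))
        np.testing.assert_allclose(b.centre_, a.centre_ + [10.0, -4.0],
                                   atol=1e-9)
        assert b.length_scale_ == pytest.approx(a.length_scale_, rel=1e-9)

    def test_error_shrinks_with_sample_size(self):
        L, D = 4.0, 20.0
        errs = {}
        for n in (500, 8000):
            rep_errs = []
            for s in range(3):
                spec = synthetic.PopulationSpec(
                    n_animals=1, potential=rw.HarmonicPotential(L), D=D,
                    extent=1e-6, fix_interval=2 * L * L / (2 * D),
                    n_fixes=n, seed=40 + s, dt_divisor=20)
                traj = synthetic.generate_tethered(spec)
                est = rw.SteadyStatePotentialEstimator("harmonic").fit(traj)
                rep_errs.append(abs(est.length_scale_ - L))
            errs[n] = np.median(rep_errs)
        assert errs[8000] < errs[500]

    def test_too_few_fixes_rejected(self):
        df = pd.DataFrame({"id": 0, "t": [0.0, 1.0], "x": [0, 1], "y": [0, 1]})
        with pytest.raises(ValueError):
            rw.SteadyStatePotentialEstimator("harmonic").fit(rw.TrajectorySet(df))


class TestSmoluchowskiMLE:
    def test_point_estimates_close_to_truth(self):
        D, L = 50.0, 8.0
        tau = L * L / (2 * D)
        spec = synthetic.PopulationSpec(
            n_animals=12, potential=rw.HarmonicPotential(L), D=D,
            extent=1e-3, fix_interval=tau, n_fixes=60, seed=21, dt_divisor=400)
        traj = synthetic.generate_tethered(spec)
        est = rw.SmoluchowskiMLE(n_boot=0, n_restarts=2, seed=0).fit(traj)
        assert est.params_["D"] == pytest.approx(D, rel=0.25)
        assert est.params_["L"] == pytest.approx(L, rel=0.10)

    def test_maximised_likelihood_beats_moment_start(self):
        spec = synthetic.PopulationSpec(
            n_animals=4, potential=rw.HarmonicPotential(5.0), D=10.0,
            extent=1e-3, fix_interval=1.0, n_fixes=30, seed=2)
        traj = synthetic.generate_tethered(spec)
        est = rw.SmoluchowskiMLE(n_boot=0, n_restarts=3, seed=0).fit(traj)
        from rangewalk.trajstats import _ou_nll, _stack_blocks
        blocks = est._blocks(traj)
        starts, dt, x0, x1 = _stack_blocks(blocks)
        p = est.params_
        at_opt = -_ou_nll([np.log(p["D"]), np.log(p["L"]), p["xc"], p["yc"]],
                          starts, dt, x0, x1)
        assert est.log_likelihood_ == pytest.approx(at_opt, abs=1e-6)
        off = -_ou_nll([np.log(2 * p["D"]), np.log(p["L"]), p["xc"], p["yc"]],
                       starts, dt, x0, x1)
        assert est.log_likelihood_ >= off

    def test_single_fix_rejected(self):
        df = pd.DataFrame({"id": [0], "t": [0.0], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="degenerate"):
            rw.SmoluchowskiMLE().fit(rw.TrajectorySet(df))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            rw.SmoluchowskiMLE(model="nope").fit(
                rw.TrajectorySet(pd.DataFrame(
                    {"id": [0, 0], "t": [0.0, 1.0], "x": [0, 1], "y": [0, 1]})))

    def test_sklearn_param_interface(self):
        est = rw.SmoluchowskiMLE(n_boot=7)
        assert est.get_params()["n_boot"] == 7
        est.set_params(seed=3)
        assert est.seed == 3

    def test_trw_adiabatic_recovers_territory_width(self):
        rng = np.random.default_rng(14)
        # independent fixes from a uniform box of full width 10, wobbling edges
        n = 800
        sep = np.abs(10.0 + rng.standard_normal(n))
        x = (rng.random(n) - 0.5) * sep
        sep_y = np.abs(10.0 + rng.standard_normal(n))
        y = (rng.random(n) - 0.5) * sep_y
        df = pd.DataFrame({"id": 0, "t": np.arange(float(n)), "x": x, "y": y})
        est = rw.SmoluchowskiMLE(model="trw_adiabatic", seed=0).fit(
            rw.TrajectorySet(df))
        assert est.params_["Lbar"] == pytest.approx(10.0, rel=0.15)


class TestWindowedMoment:
    def test_wide_window_limit_matches_free_gaussian_moment(self):
        from scipy.special import gamma as gamma_fn
        from rangewalk.trajstats import windowed_gaussian_moment
        sigma, G, q = 0.5, 40.0, 2.0
        free = (2 * sigma**2) ** (q / 2) * gamma_fn(1 + q / 2)
        val = windowed_gaussian_moment(q, sigma, G)
        assert val == pytest.approx(free, rel=0.05)

    def test_narrow_window_suppresses_high_moments(self):
        from rangewalk.trajstats import windowed_gaussian_moment
        sigma = 1.0
        wide = windowed_gaussian_moment(4.0, sigma, 30.0)
        narrow = windowed_gaussian_moment(4.0, sigma, 2.0)
        assert narrow < 0.5 * wide
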