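"""Territorial random walk: bias rules, competition parameter, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rangewalk as rw


class TestRetreatBias:
    @pytest.mark.parametrize("alpha", [1.0, 2.0, 10.0, np.inf])
    def test_endpoints(self, alpha):
        assert rw.retreat_bias(0.0, 10.0, alpha) == pytest.approx(1.0)
        assert rw.retreat_bias(10.0, 10.0, alpha) == pytest.approx(0.5)

    def test_beyond_active_time_is_neutral(self):
        assert rw.retreat_bias(10.1, 10.0, 2.0) == 0.5

    def test_infinite_alpha_is_step_response(self):
        assert rw.retreat_bias(9.9, 10.0, np.inf) == pytest.approx(1.0)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            rw.retreat_bias(1.0, 10.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(tau=st.floats(min_value=0, max_value=20),
           alpha=st.floats(min_value=0.1, max_value=50))
    def test_bias_always_between_half_and_one(self, tau, alpha):
        p = rw.retreat_bias(tau, 10.0, alpha)
        assert 0.5 <= p <= 1.0


class TestStepProbabilities:
    def test_neutral_bias_is_uniform(self):
        probs = rw.step_probabilities((3, 4), (1, 1), 0.5)
        np.testing.assert_allclose(probs, 0.25)

    def test_full_bias_due_east_of_centroid(self):
        # walker east of its centroid retreats west: l+ takes the freed mass
        lp, lm, up, um = rw.step_probabilities((5, 0), (0, 0), 1.0)
        assert (lp, lm, up, um) == pytest.approx((0.5, 0.0, 0.25, 0.25))

    def test_on_centroid_is_unbiased(self):
        np.testing.assert_allclose(rw.step_probabilities((2, 2), (2, 2), 0.9),
                                   0.25)

    def test_rejects_bias_outside_range(self):
        with pytest.raises(ValueError):
            rw.step_probabilities((1, 0), (0, 0), 0.4)

    @settings(max_examples=50, deadline=None)
    @given(m=st.integers(-10, 10), n=st.integers(-10, 10),
           p=st.floats(min_value=0.5, max_value=1.0))
    def test_probabilities_sum_to_one(self, m, n, p):
        probs = rw.step_probabilities((m, n), (0, 0), p)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        assert all(q >= -1e-12 for q in probs)


class TestSpatialCompetition:
    def test_reference_lattice_configuration(self):
        # 16 walkers on 25x25, nearest-neighbour diffusivity 1/4:
        # Z = 32 requires T_A = 1250 hops
        rho = 16 / 625
        D = rw.lattice_diffusivity(two_d=True)
        assert rw.spatial_competition(D, rho, 1250) == pytest.approx(32.0)

    def test_linear_in_density(self):
        assert rw.spatial_competition(0.25, 0.08, 100) == pytest.approx(
            2 * rw.spatial_competition(0.25, 0.04, 100))

    def test_zero_diffusivity_gives_zero(self):
        assert rw.spatial_competition(0.0, 0.1, 50) == 0.0


class TestSimulate:
    def test_deterministic_under_seed(self):
        cfg = rw.TRWConfig(nx=15, ny=15, n_walkers=4, T_A=50, steps=300,
                           seed=7, record_interval=50)
        a = rw.simulate(cfg)
        b = rw.simulate(cfg)
        np.testing.assert_array_equal(a.trajectories, b.trajectories)
        np.testing.assert_array_equal(a.active_snapshots, b.active_snapshots)

    def test_single_walker_is_simple_random_walk(self):
        # ensemble Einstein slope 1 site²/hop (2d nearest-neighbour, 4D = 1)
        disp = []
        for s in range(60):
            cfg = rw.TRWConfig(nx=75, ny=75, n_walkers=1, T_A=10, steps=300,
                               seed=s, record_interval=0)
            res = rw.simulate(cfg)
            d = res.trajectories[:, 0, :] - res.trajectories[0, 0, :]
            disp.append((d**2).sum(axis=1))
        msd = np.mean(disp, axis=0)
        t = np.arange(len(msd))
        slope = np.polyfit(t, msd, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.12)

    def test_full_exclusion_marked_areas_disjoint(self):
        cfg = rw.TRWConfig(nx=25, ny=25, n_walkers=16, T_A=1250, steps=8000,
                           seed=11, record_interval=250)
        res = rw.simulate(cfg)
        assert res.overlaps_disjoint()

    def test_alpha_family_allows_overlap(self):
        cfg = rw.TRWConfig(nx=25, ny=25, n_walkers=16, T_A=1250, steps=5000,
                           seed=2, mode="alpha_family", alpha=10.0,
                           record_interval=250)
        res = rw.simulate(cfg)
        owners_per_site = res.active_snapshots.sum(axis=1)
        assert owners_per_site.max() > 1

    def test_scent_blind_alpha_recovers_free_statistics(self):
        # alpha -> 0 drives the retreat bias to 1/2: walkers ignore scent
        disp = []
        for s in range(40):
            cfg = rw.TRWConfig(nx=75, ny=75, n_walkers=4, T_A=50, steps=300,
                               seed=s, mode="alpha_family", alpha=1e-9,
                               record_interval=0)
            res = rw.simulate(cfg)
            d = res.trajectories - res.trajectories[0]
            disp.append((d**2).sum(axis=2).mean(axis=1))
        msd = np.mean(disp, axis=0)
        slope = np.polyfit(np.arange(len(msd)), msd, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.12)

    def test_utilization_maps_normalised(self):
        cfg = rw.TRWConfig(nx=15, ny=15, n_walkers=4, T_A=100, steps=1000,
                           seed=3, record_interval=100)
        res = rw.simulate(cfg)
        np.testing.assert_allclose(res.utilization.sum(axis=(1, 2)), 1.0,
                                   atol=1e-12)

    def test_strong_competition_shrinks_utilization_overlap(self):
        # overlap coefficient of utilization maps collapses as Z grows;
        # accumulate both over the same window so the comparison is fair
        def mean_overlap(T_A, steps):
            cfg = rw.TRWConfig(nx=15, ny=15, n_walkers=4, T_A=T_A,
                               steps=steps, seed=9, record_interval=0,
                               respond_on="target")
            res = rw.simulate(cfg)
            u = res.utilization_over(window=1500)
            tot = 0.0
            cnt = 0
            for i in range(4):
                for j in range(i + 1, 4):
                    tot += np.minimum(u[i], u[j]).sum()
                    cnt += 1
            return tot / cnt
        weak = mean_overlap(T_A=5, steps=4000)      # Z ~ 0.09
        strong = mean_overlap(T_A=2000, steps=4000)  # Z ~ 36
        assert strong < 0.5 * weak

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            rw.TRWConfig(nx=3, ny=3, n_walkers=10, T_A=5, steps=10, seed=0)
        with pytest.raises(ValueError):
            rw.TRWConfig(nx=5, ny=5, n_walkers=2, T_A=0, steps=10, seed=0)


class TestKacRecurrence:
    def test_mean_return_time_equals_site_count(self):
        val = rw.mean_return_time(5, 5, 3_000_000, seed=12)
        assert val == pytest.approx(25.0, rel=0.05)


class TestBoundary1d:
    def test_requires_one_dimensional_lattice(self):
        cfg = rw.TRWConfig(nx=10, ny=10, n_walkers=4, T_A=10, steps=100, seed=0)
        with pytest.raises(ValueError):
            rw.boundary_msd_1d(cfg)

    def test_edges_stay_put_when_marks_never_expire(self):
        # T_A longer than the whole run: exclusion freezes the interfaces
        cfg = rw.TRWConfig(nx=100, ny=1, n_walkers=5, T_A=10**7, steps=30000,
                           seed=4, record_interval=100, respond_on="target")
        lags, msd, _ = rw.boundary_msd_1d(cfg, lags=np.array([20, 60]))
        assert np.nanmax(msd) < 3.0
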