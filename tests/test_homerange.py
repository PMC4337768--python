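"""Saturation-MSD closed forms, quadrature pipeline, and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import rangewalk as rw
from rangewalk.homerange import SaturationOutOfRangeError, _normalizer


class TestClosedForms:
    def test_both_families_reach_one_at_large_zeta(self):
        assert rw.msd_ss_harmonic(1e3) == pytest.approx(1.0, abs=1e-3)
        assert rw.msd_ss_logarithmic(1e3) == pytest.approx(1.0, abs=1e-3)

    def test_both_families_vanish_at_small_zeta(self):
        assert rw.msd_ss_harmonic(1e-3) < 1e-4
        assert rw.msd_ss_logarithmic(1e-3) < 1e-2

    def test_sigmoid_monotone(self):
        z = np.geomspace(1e-2, 1e2, 200)
        assert np.all(np.diff(rw.msd_ss_harmonic(z)) > 0)
        assert np.all(np.diff(rw.msd_ss_logarithmic(z)) > 0)

    @pytest.mark.parametrize("fn", [rw.msd_ss_harmonic, rw.msd_ss_logarithmic])
    def test_rejects_nonpositive_zeta(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)


class TestQuadraturePipeline:
    @pytest.mark.parametrize("zeta", [0.05, 0.5, 2.0])
    def test_harmonic_quadrature_matches_closed_form(self, zeta):
        w = rw.ObservationWindow(G=1.0, dimension=1)
        num = rw.msd_ss_numeric(rw.HarmonicPotential(zeta), w) / (1 / 6)
        assert num == pytest.approx(rw.msd_ss_harmonic(zeta), rel=1e-6)

    @pytest.mark.parametrize("zeta", [0.05, 0.5, 2.0])
    def test_logarithmic_quadrature_matches_closed_form(self, zeta):
        w = rw.ObservationWindow(G=1.0, dimension=1)
        num = rw.msd_ss_numeric(rw.LogarithmicPotential(zeta), w) / (1 / 6)
        assert num == pytest.approx(rw.msd_ss_logarithmic(zeta), rel=1e-5)

    def test_flat_interior_limit_is_G_squared_over_six(self):
        # a huge home range leaves two independent uniforms on the window
        G = 2.0
        w = rw.ObservationWindow(G=G, dimension=1)
        val = rw.msd_ss_numeric(rw.HarmonicPotential(500.0 * G), w)
        assert val == pytest.approx(G**2 / 6, rel=1e-4)

    def test_2d_rectangular_window_sums_axes(self):
        wx = rw.ObservationWindow(G=1.0, dimension=1)
        wy = rw.ObservationWindow(G=2.0, dimension=1)
        w2 = rw.ObservationWindow(G=1.0, dimension=2, Gy=2.0)
        px = rw.HarmonicPotential(0.6)
        py = rw.HarmonicPotential(1.1)
        total = rw.msd_ss_numeric(px, w2, potential_y=py)
        assert total == pytest.approx(
            rw.msd_ss_numeric(px, wx) + rw.msd_ss_numeric(py, wy), rel=1e-8)

    def test_probe_motion_factorization(self):
        """The reciprocal-space form (probe factor x motion factor) agrees
        with the real-space convolution form for the harmonic family."""
        L, G = 0.8, 1.0
        alpha = L**2 / 2.0          # P(k) ∝ exp(-alpha k²/2) ... P² ∝ e^{-alpha k²}
        probe = lambda k: (np.sin(G * k / 2) / (k / 2))**2 if k != 0 else G**2
        p2 = lambda k: np.exp(-alpha * k**2)
        d2p2 = lambda k: (4 * (alpha / 2)**2 * 4 * k**2 - 2 * alpha) * np.exp(-alpha * k**2)
        num, _ = quad(lambda k: -d2p2(k) * probe(k), -60, 60, limit=400)
        den, _ = quad(lambda k: p2(k) * probe(k), -60, 60, limit=400)
        kspace = num / den
        real = rw.msd_ss_numeric(rw.HarmonicPotential(L),
                                 rw.ObservationWindow(G=G, dimension=1))
        assert kspace == pytest.approx(real, rel=1e-5)


class TestSaturationCurve:
    def test_curve_monotone_in_unit_interval(self):
        z = np.geomspace(0.01, 100, 41)
        for family in ("harmonic", "logarithmic"):
            c = rw.build_saturation_curve(family, z)
            assert np.all(np.diff(c.msd_norm) > 0)
            assert np.all((c.msd_norm > 0) & (c.msd_norm < 1))

    def test_quadrature_families_share_sigmoid_envelope(self):
        z = np.geomspace(0.05, 20, 7)
        for family in ("box_erf", "multi_harmonic"):
            c = rw.build_saturation_curve(family, z)
            assert np.all(np.diff(c.msd_norm) > 0)
            assert np.all((c.msd_norm > 0) & (c.msd_norm < 1))

    def test_single_point_grid_is_valid(self):
        c = rw.build_saturation_curve("harmonic", [1.0])
        assert c.msd_norm.shape == (1,)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            rw.build_saturation_curve("harmonic", [1.0, 0.5])


class TestInversion:
    def test_round_trip_recovers_zeta(self):
        w = rw.ObservationWindow(G=3.0, dimension=1)
        curve = rw.build_saturation_curve("harmonic", np.geomspace(0.01, 100, 41))
        for z in [0.05, 0.3, 1.0, 7.0, 60.0]:
            msd = rw.msd_ss_harmonic(z) * _normalizer(w)
            est = rw.invert_msd(msd, w, curve)
            assert est.zeta == pytest.approx(z, rel=1e-6)
            assert est.L == pytest.approx(z * 3.0, rel=1e-6)

    def test_above_asymptote_rejected(self):
        w = rw.ObservationWindow(G=1.0, dimension=1)
        curve = rw.build_saturation_curve("harmonic", np.geomspace(0.01, 100, 21))
        with pytest.raises(SaturationOutOfRangeError):
            rw.invert_msd(1.05 / 6, w, curve)

    def test_interval_brackets_point_estimate(self):
        w = rw.ObservationWindow(G=1.0, dimension=1)
        curve = rw.build_saturation_curve("harmonic", np.geomspace(0.01, 100, 21))
        msd = rw.msd_ss_harmonic(0.8) / 6
        est = rw.invert_msd(msd, w, curve, err=0.2 * msd)
        assert est.L_lo <= est.L <= est.L_hi
        assert est.zeta_lo < est.zeta < est.zeta_hi


@settings(max_examples=30, deadline=None)
@given(z=st.floats(min_value=1e-2, max_value=1e2))
def test_inversion_is_left_inverse_of_curve(z):
    curve = rw.build_saturation_curve("harmonic", np.geomspace(1e-3, 1e3, 61))
    assert curve.invert(float(rw.msd_ss_harmonic(z))) == pytest.approx(z, rel=1e-6)


class TestNonUniformBurrows:
    def test_uniform_density_reduces_to_standard_pipeline(self):
        from rangewalk.homerange import msd_ss_nonuniform
        w = rw.ObservationWindow(G=1.0, dimension=1)
        pot = rw.HarmonicPotential(0.7)
        a = msd_ss_nonuniform(pot, w, lambda xc: 1.0, half_range=4.0)
        assert a == pytest.approx(rw.msd_ss_numeric(pot, w), rel=1e-6)

    def test_burrows_clustered_at_centre_raise_the_msd(self):
        from rangewalk.homerange import msd_ss_nonuniform
        w = rw.ObservationWindow(G=1.0, dimension=1)
        pot = rw.HarmonicPotential(0.7)
        uni = msd_ss_nonuniform(pot, w, lambda xc: 1.0, half_range=4.0)
        clus = msd_ss_nonuniform(pot, w, lambda xc: np.exp(-32 * xc * xc),
                                 half_range=4.0)
        # centred burrows explore the full window; off-window burrows only
        # contribute displacements clipped near one edge
        assert clus > uni
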