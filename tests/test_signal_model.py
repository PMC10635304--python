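"""Closed-form building blocks: Lorentzian lines, R_ex, R_eff, composer, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synthcest.params import (
    AcquisitionParams,
    ComponentSpectra,
    PoolParams,
    TissueState,
    ZSpectrum,
    ut_to_radps,
)
from synthcest.signal_model import (
    arex,
    cestr,
    compose_zspectrum,
    cos2theta,
    lorentzian_line,
    r1obs_from_components,
    reff,
    rex_slow,
    transient_signal,
)

W1 = ut_to_radps(1.0)


class TestLorentzianLine:
    @pytest.mark.parametrize(
        "offset, expected",
        [(3.5, 0.05), (4.5, 0.025), (2.5, 0.025)],  # peak; half-max at ±W/2
    )
    def test_peak_and_half_maximum(self, offset, expected):
        val = lorentzian_line(0.05, 2.0, 3.5, np.array([offset]))[0]
        assert val == pytest.approx(expected, abs=1e-15)

    def test_zero_amplitude_gives_zero_spectrum(self):
        off = np.linspace(-10, 10, 87)
        assert np.all(lorentzian_line(0.0, 3.0, 1.0, off) == 0.0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian_line(0.1, 0.0, 3.5, np.array([0.0]))


class TestRexSlow:
    def test_zero_fraction_gives_zero(self, acq):
        pool = PoolParams("amide", 0.0, 50.0, 3.5, R2s=30.0)
        assert np.all(rex_slow(pool, W1, acq.offsets_ppm) == 0.0)

    def test_on_resonance_value_matches_algebraic_reduction(self, acq):
        pool = PoolParams("amide", 1e-3, 50.0, 3.5, R2s=30.0)
        spec = rex_slow(pool, W1, acq.offsets_ppm)
        i = np.argmin(np.abs(acq.offsets_ppm - 3.5))
        expected = 1e-3 * 50.0 * W1**2 / (W1**2 + (30.0 + 50.0) * 50.0)
        assert spec[i] == pytest.approx(expected, rel=1e-12)
        # the on-resonance point is the maximum on a grid containing Δ
        assert i == np.argmax(spec)

    def test_negative_power_rejected(self, acq):
        pool = PoolParams("amide", 1e-3, 50.0, 3.5)
        with pytest.raises(ValueError):
            rex_slow(pool, -1.0, acq.offsets_ppm)


class TestReff:
    tissue = TissueState(R1obs=0.6, R1w=0.55, R2w=20.0)

    def test_far_offset_approaches_r1obs(self):
        val = reff(self.tissue, W1, np.array([250.0]))[0]
        assert val == pytest.approx(0.6, rel=1e-5)

    def test_on_resonance_equals_r2w(self):
        assert reff(self.tissue, W1, np.array([0.0]))[0] == pytest.approx(20.0)

    def test_45_degree_tilt_is_mean_of_rates(self):
        # offset where Δω (rad/s) equals ω1
        off_ppm = W1 / (400.0 * 2 * np.pi)
        val = reff(self.tissue, W1, np.array([off_ppm]))[0]
        assert val == pytest.approx((0.6 + 20.0) / 2, rel=1e-12)


class TestR1obs:
    @pytest.mark.parametrize("R1w,R1M,fm,r_MT,expected", [
        (0.55, 1.0, 0.0, 1.0, 0.55),    # no semisolid pool
        (0.55, 1.0, 0.1, 0.0, 0.55),    # zero scaling
        (0.7, 0.7, 0.12, 1.5, 0.7),     # equal rates: weighted mean is invariant
        (0.5, 1.0, 0.1, 1.0, (0.5 + 0.1) / 1.1),
    ])
    def test_pool_weighted_mean(self, R1w, R1M, fm, r_MT, expected):
        assert r1obs_from_components(R1w, R1M, fm, r_MT) == pytest.approx(expected)


def _components(offsets, tissue, apt_scale=1.0):
    apt = apt_scale * lorentzian_line(0.2, 1.0, 3.5, offsets)
    noe = lorentzian_line(0.3, 3.0, -3.5, offsets)
    amines = lorentzian_line(0.4, 4.0, 2.0, offsets)
    mt = lorentzian_line(1.0, 40.0, -2.3, offsets)
    return ComponentSpectra(
        offsets=offsets,
        Reff=reff(tissue, W1, offsets),
        Rex_apt=apt, Rex_noe=noe, Rex_amines=amines, Rex_mt=mt,
    )


class TestCompose:
    tissue = TissueState(R1obs=0.6, R1w=0.55, R2w=20.0, fm=0.1,
                         r_amines=1.2, r_MT=0.8)

    def test_empty_pools_give_pure_direct_saturation(self, acq):
        off = acq.offsets_ppm
        zeros = np.zeros_like(off)
        tissue = TissueState(R1obs=0.6, R1w=0.55, R2w=20.0, fm=0.1,
                             r_amines=0.0, r_MT=0.0)
        comp = ComponentSpectra(off, reff(tissue, W1, off), zeros, zeros,
                                zeros, zeros)
        z = compose_zspectrum(comp, tissue, W1)
        expected = 0.6 * cos2theta(off, W1) / reff(tissue, W1, off)
        np.testing.assert_allclose(z.values, expected, rtol=1e-12)

    def test_control_offset_signal_is_unity(self):
        off = np.array([-250.0, 250.0])
        zeros = np.zeros(2)
        comp = ComponentSpectra(off, reff(self.tissue, W1, off), zeros, zeros,
                                zeros, zeros)
        z = compose_zspectrum(comp, self.tissue, W1)
        np.testing.assert_allclose(z.values, 1.0, atol=1e-5)

    def test_label_reference_arex_identity(self, acq):
        """AREX of a composed pair with/without APT recovers the APT component

        scaled by (1+fm)/((1+r_MT·fm)·cos²θ) — the algebraic inverse of the
        composition — to machine precision.
        """
        off = acq.offsets_ppm
        comp_lab = _components(off, self.tissue)
        comp_ref = _components(off, self.tissue, apt_scale=0.0)
        z_lab = compose_zspectrum(comp_lab, self.tissue, W1)
        z_ref = compose_zspectrum(comp_ref, self.tissue, W1)
        mask = np.abs(off) > 0.2  # AREX undefined at exact resonance (S→0)
        got = arex(z_ref.values[mask], z_lab.values[mask],
                   self.tissue.R1obs, self.tissue.fm)
        c2 = cos2theta(off[mask], W1)
        expected = (comp_lab.Rex_apt[mask] * (1 + self.tissue.fm)
                    / ((1 + self.tissue.r_MT * self.tissue.fm) * c2))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_bounded_and_monotone_in_components(self, acq):
        off = acq.offsets_ppm
        comp = _components(off, self.tissue)
        z = compose_zspectrum(comp, self.tissue, W1)
        assert np.all(z.values >= 0) and np.all(z.values <= 1.0 + 1e-12)
        # adding a strictly positive component decreases S/S0 where positive
        comp2 = _components(off, self.tissue, apt_scale=2.0)
        z2 = compose_zspectrum(comp2, self.tissue, W1)
        gain = (comp.Rex_apt > 1e-12) & (np.abs(off) > 1e-9)  # S = 0 at 0 ppm
        assert np.all(z2.values[gain] < z.values[gain])

    def test_unphysical_denominator_rejected(self):
        off = np.array([1.0, 2.0, 3.0])
        zeros = np.zeros(3)
        comp = ComponentSpectra(off, -np.ones(3), zeros, zeros, zeros, zeros)
        with pytest.raises(ValueError, match="unphysical"):
            compose_zspectrum(comp, self.tissue, W1)


class TestMetrics:
    def test_cestr_of_equal_spectra_is_zero(self):
        s = np.array([0.5, 0.6, 0.7])
        assert np.all(cestr(s, s) == 0.0)

    def test_cestr_arithmetic_and_sign(self):
        assert cestr(np.array([0.60]), np.array([0.55]))[0] == pytest.approx(0.05)
        ref, lab = np.array([0.6, 0.5]), np.array([0.55, 0.52])
        assert np.all(cestr(ref, lab)[ref >= lab] >= 0)

    def test_cestr_grid_mismatch_rejected(self):
        z1 = ZSpectrum(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        z2 = ZSpectrum(np.array([1.0, 3.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            cestr(z1, z2)

    def test_arex_direct_arithmetic(self):
        val = arex(np.array([0.55]), np.array([0.5]), 0.6, 0.1)[0]
        assert val == pytest.approx(0.6 * 1.1 * (2.0 - 1.0 / 0.55), rel=1e-12)

    def test_arex_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            arex(np.array([0.5]), np.array([0.0]), 0.6)


class TestTransient:
    r1rho = np.array([1.0, 2.0, 5.0])
    s_ss = np.array([0.3, 0.6, 0.9])

    def test_zero_saturation_time_gives_unity(self):
        np.testing.assert_allclose(
            transient_signal(self.s_ss, self.r1rho, 0.0), 1.0)

    def test_long_saturation_reaches_steady_state(self):
        np.testing.assert_allclose(
            transient_signal(self.s_ss, self.r1rho, 1e4), self.s_ss)

    @given(st.floats(0.0, 20.0), st.floats(0.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_tp(self, t1, t2):
        lo, hi = sorted((t1, t2))
        a = transient_signal(self.s_ss, self.r1rho, lo)
        b = transient_signal(self.s_ss, self.r1rho, hi)
        assert np.all(b <= a + 1e-12)

    def test_five_seconds_is_effectively_steady_state(self):
        """At t_p = 5 s and R_1ρ ≥ 2 s⁻¹ the transient correction is < 1e−4,

        which justifies treating the 5 s continuous-wave acquisition as
        steady state throughout the synthesis platform.
        """
        r1rho = np.full(5, 2.0)
        s = np.linspace(0.1, 0.99, 5)
        assert np.max(np.abs(transient_signal(s, r1rho, 5.0) - s)) < 1e-4
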