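"""Corticothalamic core: sigmoid, dendritic filter, steady state, spectrum."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from ctmaug.core import (
    CTMGains,
    PhysioParams,
    SpectrumGrid,
    analytic_spectrum,
    default_gains,
    default_physio,
    dendritic_transfer,
    gains_from_physio,
    physio_from_gains,
    sigmoid_rate,
    sigmoid_slope,
    steady_state,
    transfer_function,
)
from ctmaug.errors import InfeasibleGains


class TestSigmoid:
    def test_midpoint_is_half_max(self):
        p = default_physio()
        assert sigmoid_rate(p.theta, p) == pytest.approx(p.Q_max / 2)

    def test_saturation_limits(self):
        p = default_physio()
        assert sigmoid_rate(10.0, p) == pytest.approx(p.Q_max)
        assert sigmoid_rate(-10.0, p) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-0.05, 0.05))
    def test_slope_matches_finite_difference(self, v):
        p = default_physio()
        h = 1e-7
        fd = (sigmoid_rate(v + h, p) - sigmoid_rate(v - h, p)) / (2 * h)
        assert sigmoid_slope(v, p) == pytest.approx(fd, rel=1e-5)

    def test_strictly_increasing(self):
        p = default_physio()
        v = np.linspace(-0.1, 0.1, 200)
        assert np.all(np.diff(sigmoid_rate(v, p)) > 0)


class TestDendriticFilter:
    def test_dc_gain_is_unity(self):
        assert dendritic_transfer(0.0, 83.0, 380.0) == pytest.approx(1 + 0j)

    def test_magnitude_closed_form(self):
        w = np.linspace(0, 500, 50)
        mag2 = np.abs(dendritic_transfer(w, 83.0, 380.0)) ** 2
        expect = 1.0 / ((1 + w**2 / 83.0**2) * (1 + w**2 / 380.0**2))
        np.testing.assert_allclose(mag2, expect, rtol=1e-12)
        # with a very fast rise rate the filter is first order: half power at alpha
        assert abs(dendritic_transfer(83.0, 83.0, 1e9)) ** 2 == pytest.approx(0.5, rel=1e-6)

    def test_magnitude_decreasing_and_bounded(self):
        w = np.linspace(0, 800, 300)
        mag = np.abs(dendritic_transfer(w, 83.0, 380.0))
        assert np.all(np.diff(mag) < 0) and mag.max() <= 1.0

    @pytest.mark.parametrize("w", [10.0, 60.0, 200.0])
    def test_matches_impulse_response_quadrature(self, w):
        """Frequency response equals the Fourier integral of the time kernel."""
        from ctmaug.simulate import impulse_response

        re_ = quad(lambda t: impulse_response(t, 83.0, 380.0) * np.cos(w * t),
                   0, 1.0, limit=300)[0]
        im_ = quad(lambda t: impulse_response(t, 83.0, 380.0) * np.sin(w * t),
                   0, 1.0, limit=300)[0]
        assert complex(re_, im_) == pytest.approx(
            dendritic_transfer(w, 83.0, 380.0), rel=1e-9)


class TestSteadyState:
    def test_decoupled_fixed_point(self):
        p = default_physio(nu_ee=0.0, nu_ei=0.0, nu_es=0.0, nu_se=0.0,
                           nu_sr=0.0, nu_re=0.0, nu_rs=0.0)
        ss = steady_state(p)
        assert ss.V_s == pytest.approx(p.nu_sn * p.phi_n0, rel=1e-10)
        assert ss.V_e == pytest.approx(0.0, abs=1e-12)
        assert ss.V_r == pytest.approx(0.0, abs=1e-12)

    def test_residual_below_tolerance(self):
        ss = steady_state(default_physio())
        assert ss.residual < 1e-10

    def test_rho_equals_sigmoid_derivative(self):
        p = default_physio()
        ss = steady_state(p)
        for V, rho in ((ss.V_e, ss.rho_e), (ss.V_r, ss.rho_r), (ss.V_s, ss.rho_s)):
            assert rho == pytest.approx(float(sigmoid_slope(V, p)), rel=1e-8)
            assert rho > 0


class TestGainComposition:
    def test_zero_thalamic_projection_kills_loops(self):
        p = default_physio(nu_es=0.0)
        g = gains_from_physio(p)
        assert g.G_ese == 0.0 and g.G_esre == 0.0

    def test_linearity_at_frozen_fixed_point(self):
        p = default_physio()
        ss = steady_state(p)
        g1 = gains_from_physio(p, steady=ss)
        p2 = default_physio(nu_ee=2 * p.nu_ee)
        g2 = gains_from_physio(p2, steady=ss)
        assert g2.G_ee == pytest.approx(2 * g1.G_ee, rel=1e-12)

    def test_round_trip_on_template(self):
        p = default_physio()
        g = gains_from_physio(p)
        g2 = gains_from_physio(physio_from_gains(g, p))
        for name in ("G_ee", "G_ei", "G_ese", "G_esre", "G_srs", "amplitude"):
            assert getattr(g2, name) == pytest.approx(getattr(g, name), rel=1e-6)

    def test_round_trip_on_default_gains(self, gains):
        g2 = gains_from_physio(physio_from_gains(gains))
        for name in ("G_ee", "G_ei", "G_ese", "G_esre", "G_srs", "amplitude"):
            assert getattr(g2, name) == pytest.approx(getattr(gains, name), rel=1e-6)

    def test_inversion_respects_sign_pattern(self, rng):
        """Whenever a prior-box draw is invertible, the recovered connection
        strengths carry the admissible excitatory/inhibitory signs."""
        tpl = default_physio()
        n_ok = 0
        for _ in range(15):
            g = CTMGains(
                G_ee=rng.uniform(0, 15), G_ei=-rng.uniform(2, 25),
                G_ese=rng.uniform(0.5, 40), G_esre=-rng.uniform(0, 40),
                G_srs=-rng.uniform(0.1, 10), amplitude=rng.uniform(0.5, 5))
            try:
                p = physio_from_gains(g, tpl)
            except InfeasibleGains:
                continue
            n_ok += 1
            assert p.nu_ei <= 0 and p.nu_sr <= 0
            assert min(p.nu_ee, p.nu_es, p.nu_se, p.nu_re, p.nu_rs, p.nu_sn) >= 0
            g2 = gains_from_physio(p)
            assert g2.G_ese == pytest.approx(g.G_ese, rel=1e-6)
        assert n_ok >= 3  # the generic regime must be broadly invertible

    def test_degenerate_zero_loop_gains(self):
        g0 = CTMGains(G_ee=0, G_ei=0, G_ese=0, G_esre=0, G_srs=0, amplitude=2.0)
        p0 = physio_from_gains(g0)
        assert p0.nu_ee == p0.nu_ei == p0.nu_es == 0.0
        back = gains_from_physio(p0)
        assert back.amplitude == pytest.approx(2.0, rel=1e-8)
        assert back.G_ese == back.G_srs == 0.0


class TestTransferFunction:
    def test_zero_gain_dc_value(self):
        g0 = CTMGains(G_ee=0, G_ei=0, G_ese=0, G_esre=0, G_srs=0, amplitude=1.0)
        assert abs(transfer_function(g0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_strong_cortical_inhibition_suppresses_dc(self):
        vals = [abs(transfer_function(
            CTMGains(G_ee=0, G_ei=-gei, G_ese=0, G_esre=0, G_srs=0), 0.0, 0.0))
            for gei in (0.0, 2.0, 8.0, 20.0)]
        assert np.all(np.diff(vals) < 0)

    def test_matches_symbolic_evaluation(self, rng):
        """Independent symbolic (sympy) evaluation of the transfer function."""
        import sympy as sp

        for _ in range(10):
            g = default_gains().replace(
                G_ee=float(rng.uniform(0, 8)), G_ei=-float(rng.uniform(2, 12)),
                G_ese=float(rng.uniform(0.5, 10)),
                G_esre=-float(rng.uniform(0.5, 10)),
                G_srs=-float(rng.uniform(0.1, 3)),
                amplitude=float(rng.uniform(0.5, 3)))
            k = float(rng.uniform(0, 30))
            w = float(rng.uniform(1, 250))
            I = sp.I
            L = 1 / ((1 - I * w / g.alpha) * (1 - I * w / g.beta))
            thal = 1 - g.G_srs * L**2
            cort = 1 - g.G_ei * L
            q2re2 = ((1 - I * w / g.gamma_e) ** 2
                     - (L * g.G_ee + (L**2 * g.G_ese + L**3 * g.G_esre)
                        * sp.exp(I * w * g.t0) / thal) / cort)
            phi = (g.amplitude * L**2 * sp.exp(I * w * g.t0 / 2)
                   / (thal * cort * (k**2 * g.r_e**2 + q2re2)))
            expect = complex(sp.N(phi, 20))
            assert transfer_function(g, k, w) == pytest.approx(expect, rel=1e-10)


class TestAnalyticSpectrum:
    def test_single_mode_sum_is_one_term(self, gains):
        freqs = np.linspace(2, 40, 60)
        grid = SpectrumGrid(m_max=0)
        ps = analytic_spectrum(gains, grid, freqs)
        dk = (2 * np.pi) ** 2 / (grid.Lx * grid.Ly)
        phi = transfer_function(gains, 0.0, 2 * np.pi * freqs)
        np.testing.assert_allclose(ps.power, np.abs(phi) ** 2 * dk, rtol=1e-12)

    def test_zero_gain_closed_form(self):
        g0 = CTMGains(G_ee=0, G_ei=0, G_ese=0, G_esre=0, G_srs=0, amplitude=2.0)
        grid = SpectrumGrid()
        ps = analytic_spectrum(g0, grid)
        w = 2 * np.pi * ps.freqs
        L2 = np.abs(dendritic_transfer(w, g0.alpha, g0.beta)) ** 2
        k2, wt = grid.mode_weights()
        denom = np.abs((1 - 1j * w / g0.gamma_e) ** 2
                       + k2[:, None] * g0.r_e ** 2) ** 2
        closed = g0.amplitude ** 2 * L2 ** 2 * (wt[:, None] / denom).sum(0)
        np.testing.assert_allclose(ps.power, closed, rtol=1e-10)

    def test_truncation_band_power_cauchy(self, gains):
        bps = [analytic_spectrum(gains, SpectrumGrid(m_max=m)).band_power((8, 30))
               for m in (2, 4, 8, 16)]
        diffs = [abs(bps[i + 1] - bps[i]) for i in range(3)]
        assert diffs[0] >= diffs[1] >= diffs[2]
        assert abs(bps[3] - bps[2]) / bps[2] < 1e-3

    def test_positive_spectra_across_stable_prior_draws(self, rng):
        """Spectrum positivity and unit DC dendritic gain over >=100 stable draws."""
        from ctmaug.fit import stability_check

        n_checked = 0
        while n_checked < 100:
            g = default_gains().replace(
                G_ee=float(rng.uniform(0, 15)), G_ei=-float(rng.uniform(0, 20)),
                G_ese=float(rng.uniform(0, 20)), G_esre=-float(rng.uniform(0, 20)),
                G_srs=-float(rng.uniform(0, 6)),
                alpha=float(rng.uniform(30, 150)), t0=float(rng.uniform(0.07, 0.13)))
            if not stability_check(g):
                continue
            ps = analytic_spectrum(g)
            assert np.all(ps.power > 0) and np.all(np.isfinite(ps.power))
            assert dendritic_transfer(0.0, g.alpha, g.beta) == pytest.approx(1 + 0j)
            n_checked += 1


class TestParameterEffects:
    """Directional spectral effects of the physiological parameters."""

    def _peak(self, g, lo=7.0, hi=14.0):
        ps = analytic_spectrum(g, freqs=np.arange(lo, hi, 0.02))
        i = np.argmax(ps.power)
        return ps.freqs[i], ps.power[i]

    @staticmethod
    def _beta_peak(g):
        """First local maximum above the alpha shoulder (the beta resonance)."""
        from scipy.signal import find_peaks

        f = np.arange(14.0, 34.0, 0.02)
        p = analytic_spectrum(g, freqs=f).power
        peaks, _ = find_peaks(np.log10(p))
        assert peaks.size >= 1
        return f[peaks[0]]

    def test_shorter_loop_delay_raises_resonance_frequencies(self, gains):
        f0, _ = self._peak(gains)
        f1, _ = self._peak(gains.replace(t0=gains.t0 - 0.010))
        assert f1 > f0
        # the beta resonance (second harmonic of the loop) shifts up as well
        assert self._beta_peak(gains.replace(t0=gains.t0 - 0.010)) \
            > self._beta_peak(gains)

    def test_lower_damping_lowers_and_weakens_alpha_peak(self, gains):
        f0, h0 = self._peak(gains)
        f1, h1 = self._peak(gains.replace(gamma_e=gains.gamma_e - 26.0))
        assert f1 < f0 and h1 < h0

    def test_slower_synaptic_decay_cuts_high_band_power_most(self, gains):
        ps0 = analytic_spectrum(gains)
        ps1 = analytic_spectrum(gains.replace(alpha=gains.alpha - 23.0))
        assert ps1.band_power((8, 30)) < ps0.band_power((8, 30))
        lo0, lo1 = (p.band_power((8, 20)) for p in (ps0, ps1))
        hi0, hi1 = (p.band_power((20, 30)) for p in (ps0, ps1))
        assert (1 - hi1 / hi0) > (1 - lo1 / lo0)


class TestValidation:
    def test_sign_invariants_enforced(self):
        with pytest.raises(ValueError):
            CTMGains(G_ei=1.0)
        with pytest.raises(ValueError):
            CTMGains(alpha=300.0, beta=100.0)
        with pytest.raises(ValueError):
            PhysioParams(nu_ei=0.1)

    def test_spectrum_rejects_bad_frequency_grids(self, gains):
        with pytest.raises(ValueError):
            analytic_spectrum(gains, freqs=np.array([5.0, 4.0]))
        with pytest.raises(ValueError):
            analytic_spectrum(gains, freqs=np.array([0.0, 1.0]))
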