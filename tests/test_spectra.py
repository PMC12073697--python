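"""Dielectric sweep processing: HN evaluation, derivative loss, peaks, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdkit.errors import (
    BoundaryPeakError,
    InsufficientDataError,
    InvalidModelError,
    OrderOfOperationsError,
)
from asdkit.spectra import (
    DielectricSpectrum,
    HNFit,
    HNMode,
    fit_hn,
    hn_eval,
    hn_peak_tau,
    hn_shape_factor,
    log_derivative,
    modulus_transform,
    normalize_loss,
    pick_peak_tau,
)

from conftest import debye_spectrum


def hn_oracle(eps_inf, modes, f):
    """Trigonometric-form HN evaluation, independent of complex arithmetic.

    (1 + (i w tau)^a)^-b written out via the polar form of
    1 + (w tau)^a (cos(a pi/2) + i sin(a pi/2)).
    """
    w = 2 * np.pi * np.asarray(f, dtype=float)
    er = np.full_like(w, float(eps_inf))
    ei = np.zeros_like(w)
    for m in modes:
        wt = (w * m.tau_hn) ** m.alpha_hn
        re = 1.0 + wt * math.cos(m.alpha_hn * math.pi / 2)
        im = wt * math.sin(m.alpha_hn * math.pi / 2)
        r = np.hypot(re, im) ** (-m.beta_hn)
        th = -m.beta_hn * np.arctan2(im, re)
        er = er + m.delta_eps * r * np.cos(th)
        ei = ei - m.delta_eps * r * np.sin(th)
    return er, ei


class TestHNEval:
    def test_static_limit_is_eps_inf_plus_delta_eps(self):
        m = HNMode(delta_eps=2.0, tau_hn=1.0, alpha_hn=1.0, beta_hn=1.0)
        er, ei = hn_eval(3.0, [m], [1e-6])
        assert er[0] == pytest.approx(5.0, abs=1e-6)
        assert ei[0] == pytest.approx(0.0, abs=1e-4)

    def test_debye_at_unit_omega_tau(self):
        m = HNMode(delta_eps=2.0, tau_hn=1.0 / (2 * np.pi), alpha_hn=1.0,
                   beta_hn=1.0)
        er, ei = hn_eval(3.0, [m], [1.0])
        assert er[0] == pytest.approx(4.0, rel=1e-12)
        assert ei[0] == pytest.approx(1.0, rel=1e-12)

    def test_matches_trigonometric_oracle(self):
        m = HNMode(delta_eps=1.0, tau_hn=1e-3, alpha_hn=0.8, beta_hn=0.6)
        f = np.array([500.0])
        er, ei = hn_eval(2.0, [m], f)
        oer, oei = hn_oracle(2.0, [m], f)
        assert er[0] == pytest.approx(oer[0], rel=1e-12)
        assert ei[0] == pytest.approx(oei[0], rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(de=st.floats(0.1, 10), lt=st.floats(-6, 1),
           a=st.floats(0.2, 1.0), b=st.floats(0.2, 1.0))
    def test_oracle_equivalence_on_random_parameters(self, de, lt, a, b):
        m = HNMode(delta_eps=de, tau_hn=10.0 ** lt, alpha_hn=a, beta_hn=b)
        f = np.logspace(-1, 6, 15)
        er, ei = hn_eval(1.5, [m], f)
        oer, oei = hn_oracle(1.5, [m], f)
        np.testing.assert_allclose(er, oer, rtol=1e-12)
        np.testing.assert_allclose(ei, oei, rtol=1e-12, atol=1e-15)

    def test_modes_are_additive_and_loss_nonnegative(self):
        m1 = HNMode(delta_eps=2.0, tau_hn=1e-1, alpha_hn=0.7, beta_hn=0.9)
        m2 = HNMode(delta_eps=1.0, tau_hn=1e-4, alpha_hn=0.9, beta_hn=0.5)
        f = np.logspace(-2, 6, 33)
        er12, ei12 = hn_eval(2.0, [m1, m2], f)
        er1, ei1 = hn_eval(2.0, [m1], f)
        er2, ei2 = hn_eval(0.0, [m2], f)
        np.testing.assert_allclose(er12, er1 + er2, rtol=1e-12)
        np.testing.assert_allclose(ei12, ei1 + ei2, rtol=1e-12)
        assert np.all(ei12 >= 0)
        # single-mode eps' is non-increasing with frequency
        assert np.all(np.diff(er1) <= 1e-12)

    def test_empty_model_rejected(self):
        with pytest.raises(InvalidModelError):
            hn_eval(None, [], [1.0])

    @pytest.mark.parametrize("bad", [
        dict(delta_eps=-1, tau_hn=1, alpha_hn=0.5, beta_hn=0.5),
        dict(delta_eps=1, tau_hn=0, alpha_hn=0.5, beta_hn=0.5),
        dict(delta_eps=1, tau_hn=1, alpha_hn=1.2, beta_hn=0.5),
        dict(delta_eps=1, tau_hn=1, alpha_hn=0.5, beta_hn=0.0),
    ])
    def test_mode_invariants(self, bad):
        with pytest.raises(InvalidModelError):
            HNMode(**bad)


class TestLogDerivative:
    def test_constant_eps_real_gives_zero(self):
        f = np.logspace(-1, 3, 41)
        s = DielectricSpectrum(100.0, f, np.full_like(f, 4.0), np.zeros_like(f))
        s = log_derivative(s)
        np.testing.assert_allclose(s.eps_der, 0.0, atol=1e-12)

    def test_debye_closed_form_within_one_percent(self):
        # eps_der(w) = (pi/2) de 2(wt)^2/(1+(wt)^2)^2 -> pi de/4 at wt=1
        de, tau = 2.0, 1.0 / (2 * np.pi)
        s = log_derivative(debye_spectrum(delta_eps=de, tau=tau, ppd=20))
        i = np.argmin(np.abs(s.frequencies - 1.0))
        assert s.eps_der[i] == pytest.approx(np.pi * de / 4, rel=0.01)
        wt = 2 * np.pi * s.frequencies * tau
        analytic = (np.pi / 2) * de * 2 * wt**2 / (1 + wt**2) ** 2
        inner = slice(5, -5)
        np.testing.assert_allclose(s.eps_der[inner], analytic[inner], rtol=0.015)

    def test_ohmic_conductivity_is_invisible(self):
        clean = log_derivative(debye_spectrum())
        conducting = log_derivative(debye_spectrum(conductivity=5.0))
        np.testing.assert_array_equal(clean.eps_der, conducting.eps_der)

    @pytest.mark.parametrize("alpha", [0.6, 0.8, 1.0])
    @pytest.mark.parametrize("beta", [0.5, 1.0])
    def test_peak_position_matches_eps_imag(self, alpha, beta):
        f = np.logspace(-3, 3, 121)
        er, ei = hn_eval(3.0, [HNMode(delta_eps=2.0, tau_hn=1e-2,
                                      alpha_hn=alpha, beta_hn=beta)], f)
        s = log_derivative(DielectricSpectrum(100.0, f, er, ei))
        assert abs(int(np.argmax(s.eps_der)) - int(np.argmax(ei))) <= 1

    def test_too_few_points_rejected(self):
        f = np.logspace(0, 1, 5)
        s = DielectricSpectrum(100.0, f, np.full(5, 2.0), np.zeros(5))
        with pytest.raises(InsufficientDataError):
            log_derivative(s, smoothing_window=7)


class TestNormalizeAndModulus:
    def test_normalize_identities(self, debye):
        s = debye.with_eps_der(np.zeros(debye.n_points))
        np.testing.assert_array_equal(normalize_loss(s), 0.0)
        s = debye.with_eps_der(debye.eps_real.copy())
        np.testing.assert_allclose(normalize_loss(s), 1.0)

    def test_normalize_requires_derivative(self, debye):
        with pytest.raises(OrderOfOperationsError):
            normalize_loss(debye)

    def test_normalized_peak_shifts_to_higher_frequency(self):
        s = log_derivative(debye_spectrum(tau=1e-1))
        ratio = normalize_loss(s)
        assert np.argmax(ratio) >= np.argmax(s.eps_der)

    def test_modulus_of_known_values(self):
        f = np.logspace(0, 1, 5)
        s = DielectricSpectrum(100.0, f, np.full(5, 1.0), np.zeros(5))
        mr, mi = modulus_transform(s)
        np.testing.assert_allclose(mr, 1.0)
        np.testing.assert_allclose(mi, 0.0)
        s = DielectricSpectrum(100.0, f, np.full(5, 3.0), np.full(5, 4.0))
        mr, mi = modulus_transform(s)
        np.testing.assert_allclose(mr, 0.12)
        np.testing.assert_allclose(mi, 0.16)

    def test_conductivity_peak_in_modulus_absent_in_derivative_loss(self):
        # d.c. conductivity creates a low-frequency M'' peak while the
        # derivative loss keeps only the relaxation peak
        s = debye_spectrum(tau=1e-3, conductivity=1.0, f_lo=-2, f_hi=5)
        s = log_derivative(s)
        _, mi = modulus_transform(s)
        from scipy.signal import find_peaks
        m_peaks = find_peaks(mi)[0]
        d_peaks = find_peaks(s.eps_der)[0]
        assert len(m_peaks) >= 2   # conductivity peak + relaxation peak
        assert len(d_peaks) == 1


class TestPeakPicking:
    def test_paper_frequency_conversion(self):
        # a maximum at 14 Hz corresponds to log10 tau = -1.94
        pt = pick_peak_tau(*self._curve(14.0), temperature=90.0)
        assert pt.log10_tau == pytest.approx(-1.94, abs=0.005)

    def test_unit_conversion_at_one_over_two_pi(self):
        pt = pick_peak_tau(*self._curve(1.0 / (2 * np.pi)), temperature=90.0)
        assert pt.log10_tau == pytest.approx(0.0, abs=1e-6)

    def test_debye_peak_recovered_within_half_grid_step(self):
        tau = 1e-4
        s = debye_spectrum(tau=tau, f_lo=0, f_hi=6, ppd=10)
        pt = pick_peak_tau(s.frequencies, s.eps_imag, 100.0)
        assert abs(pt.log10_tau - np.log10(tau)) < 0.5 / 10

    def test_boundary_peak_rejected(self):
        f = np.logspace(0, 2, 21)
        y = np.linspace(0, 1, 21)   # maximum at the edge
        with pytest.raises(BoundaryPeakError):
            pick_peak_tau(f, y, 100.0)

    @staticmethod
    def _curve(f_max):
        f = np.logspace(np.log10(f_max) - 2, np.log10(f_max) + 2, 81)
        er, ei = hn_eval(3.0, [HNMode(delta_eps=1.0, tau_hn=1 / (2 * np.pi * f_max),
                                      alpha_hn=1.0, beta_hn=1.0)], f)
        return f, ei


class TestHNFit:
    def test_single_mode_recovery_within_one_percent(self, single_hn_spectrum):
        spec, truth, eps_inf = single_hn_spectrum
        fit = fit_hn(spec, n_modes=1)
        m = fit.modes[0]
        assert fit.converged
        assert m.delta_eps == pytest.approx(truth.delta_eps, rel=0.01)
        assert m.tau_hn == pytest.approx(truth.tau_hn, rel=0.01)
        assert m.alpha_hn == pytest.approx(truth.alpha_hn, rel=0.01)
        assert m.beta_hn == pytest.approx(truth.beta_hn, rel=0.01)
        assert fit.eps_inf == pytest.approx(eps_inf, rel=0.01)

    def test_two_mode_taus_within_five_percent(self):
        # tau ratio 100, strength ratio 4
        m1 = HNMode(delta_eps=4.0, tau_hn=1e-1, alpha_hn=0.8, beta_hn=0.9)
        m2 = HNMode(delta_eps=1.0, tau_hn=1e-3, alpha_hn=0.85, beta_hn=0.8)
        f = np.logspace(-2, 5, 71)
        er, ei = hn_eval(3.0, [m1, m2], f)
        fit = fit_hn(DielectricSpectrum(100.0, f, er, ei), n_modes=2)
        assert fit.modes[0].tau_hn == pytest.approx(1e-1, rel=0.05)
        assert fit.modes[1].tau_hn == pytest.approx(1e-3, rel=0.05)
        assert fit.modes[0].tau_hn > fit.modes[1].tau_hn

    def test_self_consistency_on_model_generated_data(self, single_hn_spectrum):
        spec, truth, _ = single_hn_spectrum
        from asdkit.spectra import hn_eps_der
        exact = spec.with_eps_der(hn_eps_der(0.0, [truth], spec.frequencies))
        fit = fit_hn(exact, n_modes=1)
        assert fit.residual_rms < 1e-10

    def test_fit_idempotence(self, single_hn_spectrum):
        spec, _, _ = single_hn_spectrum
        fit1 = fit_hn(spec, n_modes=1)
        from asdkit.spectra import hn_eps_der
        regen = spec.with_eps_der(
            hn_eps_der(fit1.eps_inf, fit1.modes, spec.frequencies))
        fit2 = fit_hn(regen, n_modes=1)
        assert fit2.modes[0].tau_hn == pytest.approx(fit1.modes[0].tau_hn,
                                                     rel=1e-4)
        assert fit2.modes[0].delta_eps == pytest.approx(
            fit1.modes[0].delta_eps, rel=1e-4)

    def test_narrow_window_rejected(self, single_hn_spectrum):
        spec, _, _ = single_hn_spectrum
        with pytest.raises(InsufficientDataError):
            fit_hn(spec, freq_window=(1.0, 5.0))


class TestHNPeakTau:
    def test_debye_limit_exact(self):
        assert hn_shape_factor(1.0, 1.0) == pytest.approx(1.0, rel=1e-14)

    def test_closed_form_matches_numeric_maximisation(self):
        m = HNMode(delta_eps=1.0, tau_hn=1e-3, alpha_hn=0.8, beta_hn=0.6)
        fit = HNFit(eps_inf=0.0, modes=(m,), residual_rms=0.0, converged=True,
                    temperature=100.0)
        pt = hn_peak_tau(fit, 0)
        f = np.logspace(-1, 7, 4_000_001)
        _, ei = hn_eval(0.0, [m], f)
        brute = np.log10(1.0 / (2 * np.pi * f[np.argmax(ei)]))
        assert pt.log10_tau == pytest.approx(brute, abs=5e-5)

    def test_two_mode_labels_follow_tau_ordering(self):
        m1 = HNMode(delta_eps=1.0, tau_hn=1e-1, alpha_hn=0.9, beta_hn=0.9)
        m2 = HNMode(delta_eps=1.0, tau_hn=1e-4, alpha_hn=0.9, beta_hn=0.9)
        fit = HNFit(eps_inf=0.0, modes=(m1, m2), residual_rms=0.0,
                    converged=True, temperature=100.0)
        p1, p2 = hn_peak_tau(fit, 0), hn_peak_tau(fit, 1)
        assert p1.label == "alpha1" and p2.label == "alpha2"
        assert p1.log10_tau > p2.log10_tau
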