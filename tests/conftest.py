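import numpy as np
import pytest

from asdkit.dynamics import VTFHParams
from asdkit.spectra import DielectricSpectrum, HNMode, hn_eval
from asdkit.synthetic import SyntheticMode, SyntheticScenario


def debye_spectrum(delta_eps=2.0, tau=1e-2, eps_inf=3.0, f_lo=-3, f_hi=3,
                   ppd=20, temperature=100.0, conductivity=0.0):
    """Noiseless Debye isotherm on a uniform log-frequency grid."""
    n = int(round((f_hi - f_lo) * ppd)) + 1
    f = np.logspace(f_lo, f_hi, n)
    er, ei = hn_eval(eps_inf, [HNMode(delta_eps=delta_eps, tau_hn=tau,
                                      alpha_hn=1.0, beta_hn=1.0)], f)
    if conductivity:
        ei = ei + conductivity / (2.0 * np.pi * f)
    return DielectricSpectrum(temperature=temperature, frequencies=f,
                              eps_real=er, eps_imag=ei)


@pytest.fixture
def debye():
    return debye_spectrum()


@pytest.fixture
def single_hn_spectrum():
    """One asymmetric HN mode over the full sweep, noiseless."""
    f = np.logspace(-1, 6, 71)
    truth = HNMode(delta_eps=1.5, tau_hn=1e-3, alpha_hn=0.85, beta_hn=0.7)
    er, ei = hn_eval(2.5, [truth], f)
    spec = DielectricSpectrum(temperature=100.0, frequencies=f,
                              eps_real=er, eps_imag=ei)
    return spec, truth, 2.5


@pytest.fixture
def two_mode_scenario():
    """Split alpha relaxation patterned on a high-drug-content blend."""
    return SyntheticScenario(
        seed=2,
        modes=(SyntheticMode(vtfh=VTFHParams(b_K=2356, t0_C=2.0),
                             delta_eps0=1.0, alpha_hn=0.9, beta_hn=0.9),
               SyntheticMode(vtfh=VTFHParams(b_K=1759, t0_C=11.2),
                             delta_eps0=4.0, alpha_hn=0.85, beta_hn=0.8)),
        temperatures_C=tuple(float(t) for t in range(95, 136, 5)),
        c_cond=1.0)
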