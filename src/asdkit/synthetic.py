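"""Ground-truthed synthetic instrument recordings.

Emulates the two kinds of raw data the pipeline consumes, with known
ground truth so that every fitting stage can be validated as a round
trip:

* dielectric isotherm sweeps - sums of 1-2 Havriliak-Negami modes whose
  relaxation times follow per-mode VTFH laws, on top of ohmic
  conductivity (``c_cond / omega`` in the loss only) and an electrode-
  polarisation power law ``a (i omega)^(-s)`` that feeds both parts, with
  optional multiplicative noise;
* MDSC-style thermograms - logistic Cp steps plus Gaussian exo/endo peaks
  of prescribed integrated enthalpy on affine baselines.

Every generator is a pure function of its scenario: the same seed gives
bit-identical arrays.  What the generators do NOT emulate: capacitance
drift from powder coalescence, Maxwell-Wagner interfacial polarisation,
moisture loss, or crystallisation kinetics - amplitudes here follow
prescribed paths rather than nucleation-and-growth laws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calorimetry import Thermogram
from .dynamics import KELVIN, VTFHParams, vtfh_eval
from .errors import DomainError, ScenarioError
from .spectra import DielectricSpectrum, HNMode, hn_eval, hn_shape_factor

__all__ = [
    "SyntheticMode",
    "SyntheticScenario",
    "ThermoScenario",
    "gen_spectrum",
    "gen_isotherm_series",
    "gen_thermogram",
    "gen_recrystallization_series",
]


@dataclass(frozen=True)
class SyntheticMode:
    """Ground truth for one relaxation mode.

    The HN shape (alpha, beta) is temperature-independent; the dielectric
    strength is affine in temperature,
    ``delta_eps(T) = delta_eps0 + delta_eps_slope * (T - 100 degC)``.
    The VTFH law governs the peak relaxation time tau_max (the quantity
    plotted in Arrhenius diagrams); the HN time handed to the forward
    model is ``tau_HN = tau_max * shape_factor`` so that analysing the
    generated spectra recovers exactly the prescribed VTFH law.
    """

    vtfh: VTFHParams
    delta_eps0: float = 2.0
    delta_eps_slope: float = 0.0
    alpha_hn: float = 0.85
    beta_hn: float = 0.9

    def delta_eps(self, temperature_C: float) -> float:
        return self.delta_eps0 + self.delta_eps_slope * (temperature_C - 100.0)

    def hn_mode(self, temperature_C: float) -> HNMode:
        tau_max = 10.0 ** vtfh_eval(self.vtfh, temperature_C)
        tau = tau_max * hn_shape_factor(self.alpha_hn, self.beta_hn)
        return HNMode(delta_eps=self.delta_eps(temperature_C), tau_hn=tau,
                      alpha_hn=self.alpha_hn, beta_hn=self.beta_hn)


@dataclass(frozen=True)
class SyntheticScenario:
    """Forward model of a broadband dielectric isotherm series.

    Defaults mirror the measurement conditions the pipeline targets:
    sweeps from 0.1 Hz to 1 MHz at 10 points per decade, isotherms from
    85 to 150 degC in 5 degC steps.  ``c_cond`` collapses the ohmic term
    sigma/(eps0 omega) into a single loss amplitude ``c_cond / omega``;
    ``ep_amplitude``/``ep_exponent`` parametrise the electrode
    polarisation power law (0 < s < 1); ``noise_rel_sd`` is the relative
    s.d. of the multiplicative noise.
    """

    seed: int = 0
    f_min_hz: float = 0.1
    f_max_hz: float = 1e6
    points_per_decade: int = 10
    temperatures_C: tuple[float, ...] = tuple(float(t) for t in range(85, 151, 5))
    eps_inf: float = 3.0
    modes: tuple[SyntheticMode, ...] = ()
    c_cond: float = 0.0
    ep_amplitude: float = 0.0
    ep_exponent: float = 0.8
    noise_rel_sd: float = 0.0

    def __post_init__(self):
        if self.c_cond < 0 or self.ep_amplitude < 0 or self.noise_rel_sd < 0:
            raise ScenarioError("amplitudes must be non-negative")
        if self.ep_amplitude > 0 and not (0 < self.ep_exponent < 1):
            raise ScenarioError("electrode-polarisation exponent must be in (0, 1)")
        if self.f_min_hz <= 0 or self.f_max_hz <= self.f_min_hz:
            raise ScenarioError("need 0 < f_min < f_max")

    @property
    def frequencies(self) -> np.ndarray:
        lo, hi = math.log10(self.f_min_hz), math.log10(self.f_max_hz)
        n = int(round((hi - lo) * self.points_per_decade)) + 1
        return np.logspace(lo, hi, n)


def _rng_for(seed: int, temperature_C: float, salt: int = 0) -> np.random.Generator:
    # sub-stream per isotherm so series members are independent yet
    # reproducible; temperature keyed to 0.01 degC
    key = [int(seed), int(round(temperature_C * 100)) & 0x7FFFFFFF, int(salt)]
    return np.random.default_rng(np.random.SeedSequence(key))


def gen_spectrum(scenario: SyntheticScenario, temperature_C: float,
                 salt: int = 0) -> DielectricSpectrum:
    """Generate one isotherm of the scenario's forward model."""
    for m in scenario.modes:
        if temperature_C + KELVIN <= m.vtfh.t0_K:
            raise DomainError(
                f"isotherm {temperature_C} degC at or below a mode's Vogel "
                f"temperature {m.vtfh.t0_C} degC")
    f = scenario.frequencies
    omega = 2.0 * np.pi * f
    hn_modes = [m.hn_mode(temperature_C) for m in scenario.modes]
    er, ei = hn_eval(scenario.eps_inf, hn_modes, f)
    if scenario.ep_amplitude > 0:
        s = scenario.ep_exponent
        mag = scenario.ep_amplitude * omega ** (-s)
        er = er + mag * math.cos(0.5 * math.pi * s)
        ei = ei + mag * math.sin(0.5 * math.pi * s)
    if scenario.c_cond > 0:
        ei = ei + scenario.c_cond / omega
    if scenario.noise_rel_sd > 0:
        rng = _rng_for(scenario.seed, temperature_C, salt)
        er = er * (1.0 + scenario.noise_rel_sd * rng.standard_normal(f.size))
        ei = ei * (1.0 + scenario.noise_rel_sd * rng.standard_normal(f.size))
    return DielectricSpectrum(temperature=float(temperature_C), frequencies=f,
                              eps_real=er, eps_imag=ei)


def gen_isotherm_series(scenario: SyntheticScenario) -> list[DielectricSpectrum]:
    """Generate the full temperature series of the scenario."""
    if len(scenario.temperatures_C) < 2:
        raise ScenarioError("need >= 2 isotherm temperatures")
    return [gen_spectrum(scenario, t) for t in scenario.temperatures_C]


# ---------------------------------------------------------------------------
# thermograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermoScenario:
    """Forward model of a reversible-Cp thermogram.

    ``transitions`` are (midpoint degC, delta_cp, width degC) logistic
    steps - slope delta_cp/(4 width) at the midpoint; ``peaks`` are
    (center degC, enthalpy J g^-1, width degC, sign) Gaussians whose
    integral over temperature equals the signed enthalpy.
    """

    seed: int = 0
    t_min_C: float = 20.0
    t_max_C: float = 180.0
    step_C: float = 0.1
    baseline_level: float = 1.2
    baseline_slope: float = 0.0
    transitions: tuple[tuple[float, float, float], ...] = ()
    peaks: tuple[tuple[float, float, float, int], ...] = ()
    noise_sd: float = 0.0

    def __post_init__(self):
        for _, dcp, w in self.transitions:
            if w <= 0 or dcp <= 0:
                raise ScenarioError("transition widths and steps must be positive")
        for _, _, w, sign in self.peaks:
            if w <= 0 or sign not in (-1, 1):
                raise ScenarioError("peak widths positive, sign in {-1, +1}")
        mids = sorted((m, w) for m, _, w in self.transitions)
        for (m1, w1), (m2, w2) in zip(mids, mids[1:]):
            if m2 - m1 < 4.0 * (w1 + w2):
                raise ScenarioError(
                    f"transitions at {m1} and {m2} degC overlap")


def gen_thermogram(scenario: ThermoScenario) -> Thermogram:
    """Generate the thermogram of the scenario."""
    t = np.arange(scenario.t_min_C, scenario.t_max_C + scenario.step_C / 2,
                  scenario.step_C)
    cp = scenario.baseline_level + scenario.baseline_slope * (t - t[0])
    for mid, dcp, w in scenario.transitions:
        cp = cp + dcp / (1.0 + np.exp(-(t - mid) / w))
    for center, enthalpy, w, sign in scenario.peaks:
        cp = cp + sign * enthalpy / (w * math.sqrt(2.0 * math.pi)) * \
            np.exp(-0.5 * ((t - center) / w) ** 2)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        cp = cp + scenario.noise_sd * rng.standard_normal(t.size)
    return Thermogram(temperatures=t, rev_cp=cp)


# ---------------------------------------------------------------------------
# isothermal recrystallisation series
# ---------------------------------------------------------------------------

def gen_recrystallization_series(
        scenario: SyntheticScenario,
        times_s: np.ndarray | list,
        composition_path,
        references: dict[float, VTFHParams],
        temperature_C: float,
        alpha1_composition: float | None = None,
) -> list[tuple[float, DielectricSpectrum]]:
    """Time series of spectra at one temperature under recrystallisation.

    ``composition_path`` maps time (s) to the drug weight fraction
    remaining in the fast (alpha2) amorphous phase; it must be monotone
    non-increasing.  At each time the alpha2 relaxation time is set from
    the piecewise-linear interpolation of the ``references`` VTFH family
    at the current composition (the same interpolation the composition
    readback inverts), and its strength is scaled by the fraction of the
    drug still amorphous.  The slow alpha1 mode, when present, keeps the
    fixed composition ``alpha1_composition``.
    """
    if not (1 <= len(scenario.modes) <= 2):
        raise ScenarioError("scenario must define 1 or 2 modes")
    times = [float(t) for t in times_s]
    xs_path = [float(composition_path(t)) for t in times]
    if any(b > a + 1e-12 for a, b in zip(xs_path, xs_path[1:])):
        raise ScenarioError("composition path must be non-increasing")
    ref_x = np.array(sorted(references))
    ref_lt = np.array([vtfh_eval(references[x], temperature_C) for x in ref_x])

    def log_tau_at(x: float) -> float:
        return float(np.interp(x, ref_x, ref_lt))

    x0 = xs_path[0]
    fast = scenario.modes[-1]
    slow = scenario.modes[0] if len(scenario.modes) == 2 else None
    out = []
    for salt, (t, x) in enumerate(zip(times, xs_path)):
        # fraction of the initial drug load still amorphous; the blend
        # composition x follows from crystallising (1-u) of the drug
        u = 1.0 - (x0 - x) / (x0 * (1.0 - x)) if x < x0 else 1.0
        hn_modes = []
        if slow is not None:
            x1 = alpha1_composition if alpha1_composition is not None else x0 - 0.2
            hn_modes.append(HNMode(delta_eps=slow.delta_eps(temperature_C),
                                   tau_hn=10.0 ** log_tau_at(x1),
                                   alpha_hn=slow.alpha_hn,
                                   beta_hn=slow.beta_hn))
        de_fast = fast.delta_eps(temperature_C) * max(u, 1e-6)
        hn_modes.append(HNMode(delta_eps=de_fast,
                               tau_hn=10.0 ** log_tau_at(x),
                               alpha_hn=fast.alpha_hn, beta_hn=fast.beta_hn))
        f = scenario.frequencies
        omega = 2.0 * np.pi * f
        er, ei = hn_eval(scenario.eps_inf, hn_modes, f)
        if scenario.ep_amplitude > 0:
            s = scenario.ep_exponent
            mag = scenario.ep_amplitude * omega ** (-s)
            er = er + mag * math.cos(0.5 * math.pi * s)
            ei = ei + mag * math.sin(0.5 * math.pi * s)
        if scenario.c_cond > 0:
            ei = ei + scenario.c_cond / omega
        if scenario.noise_rel_sd > 0:
            rng = _rng_for(scenario.seed, temperature_C, salt + 1)
            er = er * (1.0 + scenario.noise_rel_sd * rng.standard_normal(f.size))
            ei = ei * (1.0 + scenario.noise_rel_sd * rng.standard_normal(f.size))
        out.append((t, DielectricSpectrum(temperature=float(temperature_C),
                                          frequencies=f, eps_real=er,
                                          eps_imag=ei)))
    return out
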