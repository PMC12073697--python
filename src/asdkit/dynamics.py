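"""Relaxation dynamics: VTFH laws, dynamic Tg, fragility, composition.

The temperature evolution of structural relaxation times in glass-forming
liquids is super-Arrhenius and is described by the
Vogel-Tammann-Fulcher-Hesse (VTFH) law

    log10 tau(T) = log10 tau_inf + B / (ln(10) (T - T0))

with T in Kelvin.  The dynamic glass transition Tg_DRS is the temperature
at which tau reaches 100 s, and the steepness ("fragility") index

    m = B Tg / (ln(10) (Tg - T0)^2)

quantifies the departure from Arrhenius behaviour (m ~ 16 for strong
liquids, up to ~170 for fragile ones).  Because relaxation times at a
fixed temperature vary monotonically with the drug content of a
drug/polymer blend, a measured log10(tau) can be inverted against a
family of reference VTFH curves to estimate the composition of the
relaxing amorphous phase - the key trick used to follow isothermal
recrystallisation dielectrically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitFailureError, InsufficientDataError
from .spectra import (
    DielectricSpectrum,
    HNFit,
    RelaxationPoint,
    fit_hn,
    hn_peak_tau,
    log_derivative,
)

__all__ = [
    "VTFHParams",
    "DerivedDynamics",
    "CompositionEstimate",
    "vtfh_eval",
    "fit_vtfh",
    "tg_from_vtfh",
    "fragility_index",
    "derived_dynamics",
    "estimate_composition",
    "track_recrystallization",
    "TAU_GLASS_S",
    "KELVIN",
]

LN10 = math.log(10.0)
#: deg C -> K offset used everywhere in the package.
KELVIN = 273.15
#: Conventional relaxation time defining the dynamic glass transition.
TAU_GLASS_S = 100.0
#: Fragility range observed between strong and fragile glass formers.
FRAGILITY_RANGE = (16.0, 170.0)


@dataclass(frozen=True)
class VTFHParams:
    """VTFH parameters; B in Kelvin, T0 stored in deg C (math in Kelvin)."""

    b_K: float
    t0_C: float
    log_tau_inf: float = -14.0
    se_b_K: float | None = None
    se_t0_C: float | None = None

    def __post_init__(self):
        if not (self.b_K > 0):
            raise DomainError(f"B must be > 0 K, got {self.b_K}")
        if self.log_tau_inf > -10:
            raise DomainError(
                f"log10 tau_inf must be <= -10 (got {self.log_tau_inf}); "
                "phonon-scale pre-exponents only")

    @property
    def t0_K(self) -> float:
        return self.t0_C + KELVIN


@dataclass(frozen=True)
class DerivedDynamics:
    """Dynamic glass transition (tau = 100 s) and fragility of one VTFH law."""

    tg_drs_C: float
    fragility_m: float


@dataclass(frozen=True)
class CompositionEstimate:
    """Drug weight fraction read back from a relaxation time."""

    x_drug: float
    bracket: tuple[float, float]
    reference_set: str = ""

    def __post_init__(self):
        lo, hi = self.bracket
        if not (lo <= self.x_drug <= hi):
            raise DomainError("estimate outside its bracket")


def vtfh_eval(params: VTFHParams, temperature_C) -> np.ndarray | float:
    """log10 tau(T) of a VTFH law; temperature in deg C."""
    t_K = np.asarray(temperature_C, dtype=float) + KELVIN
    if np.any(t_K <= params.t0_K):
        raise DomainError(
            f"temperature {temperature_C} deg C at or below the Vogel "
            f"temperature {params.t0_C} deg C")
    out = params.log_tau_inf + params.b_K / (LN10 * (t_K - params.t0_K))
    return float(out) if np.isscalar(temperature_C) else out


def fit_vtfh(points, fix_log_tau_inf: bool = True,
             log_tau_inf: float = -14.0) -> VTFHParams:
    """Unweighted least-squares VTFH fit in log10(tau).

    ``points`` is an iterable of :class:`RelaxationPoint`.  At least four
    points spanning >= 20 deg C are required.  With ``fix_log_tau_inf``
    (the default) only (B, T0) are free; the pre-exponent is pinned so
    that sparse datasets remain comparable.
    """
    pts = list(points)
    if len(pts) < 4:
        raise InsufficientDataError(f"need >= 4 points, got {len(pts)}")
    t_C = np.array([p.temperature for p in pts], dtype=float)
    y = np.array([p.log10_tau for p in pts], dtype=float)
    if t_C.max() - t_C.min() < 20.0:
        raise InsufficientDataError("points must span >= 20 deg C")
    t_K = t_C + KELVIN

    def resid(theta):
        if fix_log_tau_inf:
            b, t0 = theta
            lti = log_tau_inf
        else:
            b, t0, lti = theta
        return lti + b / (LN10 * (t_K - t0)) - y

    t0_start = t_K.min() - 60.0
    x0 = [2500.0, t0_start] if fix_log_tau_inf else [2500.0, t0_start, log_tau_inf]
    ub_t0 = t_K.min() - 1e-6
    if fix_log_tau_inf:
        bounds = ([1e-6, 0.0], [np.inf, ub_t0])
    else:
        bounds = ([1e-6, 0.0, -20.0], [np.inf, ub_t0, -10.0])
    sol = least_squares(resid, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitFailureError("VTFH fit did not converge",
                              best_residual=float(np.sqrt(np.mean(sol.fun ** 2))))
    b, t0 = sol.x[0], sol.x[1]
    lti = log_tau_inf if fix_log_tau_inf else float(sol.x[2])
    if t0 >= t_K.min():
        raise FitFailureError("fitted Vogel temperature inside the data range")
    # parameter standard errors from the Jacobian at the solution
    dof = max(len(pts) - sol.x.size, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.diag(cov))
        se_b, se_t0 = float(se[0]), float(se[1])
    except np.linalg.LinAlgError:
        se_b = se_t0 = None
    return VTFHParams(b_K=float(b), t0_C=float(t0 - KELVIN), log_tau_inf=lti,
                      se_b_K=se_b, se_t0_C=se_t0)


def tg_from_vtfh(params: VTFHParams, tau_ref_s: float = TAU_GLASS_S) -> float:
    """Temperature (deg C) at which the VTFH law reaches ``tau_ref_s``.

    Closed-form inversion: T = T0 + B / ((log10 tau_ref - log10 tau_inf) ln 10).
    """
    log_ref = math.log10(tau_ref_s)
    if log_ref <= params.log_tau_inf:
        raise DomainError("tau_ref must exceed the infinite-temperature limit")
    t_K = params.t0_K + params.b_K / ((log_ref - params.log_tau_inf) * LN10)
    return t_K - KELVIN


def fragility_index(params: VTFHParams, tg_C: float) -> float:
    """Steepness index m = B Tg / (ln10 (Tg - T0)^2), temperatures in Kelvin.

    Equals the slope d log10(tau) / d(Tg/T) evaluated at T = Tg.  A
    warning is emitted outside the empirically observed strong-fragile
    range (16-170).
    """
    tg_K = tg_C + KELVIN
    if tg_K <= params.t0_K:
        raise DomainError("Tg must exceed the Vogel temperature")
    m = params.b_K * tg_K / (LN10 * (tg_K - params.t0_K) ** 2)
    if not (FRAGILITY_RANGE[0] <= m <= FRAGILITY_RANGE[1]):
        warnings.warn(f"fragility m = {m:.1f} outside the usual range "
                      f"{FRAGILITY_RANGE}", stacklevel=2)
    return m


def derived_dynamics(params: VTFHParams,
                     tau_ref_s: float = TAU_GLASS_S) -> DerivedDynamics:
    """Dynamic Tg and fragility of one VTFH law."""
    tg = tg_from_vtfh(params, tau_ref_s)
    return DerivedDynamics(tg_drs_C=tg, fragility_m=fragility_index(params, tg))


# ---------------------------------------------------------------------------
# composition readback
# ---------------------------------------------------------------------------

def estimate_composition(log10_tau: float, temperature_C: float,
                         references: dict[float, VTFHParams],
                         reference_set: str = "") -> CompositionEstimate:
    """Invert log10(tau) at fixed T against reference VTFH curves.

    ``references`` maps drug weight fraction -> VTFH parameters.  The
    reference log10(tau) values at ``temperature_C`` must be monotone in
    composition; the query is inverted by piecewise-linear interpolation
    and bracketed by the two neighbouring reference compositions.  A
    query outside the reference envelope is clamped with a warning.
    """
    if len(references) < 2:
        raise InsufficientDataError("need >= 2 reference compositions")
    xs = np.array(sorted(references), dtype=float)
    lts = np.array([vtfh_eval(references[x], temperature_C) for x in xs])
    d = np.diff(lts)
    if not (np.all(d < 0) or np.all(d > 0)):
        raise DomainError(
            f"reference log10(tau) not monotone in composition at "
            f"{temperature_C} deg C")
    lo_env, hi_env = min(lts[0], lts[-1]), max(lts[0], lts[-1])
    if log10_tau < lo_env or log10_tau > hi_env:
        warnings.warn("query log10(tau) outside the reference envelope; "
                      "composition clamped to the nearest reference",
                      stacklevel=2)
        i = int(np.argmin(np.abs(lts - log10_tau)))
        j = max(min(i, xs.size - 2), 0)
        x = float(xs[i])
        return CompositionEstimate(x_drug=x, bracket=(float(xs[j]), float(xs[j + 1])),
                                   reference_set=reference_set)
    # exact piecewise-linear inversion on the bracketing segment
    for j in range(xs.size - 1):
        a, b = lts[j], lts[j + 1]
        if (a - log10_tau) * (b - log10_tau) <= 0:
            frac = 0.0 if a == b else (log10_tau - a) / (b - a)
            x = float(xs[j] + frac * (xs[j + 1] - xs[j]))
            return CompositionEstimate(
                x_drug=x, bracket=(float(xs[j]), float(xs[j + 1])),
                reference_set=reference_set)
    raise DomainError("no bracketing segment found")  # pragma: no cover


# ---------------------------------------------------------------------------
# isothermal recrystallisation tracking
# ---------------------------------------------------------------------------

def track_recrystallization(series, n_modes: int = 2,
                            fit_target: str = "eps_der",
                            freq_window: tuple[float, float] | None = None,
                            references: dict[float, VTFHParams] | None = None,
                            reference_set: str = "",
                            seed: int = 0) -> pd.DataFrame:
    """Follow HN mode strengths and times through a time series of spectra.

    ``series`` is an iterable of ``(time, DielectricSpectrum)`` recorded at
    one temperature on a shared frequency grid.  Each time point is fitted
    with ``n_modes`` HN modes warm-started from the previous fit (cold
    start on failure); a failed point is kept as a row of NaNs so the
    series continues.  When two-mode fits degrade (parameters pinned at
    bounds), a single-mode refit is accepted instead.

    Returns a DataFrame with per-mode strengths Delta_eps, peak times
    log10(tau), a flag on non-monotone alpha2 strength, and - when
    ``references`` are supplied - the composition of the relaxing phase
    estimated from the fastest mode's relaxation time.
    """
    items = [(float(t), s) for t, s in series]
    if len(items) < 3:
        raise InsufficientDataError("need >= 3 time points")
    temp0 = items[0][1].temperature
    f0 = items[0][1].frequencies
    for _, s in items[1:]:
        if s.temperature != temp0 or not np.array_equal(s.frequencies, f0):
            raise DomainError("series must share temperature and frequency grid")

    rows = []
    prev_fit: HNFit | None = None
    prev_de2 = None
    for t, spec in items:
        if fit_target == "eps_der" and spec.eps_der is None:
            spec = log_derivative(spec)
        row: dict = {"time": t, "ok": True, "n_modes": n_modes,
                     "de_nonmonotone": False}
        try:
            fit = fit_hn(spec, n_modes=n_modes, fit_target=fit_target,
                         freq_window=freq_window, init=prev_fit, seed=seed)
            if n_modes == 2 and fit.boundary_warning:
                refit = fit_hn(spec, n_modes=1, fit_target=fit_target,
                               freq_window=freq_window, seed=seed)
                if refit.residual_rms <= 1.5 * fit.residual_rms:
                    fit = refit
                    row["n_modes"] = 1
        except Exception:
            try:
                fit = fit_hn(spec, n_modes=n_modes, fit_target=fit_target,
                             freq_window=freq_window, init=None, seed=seed)
            except Exception:
                row.update({"ok": False})
                rows.append(row)
                prev_fit = None
                continue
        prev_fit = fit
        labels = ["alpha"] if fit.n_modes == 1 else ["alpha1", "alpha2"]
        fast_lt = None
        for k, lab in enumerate(labels):
            pt = hn_peak_tau(fit, k)
            row[f"delta_eps_{lab}"] = fit.modes[k].delta_eps
            row[f"log10_tau_{lab}"] = pt.log10_tau
            fast_lt = pt.log10_tau
        row["residual_rms"] = fit.residual_rms
        de2 = row.get("delta_eps_alpha2", row.get("delta_eps_alpha"))
        # 1% head-room so solver wobble on merging modes does not flag
        if prev_de2 is not None and de2 is not None and de2 > prev_de2 * 1.01:
            row["de_nonmonotone"] = True
        if de2 is not None:
            prev_de2 = de2
        if references is not None and fast_lt is not None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = estimate_composition(fast_lt, temp0, references,
                                               reference_set)
                row["x_drug"] = est.x_drug
                row["x_lo"], row["x_hi"] = est.bracket
            except Exception:
                row["x_drug"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
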