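"""Dielectric frequency-sweep processing.

A broadband dielectric sweep records the complex permittivity
``eps*(F) = eps'(F) - i eps''(F)`` of a sample at one temperature.  In
conducting samples the structural (alpha) relaxation is buried at low
frequency under ohmic conductivity and electrode polarisation, both of
which contribute to ``eps''`` but not to ``eps'``.  The logarithmic
derivative

    eps''_der = -(pi/2) * d eps' / d ln(omega)

therefore yields a conduction-free loss whose peaks track the underlying
relaxations.  Relaxations are modelled with the Havriliak-Negami (HN)
function

    eps*(omega) = eps_inf + delta_eps / (1 + (i omega tau_HN)**alpha)**beta

with broadening exponent ``alpha`` in (0, 1] and asymmetry exponent
``beta`` in (0, 1]; ``alpha = beta = 1`` is the Debye limit.  Two HN modes
are used to deconvolute a split alpha relaxation into its slow (alpha1)
and fast (alpha2) components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    BoundaryPeakError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
    InvalidModelError,
    OrderOfOperationsError,
)

__all__ = [
    "DielectricSpectrum",
    "HNMode",
    "HNFit",
    "RelaxationPoint",
    "hn_eval",
    "log_derivative",
    "normalize_loss",
    "modulus_transform",
    "pick_peak_tau",
    "fit_hn",
    "hn_peak_tau",
]

LN10 = math.log(10.0)

#: Labels a relaxation point may carry: a single alpha process, or the
#: slow/fast components of a split alpha process.
VALID_LABELS = ("alpha", "alpha1", "alpha2", "unlabelled")
VALID_METHODS = ("peak-pick", "hn-fit")


@dataclass(frozen=True)
class DielectricSpectrum:
    """One isotherm's frequency sweep of complex permittivity.

    Parameters
    ----------
    temperature
        Isotherm temperature in deg C.
    frequencies
        Field frequencies in Hz, strictly ascending.
    eps_real, eps_imag
        Real and imaginary permittivity per frequency (dimensionless).
    eps_der
        Conduction-free derivative loss, filled by :func:`log_derivative`.
    """

    temperature: float
    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    eps_der: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        ei = np.asarray(self.eps_imag, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "eps_real", er)
        object.__setattr__(self, "eps_imag", ei)
        if self.eps_der is not None:
            object.__setattr__(self, "eps_der",
                               np.asarray(self.eps_der, dtype=float))
        if f.size < 5:
            raise InsufficientDataError(
                f"need >= 5 frequency points, got {f.size}")
        if not (er.size == f.size == ei.size):
            raise InvalidModelError("frequency/permittivity arrays differ in length")
        if self.eps_der is not None and self.eps_der.size != f.size:
            raise InvalidModelError("eps_der length mismatch")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise InvalidModelError("frequencies must be positive and strictly increasing")
        if np.any(er <= 0):
            raise InvalidModelError("eps_real must be positive everywhere")

    @property
    def n_points(self) -> int:
        return int(self.frequencies.size)

    def with_eps_der(self, eps_der: np.ndarray) -> "DielectricSpectrum":
        return replace(self, eps_der=np.asarray(eps_der, dtype=float))


@dataclass(frozen=True)
class HNMode:
    """A single Havriliak-Negami relaxation mode.

    ``delta_eps`` is the dielectric strength (eps_s - eps_inf), ``tau_hn``
    the characteristic HN time in seconds, and ``alpha_hn``/``beta_hn``
    the broadening/asymmetry shape exponents.
    """

    delta_eps: float
    tau_hn: float
    alpha_hn: float
    beta_hn: float

    def __post_init__(self):
        if not (self.delta_eps > 0):
            raise InvalidModelError(f"delta_eps must be > 0, got {self.delta_eps}")
        if not (self.tau_hn > 0):
            raise InvalidModelError(f"tau_hn must be > 0, got {self.tau_hn}")
        if not (0 < self.alpha_hn <= 1):
            raise InvalidModelError(f"alpha_hn must be in (0, 1], got {self.alpha_hn}")
        if not (0 < self.beta_hn <= 1):
            raise InvalidModelError(f"beta_hn must be in (0, 1], got {self.beta_hn}")

    @property
    def eps_static_increment(self) -> float:
        """Contribution of this mode to the static permittivity."""
        return self.delta_eps


@dataclass(frozen=True)
class HNFit:
    """Result of fitting one or two HN modes to a loss spectrum.

    Modes are ordered by descending ``tau_hn``: mode 0 is the slow
    (low-frequency, alpha1) component, mode 1 the fast (alpha2) one.
    """

    eps_inf: float
    modes: tuple[HNMode, ...]
    residual_rms: float
    converged: bool
    temperature: float | None = None
    fit_target: str = "eps_der"
    freq_window: tuple[float, float] | None = None
    boundary_warning: bool = False

    def __post_init__(self):
        if not self.modes:
            raise InvalidModelError("an HN fit must carry at least one mode")
        if len(self.modes) > 2:
            raise InvalidModelError("at most two HN modes are supported")
        if self.eps_inf < 0:
            raise InvalidModelError("eps_inf must be >= 0")
        if self.residual_rms < 0:
            raise InvalidModelError("residual_rms must be >= 0")
        taus = [m.tau_hn for m in self.modes]
        if len(taus) == 2 and not taus[0] > taus[1]:
            raise InvalidModelError("modes must be ordered by descending tau_hn")

    @property
    def n_modes(self) -> int:
        return len(self.modes)


@dataclass(frozen=True)
class RelaxationPoint:
    """A (temperature, log10 tau_max) point for the Arrhenius diagram."""

    temperature: float
    log10_tau: float
    label: str = "alpha"
    method: str = "peak-pick"

    def __post_init__(self):
        if not np.isfinite(self.log10_tau):
            raise InvalidModelError("log10_tau must be finite")
        if self.label not in VALID_LABELS:
            raise InvalidModelError(f"label must be one of {VALID_LABELS}")
        if self.method not in VALID_METHODS:
            raise InvalidModelError(f"method must be one of {VALID_METHODS}")


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def hn_complex(eps_inf: float, modes, frequencies) -> np.ndarray:
    """Complex permittivity eps* = eps' - i eps'' of a sum of HN modes."""
    f = np.asarray(frequencies, dtype=float)
    omega = 2.0 * np.pi * f
    eps = np.full_like(omega, float(eps_inf), dtype=complex)
    for m in modes:
        eps = eps + m.delta_eps * (1.0 + (1j * omega * m.tau_hn) ** m.alpha_hn) ** (-m.beta_hn)
    return eps


def hn_eval(eps_inf: float, modes, frequencies):
    """Evaluate a sum of HN modes; returns ``(eps_real, eps_imag)``.

    ``eps_imag`` is the positive loss, i.e. ``-Im(eps*)``.
    """
    if not modes:
        if eps_inf is None:
            raise InvalidModelError("no modes and no eps_inf: empty model")
        f = np.asarray(frequencies, dtype=float)
        return np.full_like(f, float(eps_inf)), np.zeros_like(f)
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise DomainError("frequencies must be positive")
    eps = hn_complex(eps_inf, modes, f)
    return eps.real, -eps.imag


def hn_eps_der(eps_inf: float, modes, frequencies) -> np.ndarray:
    """Analytic derivative loss -(pi/2) d eps'/d ln(omega) of an HN sum.

    For one mode, d eps*/d ln(omega) =
    -alpha beta delta_eps (i omega tau)^alpha (1+(i omega tau)^alpha)^(-beta-1),
    so the derivative loss is commensurate with data processed by
    :func:`log_derivative` without numerical differentiation error.
    """
    f = np.asarray(frequencies, dtype=float)
    omega = 2.0 * np.pi * f
    out = np.zeros_like(omega)
    for m in modes:
        z = (1j * omega * m.tau_hn) ** m.alpha_hn
        d = -m.alpha_hn * m.beta_hn * m.delta_eps * z * (1.0 + z) ** (-m.beta_hn - 1.0)
        out = out + (-0.5 * np.pi) * d.real
    return out


# ---------------------------------------------------------------------------
# derivative loss, normalisation, modulus
# ---------------------------------------------------------------------------

def log_derivative(spectrum: DielectricSpectrum, smoothing_window: int = 5,
                   points_per_decade: int = 40) -> DielectricSpectrum:
    """Fill ``eps_der`` with the conduction-free derivative loss.

    eps' is resampled (cubic spline) onto a uniform log10(F) grid of
    ``points_per_decade``, differentiated with a local quadratic
    (Savitzky-Golay) fit over ``smoothing_window`` points with respect to
    ln(omega), scaled by -pi/2 and interpolated back to the original
    frequencies.  The internal grid is kept at least twice as dense as a
    typical sweep because the quadratic filter's truncation bias scales
    with the squared grid step.  Only eps' enters, so any ohmic
    conductivity term c/omega added to eps'' leaves the result
    bit-identical.
    """
    if smoothing_window < 3 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd integer >= 3")
    n = spectrum.n_points
    if n < smoothing_window:
        raise InsufficientDataError(
            f"need >= {smoothing_window} points for the derivative window, got {n}")
    logf = np.log10(spectrum.frequencies)
    span = logf[-1] - logf[0]
    n_grid = max(int(round(span * points_per_decade)) + 1, smoothing_window, n)
    grid = np.linspace(logf[0], logf[-1], n_grid)
    eps_on_grid = CubicSpline(logf, spectrum.eps_real)(grid)
    # d/d ln(omega) = (1/ln 10) d/d log10(omega) and d log10(omega) = d log10(F)
    delta_ln_omega = (grid[1] - grid[0]) * LN10
    deriv = savgol_filter(eps_on_grid, smoothing_window, polyorder=2,
                          deriv=1, delta=delta_ln_omega, mode="interp")
    eps_der_grid = -0.5 * np.pi * deriv
    eps_der = np.interp(logf, grid, eps_der_grid)
    return spectrum.with_eps_der(eps_der)


def normalize_loss(spectrum: DielectricSpectrum) -> np.ndarray:
    """Return the ratio eps''_der / eps'.

    The ratio removes amplitude drifts caused by changes in electrode
    filling (powder coalescence), at the cost of shifting apparent peak
    positions towards higher frequency, exactly as tan(delta) does
    relative to eps''.  Peak times read off the normalised curve are
    therefore systematically slightly short.
    """
    if spectrum.eps_der is None:
        raise OrderOfOperationsError(
            "eps_der missing: run log_derivative before normalize_loss")
    return spectrum.eps_der / spectrum.eps_real


def modulus_transform(spectrum: DielectricSpectrum):
    """Return the complex dielectric modulus M* = 1/eps* as ``(M', M'')``.

    M'' is insensitive to electrode polarisation and turns d.c.
    conductivity into a low-frequency peak, offering an independent check
    that low-frequency shoulders in eps''_der are genuine relaxations.
    """
    er, ei = spectrum.eps_real, spectrum.eps_imag
    denom = er * er + ei * ei
    if np.any(denom <= 0):
        raise DomainError("zero-magnitude permittivity: modulus undefined")
    return er / denom, ei / denom


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def _parabolic_refine(logf: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points i-1, i, i+1 in log10(F)."""
    x0, x1, x2 = logf[i - 1], logf[i], logf[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0:
        return x1
    # uniform-spacing vertex formula generalised to slightly uneven grids
    # via a direct quadratic fit
    coef = np.polyfit([x0, x1, x2], [y0, y1, y2], 2)
    if coef[0] == 0:
        return x1
    return float(-coef[1] / (2.0 * coef[0]))


def pick_peak_tau(frequencies, loss_curve, temperature: float,
                  label: str = "alpha") -> RelaxationPoint:
    """Convert the maximum of a loss curve into a relaxation point.

    The discrete maximum is refined with a three-point parabola in
    log10(F); the relaxation time follows from
    ``tau_max = 1 / (2 pi F_max)``.
    """
    f = np.asarray(frequencies, dtype=float)
    y = np.asarray(loss_curve, dtype=float)
    if f.size != y.size or f.size < 3:
        raise InsufficientDataError("need matching arrays of >= 3 points")
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        raise BoundaryPeakError(
            f"maximum at the {'low' if i == 0 else 'high'}-frequency edge: "
            "peak lies outside the sweep window")
    log_fmax = _parabolic_refine(np.log10(f), y, i)
    log10_tau = -(math.log10(2.0 * math.pi) + log_fmax)
    return RelaxationPoint(temperature=temperature, log10_tau=log10_tau,
                           label=label, method="peak-pick")


# ---------------------------------------------------------------------------
# HN fitting
# ---------------------------------------------------------------------------

def _hn_model_curve(params: np.ndarray, n_modes: int, fit_target: str,
                    frequencies: np.ndarray) -> np.ndarray:
    modes = []
    for k in range(n_modes):
        de, lt, a, b = params[4 * k:4 * k + 4]
        modes.append(HNMode(delta_eps=de, tau_hn=10.0 ** lt, alpha_hn=a, beta_hn=b))
    if fit_target == "eps_der":
        return hn_eps_der(0.0, modes, frequencies)
    return hn_eval(0.0, modes, frequencies)[1]


def _initial_guesses(freq: np.ndarray, data: np.ndarray, n_modes: int):
    """Seed (delta_eps, log10 tau) per mode from the highest loss peaks."""
    y = np.asarray(data, dtype=float)
    idx, _ = find_peaks(y)
    if idx.size:
        order = idx[np.argsort(y[idx])[::-1]]
    else:
        order = np.array([int(np.argmax(y))])
    seeds = []
    for i in order[:n_modes]:
        lt = -math.log10(2.0 * math.pi * freq[i])
        seeds.append((max(2.0 * y[i], 1e-3), lt))
    if n_modes == 2 and len(seeds) == 1:
        de, lt = seeds[0]
        seeds = [(de / 2.0, lt + 1.0), (de / 2.0, lt - 1.0)]
    # slow mode first
    seeds.sort(key=lambda s: -s[1])
    return seeds


def fit_hn(spectrum: DielectricSpectrum, n_modes: int = 1,
           fit_target: str = "eps_der",
           freq_window: tuple[float, float] | None = None,
           init: HNFit | None = None, n_restarts: int = 3,
           seed: int = 0) -> HNFit:
    """Fit 1 or 2 HN modes to a loss spectrum.

    Parameters
    ----------
    fit_target
        ``"eps_der"`` fits the analytic derivative loss of the HN model to
        the measured eps''_der (model and data are then commensurate);
        ``"eps_imag"`` fits -Im(eps*) to eps''.
    freq_window
        (f_lo, f_hi) in Hz restricting the fit, used to exclude the
        low-frequency electrode-polarisation rise; defaults to the full
        sweep.
    init
        Warm start taken from a previous fit (time-series tracking).
    n_restarts
        Number of seeded perturbed restarts beyond the first attempt.

    eps_inf is not identifiable from a loss curve; after the mode fit it
    is recovered by matching the model eps' to the measured eps' in the
    window (a linear one-parameter problem).
    """
    import lmfit

    if n_modes not in (1, 2):
        raise InvalidModelError("n_modes must be 1 or 2")
    if fit_target not in ("eps_der", "eps_imag"):
        raise InvalidModelError("fit_target must be 'eps_der' or 'eps_imag'")
    if fit_target == "eps_der":
        if spectrum.eps_der is None:
            spectrum = log_derivative(spectrum)
        data = spectrum.eps_der
    else:
        data = spectrum.eps_imag
    f = spectrum.frequencies
    if freq_window is None:
        mask = np.ones_like(f, dtype=bool)
    else:
        mask = (f >= freq_window[0]) & (f <= freq_window[1])
    if mask.sum() < 8:
        raise InsufficientDataError(
            f"fit window holds {int(mask.sum())} points; >= 8 required")
    fw, dw = f[mask], np.asarray(data)[mask]

    lt_lo = -math.log10(2.0 * np.pi * fw[-1]) - 3.0
    lt_hi = -math.log10(2.0 * np.pi * fw[0]) + 3.0
    scale = max(float(np.max(np.abs(dw))), 1e-12)

    def make_params(seeds):
        p = lmfit.Parameters()
        for k, (de, lt) in enumerate(seeds):
            p.add(f"de{k}", value=de, min=1e-8, max=1e5)
            p.add(f"lt{k}", value=float(np.clip(lt, lt_lo, lt_hi)),
                  min=lt_lo, max=lt_hi)
            p.add(f"a{k}", value=0.85, min=0.05, max=1.0)
            p.add(f"b{k}", value=0.9, min=0.05, max=1.0)
        return p

    def residual(p):
        vec = []
        for k in range(n_modes):
            vec += [p[f"de{k}"].value, p[f"lt{k}"].value,
                    p[f"a{k}"].value, p[f"b{k}"].value]
        return (_hn_model_curve(np.array(vec), n_modes, fit_target, fw) - dw) / scale

    if init is not None:
        base = [(m.delta_eps, math.log10(m.tau_hn)) for m in init.modes]
        if len(base) != n_modes:
            base = _initial_guesses(fw, dw, n_modes)
    else:
        base = _initial_guesses(fw, dw, n_modes)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1 + n_restarts):
        seeds = list(base)
        if attempt > 0:
            seeds = [(de * float(rng.uniform(0.5, 2.0)),
                      lt + float(rng.uniform(-0.7, 0.7))) for de, lt in seeds]
        params = make_params(seeds)
        if init is not None and attempt == 0:
            for k, m in enumerate(init.modes[:n_modes]):
                params[f"a{k}"].value = m.alpha_hn
                params[f"b{k}"].value = min(m.beta_hn, 1.0)
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        cost = float(np.sqrt(np.mean(res.residual ** 2)))
        if best is None or cost < best[0]:
            best = (cost, res)
        if cost * scale < 1e-12:
            break
    if best is None:
        raise FitFailureError("all HN fit attempts raised", best_residual=None)
    cost, res = best

    modes = []
    boundary = False
    for k in range(n_modes):
        de = res.params[f"de{k}"].value
        lt = res.params[f"lt{k}"].value
        a = res.params[f"a{k}"].value
        b = res.params[f"b{k}"].value
        for par, lo, hi in ((lt, lt_lo, lt_hi), (a, 0.05, 1.0), (b, 0.05, 1.0)):
            if abs(par - lo) < 1e-6 * max(1.0, abs(lo)) or \
               abs(par - hi) < 1e-6 * max(1.0, abs(hi)):
                boundary = True
        modes.append(HNMode(delta_eps=de, tau_hn=10.0 ** lt,
                            alpha_hn=min(a, 1.0), beta_hn=min(b, 1.0)))
    modes.sort(key=lambda m: -m.tau_hn)

    # recover eps_inf from eps' in the window (linear one-parameter LSQ)
    model_real = hn_eval(0.0, modes, fw)[0]
    eps_inf = float(np.mean(spectrum.eps_real[mask] - model_real))
    eps_inf = max(eps_inf, 0.0)

    residual_rms = cost * scale
    return HNFit(eps_inf=eps_inf, modes=tuple(modes),
                 residual_rms=residual_rms,
                 converged=bool(getattr(res, "success", True)),
                 temperature=spectrum.temperature, fit_target=fit_target,
                 freq_window=(float(fw[0]), float(fw[-1])),
                 boundary_warning=boundary)


def hn_shape_factor(alpha_hn: float, beta_hn: float) -> float:
    """Ratio omega_max * tau_HN fixed by the HN shape exponents.

    ``r = [sin(pi a/(2(b+1))) / sin(pi a b/(2(b+1)))]^(1/a)``, so the loss
    peak sits at ``omega_max = r / tau_HN`` and ``tau_max = tau_HN / r``;
    r = 1 in the Debye limit.
    """
    a, b = alpha_hn, beta_hn
    num = math.sin(math.pi * a / (2.0 * (b + 1.0)))
    den = math.sin(math.pi * a * b / (2.0 * (b + 1.0)))
    return (num / den) ** (1.0 / a)


def hn_peak_tau(fit: HNFit, mode_index: int = 0) -> RelaxationPoint:
    """Relaxation time at the loss maximum of one fitted HN mode.

    Uses the closed form
    ``omega_max = tau_HN^-1 [sin(pi a/(2(b+1))) / sin(pi a b/(2(b+1)))]^(1/a)``
    (exactly 1/tau_HN in the Debye limit).  For two-mode fits the slow
    mode is labelled alpha1, the fast one alpha2.
    """
    m = fit.modes[mode_index]
    tau_max = m.tau_hn / hn_shape_factor(m.alpha_hn, m.beta_hn)
    if fit.n_modes == 1:
        label = "alpha"
    else:
        label = "alpha1" if mode_index == 0 else "alpha2"
    if fit.temperature is None:
        raise InvalidModelError("fit carries no temperature")
    return RelaxationPoint(temperature=fit.temperature,
                           log10_tau=math.log10(tau_max),
                           label=label, method="hn-fit")
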