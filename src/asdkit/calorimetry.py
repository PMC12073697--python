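"""Thermal analysis: glass-transition extraction and mixing rules.

A temperature-modulated DSC scan of an amorphous blend shows the glass
transition as a sigmoidal step in the reversible heat capacity.  The
composition dependence of the blend's Tg follows the Gordon-Taylor
mixing rule

    Tg(x) = [x Tg_drug + K (1-x) Tg_polymer] / [x + K (1-x)]

where x is the drug weight fraction and K a fitting parameter.  The
Couchman-Karasz prediction K_CK = dCp_polymer / dCp_drug is what K should
be for an athermal (interaction-free) mixture, so K_GT > K_CK signals
attractive drug-polymer interactions.  Inverting the fitted rule converts
a measured Tg back into the composition of the amorphous phase - the
basis of annealing-based solubility measurements and of recrystallisation
bookkeeping via crystallisation enthalpies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .errors import (
    DomainError,
    InsufficientDataError,
    InvalidModelError,
    MultipleTransitionsError,
    NoTransitionError,
)

__all__ = [
    "Thermogram",
    "GlassTransition",
    "GordonTaylorModel",
    "CouchmanKarasz",
    "RecrystallizationResult",
    "extract_glass_transition",
    "gt_eval",
    "gt_fit",
    "gt_invert",
    "couchman_karasz",
    "recrystallization_accounting",
]


@dataclass(frozen=True)
class Thermogram:
    """Reversible heat capacity vs. temperature (J g^-1 degC^-1)."""

    temperatures: np.ndarray
    rev_cp: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        c = np.asarray(self.rev_cp, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rev_cp", c)
        if t.size < 20:
            raise InsufficientDataError(f"need >= 20 points, got {t.size}")
        if t.size != c.size:
            raise InvalidModelError("temperature/Cp length mismatch")
        if np.any(np.diff(t) <= 0):
            raise InvalidModelError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class GlassTransition:
    """Tangent-construction characterisation of one Cp step."""

    tg_onset: float
    tg_midpoint: float
    tg_end: float
    delta_cp: float

    def __post_init__(self):
        if not (self.tg_onset < self.tg_midpoint < self.tg_end):
            raise InvalidModelError("require onset < midpoint < end")
        if not (self.delta_cp > 0):
            raise InvalidModelError("delta_cp must be > 0")


@dataclass(frozen=True)
class GordonTaylorModel:
    """Gordon-Taylor state curve Tg(x) with fixed pure-component endpoints."""

    tg_drug: float
    tg_polymer: float
    k: float
    se_k: float | None = None

    def __post_init__(self):
        if not (self.k > 0):
            raise InvalidModelError("K must be > 0")
        if not (self.tg_drug < self.tg_polymer):
            raise InvalidModelError(
                "expected tg_drug < tg_polymer for this kind of blend")


@dataclass(frozen=True)
class CouchmanKarasz:
    """Heat-capacity ratio prediction for the Gordon-Taylor parameter."""

    k: float
    half_range: float
    k_min: float
    k_max: float


@dataclass(frozen=True)
class RecrystallizationResult:
    """Mass balance of partial drug recrystallisation inside a dispersion."""

    dh_cr_per_g_asd: float
    dh_cr_per_g_drug: float
    fraction_crystallized: float
    x_remaining: float


# ---------------------------------------------------------------------------
# glass-transition extraction
# ---------------------------------------------------------------------------

def _analyse_step(t, cp, dcp_dt, i_peak, baseline_width):
    """Tangent construction around one derivative peak."""
    # characteristic width from the half-maximum width of the derivative peak
    widths = peak_widths(dcp_dt, [i_peak], rel_height=0.5)[0]
    dt = float(np.mean(np.diff(t)))
    w_C = max(widths[0] * dt / 2.355, dt)  # sigma-like scale
    # parabolic refinement of the midpoint (derivative maximum)
    if 0 < i_peak < t.size - 1:
        coef = np.polyfit(t[i_peak - 1:i_peak + 2], dcp_dt[i_peak - 1:i_peak + 2], 2)
        mid = float(-coef[1] / (2 * coef[0])) if coef[0] != 0 else float(t[i_peak])
    else:
        mid = float(t[i_peak])
    # far enough out that residual step tails (~e^-margin/width) are
    # negligible against the baseline fit
    margin = max(5.0 * w_C, 2.0)
    low_hi = mid - margin
    high_lo = mid + margin
    low_mask = (t <= low_hi) & (t >= low_hi - baseline_width)
    high_mask = (t >= high_lo) & (t <= high_lo + baseline_width)
    if low_mask.sum() < 3 or high_mask.sum() < 3:
        raise InsufficientDataError(
            "not enough flat baseline on one side of the Cp step")
    p_lo = np.polyfit(t[low_mask], cp[low_mask], 1)
    p_hi = np.polyfit(t[high_mask], cp[high_mask], 1)
    # tangent through the midpoint with the maximal slope
    slope = float(np.interp(mid, t, dcp_dt))
    cp_mid = float(np.interp(mid, t, cp))
    # intersections of baseline lines with the midpoint tangent
    def intersect(p):
        if slope == p[0]:
            raise DomainError("degenerate tangent construction")
        return (cp_mid - slope * mid - (p[1])) / (p[0] - slope)
    onset = intersect(p_lo)
    end = intersect(p_hi)
    delta_cp = float(np.polyval(p_hi, mid) - np.polyval(p_lo, mid))
    return GlassTransition(tg_onset=onset, tg_midpoint=mid, tg_end=end,
                           delta_cp=delta_cp)


def extract_glass_transition(thermogram: Thermogram,
                             baseline_width: float = 10.0,
                             smooth_window: int | None = None,
                             noise_factor: float = 6.0) -> GlassTransition:
    """Locate and characterise the Cp step of a thermogram.

    The temperature derivative of the (optionally Savitzky-Golay smoothed)
    Cp signal is scanned for peaks above ``noise_factor`` times the
    median absolute derivative.  The midpoint is the refined derivative
    maximum; onset and end come from intersecting linear baselines -
    fitted over ``baseline_width`` deg C windows flanking the step - with
    the tangent at the midpoint, and Delta_Cp is the baseline gap at the
    midpoint.  Uniform Cp offsets cancel throughout.

    Raises
    ------
    NoTransitionError
        If no derivative peak rises above the noise floor.
    MultipleTransitionsError
        If two or more resolved steps are present; the per-step analyses
        ride on the exception.
    """
    t, cp = thermogram.temperatures, thermogram.rev_cp
    dt = float(np.mean(np.diff(t)))
    if smooth_window is None:
        # ~1 deg C of points, odd, at least 5
        smooth_window = max(int(round(1.0 / dt)) | 1, 5)
    smooth_window = min(smooth_window, (t.size - 1) | 1)
    cps = savgol_filter(cp, smooth_window, polyorder=2)
    dcp_dt = np.gradient(cps, t)
    scale = float(np.median(np.abs(dcp_dt)))
    height = max(noise_factor * scale, 1e-4)
    idx, props = find_peaks(dcp_dt, height=height, prominence=0.5 * height)
    if idx.size == 0:
        raise NoTransitionError("no Cp step above the noise floor")
    # merge peaks closer than 5 deg C (unresolved shoulders)
    keep = [int(idx[0])]
    for i in idx[1:]:
        if t[i] - t[keep[-1]] < 5.0:
            if dcp_dt[i] > dcp_dt[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    if len(keep) > 1:
        transitions = []
        for i in keep:
            try:
                transitions.append(_analyse_step(t, cps, dcp_dt, i, baseline_width))
            except Exception:
                pass
        raise MultipleTransitionsError(
            f"{len(keep)} resolved Cp steps detected", transitions=transitions)
    return _analyse_step(t, cps, dcp_dt, keep[0], baseline_width)


# ---------------------------------------------------------------------------
# Gordon-Taylor mixing rule
# ---------------------------------------------------------------------------

def gt_eval(model: GordonTaylorModel, x) -> np.ndarray | float:
    """Blend Tg (deg C) at drug weight fraction ``x``."""
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0) | (xa > 1)):
        raise DomainError("weight fraction outside [0, 1]")
    num = xa * model.tg_drug + model.k * (1.0 - xa) * model.tg_polymer
    den = xa + model.k * (1.0 - xa)
    out = num / den
    return float(out) if np.isscalar(x) else out


def gt_fit(points, tg_drug: float, tg_polymer: float) -> GordonTaylorModel:
    """Least-squares fit of K to (x, Tg_midpoint) data.

    The pure-component endpoints are constraints, not data: the rule
    passes through them identically for any K, so x = 0 and x = 1 points
    are excluded from the residual.
    """
    pts = [(float(x), float(tg)) for x, tg in points]
    interior = [(x, tg) for x, tg in pts if 0.0 < x < 1.0]
    if len(interior) < 3:
        raise InsufficientDataError("need >= 3 interior compositions")
    x = np.array([p[0] for p in interior])
    tg = np.array([p[1] for p in interior])
    if np.unique(x).size < 2:
        raise DomainError("degenerate compositions: rank-deficient fit")

    def resid(theta):
        m = GordonTaylorModel(tg_drug=tg_drug, tg_polymer=tg_polymer,
                              k=float(theta[0]))
        return gt_eval(m, x) - tg

    sol = least_squares(resid, [0.7], bounds=([1e-6], [1e3]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    k = float(sol.x[0])
    dof = max(x.size - 1, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    jtj = float((sol.jac.T @ sol.jac).reshape(()))
    se_k = math.sqrt(s2 / jtj) if jtj > 0 else None
    return GordonTaylorModel(tg_drug=tg_drug, tg_polymer=tg_polymer, k=k,
                             se_k=se_k)


def gt_invert(model: GordonTaylorModel, tg: float) -> float:
    """Drug weight fraction whose blend Tg equals ``tg`` (closed form).

    The rule is linear in x after cross-multiplication:
    x = K (Tg - Tg_polymer) / [(Tg_drug - Tg) + K (Tg - Tg_polymer)].
    """
    if not (model.tg_drug < tg < model.tg_polymer):
        raise DomainError(
            f"Tg = {tg} deg C outside the open interval "
            f"({model.tg_drug}, {model.tg_polymer})")
    num = model.k * (tg - model.tg_polymer)
    den = (model.tg_drug - tg) + num
    return num / den


def couchman_karasz(delta_cp_polymer: float, delta_cp_drug: float,
                    u_polymer: float = 0.0, u_drug: float = 0.0) -> CouchmanKarasz:
    """Heat-capacity ratio K_CK = dCp_polymer / dCp_drug with bounds.

    Uncertainty is propagated by min-max: k_min = (a-u_a)/(b+u_b),
    k_max = (a+u_a)/(b-u_b), then symmetrised as the half range.
    """
    a, b = delta_cp_polymer, delta_cp_drug
    if a <= 0 or b <= 0:
        raise DomainError("heat-capacity steps must be positive")
    if b - u_drug <= 0:
        raise DomainError("drug dCp uncertainty swallows the value")
    k = a / b
    k_min = (a - u_polymer) / (b + u_drug)
    k_max = (a + u_polymer) / (b - u_drug)
    return CouchmanKarasz(k=k, half_range=0.5 * (k_max - k_min),
                          k_min=k_min, k_max=k_max)


# ---------------------------------------------------------------------------
# recrystallisation enthalpy bookkeeping
# ---------------------------------------------------------------------------

def recrystallization_accounting(x_drug: float, dh_cr_per_g_asd: float,
                                 dh_ref_pure: float) -> RecrystallizationResult:
    """Mass balance of a partial recrystallisation exotherm.

    The measured enthalpy per gram of dispersion is referred to the drug
    mass (``/ x_drug``) and compared with the crystallisation enthalpy of
    the pure amorphous drug to get the crystallised fraction f; the
    remaining amorphous phase then contains
    ``x (1-f) / (x (1-f) + (1-x))`` drug by weight.
    """
    if not (0 < x_drug <= 1):
        raise DomainError("x_drug must be in (0, 1]")
    if dh_cr_per_g_asd < 0 or dh_ref_pure <= 0:
        raise DomainError("enthalpies must be non-negative (reference > 0)")
    dh_drug = dh_cr_per_g_asd / x_drug
    f = dh_drug / dh_ref_pure
    if f > 1.05:
        raise DomainError(
            f"crystallised fraction {f:.3f} exceeds 1 beyond tolerance: "
            "inconsistent enthalpies")
    if f > 1.0:
        warnings.warn("crystallised fraction marginally above 1; clamped",
                      stacklevel=2)
        f = 1.0
    amorphous_drug = x_drug * (1.0 - f)
    x_rem = amorphous_drug / (amorphous_drug + (1.0 - x_drug)) \
        if (amorphous_drug + (1.0 - x_drug)) > 0 else 0.0
    return RecrystallizationResult(dh_cr_per_g_asd=dh_cr_per_g_asd,
                                   dh_cr_per_g_drug=dh_drug,
                                   fraction_crystallized=f,
                                   x_remaining=x_rem)
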