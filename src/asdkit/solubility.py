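"""Flory-Huggins solubility and the combined phase/state diagram.

The equilibrium solubility of a crystalline drug in an amorphous polymer
follows from equating the chemical potential of the crystal with that of
the dissolved drug in Flory-Huggins lattice theory:

    (dHm/R) (1/Tm - 1/T) = ln(phi) + (1 - 1/lambda)(1 - phi) + chi (1 - phi)^2

where phi is the drug volume fraction, lambda the polymer/drug molar
volume ratio, Tm and dHm the drug's melting temperature and enthalpy, and
chi the interaction parameter (negative = attractive).  Because the
residual of this implicit equation is affine in chi, fitting chi to a set
of measured saturation points is a linear least-squares problem with a
closed-form solution.

Combining the solubility (liquidus) curve with the Gordon-Taylor Tg curve
yields the phase-and-state diagram that classifies any (composition,
temperature) point as an undersaturated liquid, a supersaturated liquid,
or a glass (itself possibly supersaturated).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .calorimetry import GordonTaylorModel, gt_eval, gt_invert
from .dynamics import KELVIN
from .errors import (
    ConfigError,
    DomainError,
    InsufficientDataError,
    NoSolutionError,
)

__all__ = [
    "GAS_CONSTANT",
    "FloryHugginsModel",
    "SolubilityPoint",
    "StateLabel",
    "PhaseDiagram",
    "volume_fraction",
    "lambda_ratio",
    "fh_residual",
    "solve_solubility_temperature",
    "fit_chi",
    "latreche_points",
    "classify_state",
    "build_phase_diagram",
]

#: J mol^-1 K^-1
GAS_CONSTANT = 8.314

#: Annealing temperatures below this reach equilibrium too slowly to
#: measure; solubility values computed below it are extrapolations.
EXTRAPOLATION_LIMIT_C = 120.0

#: Points closer than this to a diagram curve are labelled "boundary".
BOUNDARY_TOL_C = 0.05


@dataclass(frozen=True)
class FloryHugginsModel:
    """Material constants and interaction parameter of a drug/polymer pair.

    ``dhm_J_mol`` is the drug melting enthalpy in J mol^-1 (the
    kJ mol^-1 value quoted by calorimetry is converted at the interface);
    densities in g cm^-3, molar masses in g mol^-1.  ``chi`` is the
    dimensionless interaction parameter, None until fitted.
    """

    tm_C: float
    dhm_J_mol: float
    rho_drug: float
    rho_polymer: float
    m_drug: float
    mw_polymer: float
    chi: float | None = None
    se_chi: float | None = None

    def __post_init__(self):
        if self.tm_C + KELVIN <= 0:
            raise DomainError("melting temperature below absolute zero")
        if self.dhm_J_mol <= 0:
            raise DomainError("melting enthalpy must be positive")
        for name in ("rho_drug", "rho_polymer", "m_drug", "mw_polymer"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @property
    def tm_K(self) -> float:
        return self.tm_C + KELVIN

    @property
    def lam(self) -> float:
        return lambda_ratio(self)

    def with_chi(self, chi: float, se_chi: float | None = None) -> "FloryHugginsModel":
        return replace(self, chi=chi, se_chi=se_chi)


@dataclass(frozen=True)
class SolubilityPoint:
    """One annealing-derived saturation point."""

    t_anneal: float
    tg_measured: float | None
    x_sat: float

    def __post_init__(self):
        if not (0 < self.x_sat < 1):
            raise DomainError("x_sat must be in (0, 1)")


@dataclass(frozen=True)
class StateLabel:
    """Classification of one (composition, temperature) point.

    ``primary`` is one of ``undersaturated-liquid``, ``supersaturated-
    liquid``, ``glassy``, ``pure-drug`` or ``pure-polymer``; glasses below
    the solubility curve additionally carry ``supersaturated=True``.
    Points within the boundary tolerance of a curve get
    ``boundary_between`` naming both neighbouring states.
    """

    primary: str
    supersaturated: bool = False
    extrapolated: bool = False
    boundary_between: tuple[str, str] | None = None


def volume_fraction(x, model: FloryHugginsModel) -> np.ndarray | float:
    """Drug volume fraction phi from weight fraction via the densities."""
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0) | (xa > 1)):
        raise DomainError("weight fraction outside [0, 1]")
    num = xa / model.rho_drug
    out = num / (num + (1.0 - xa) / model.rho_polymer)
    return float(out) if np.isscalar(x) else out


def lambda_ratio(model: FloryHugginsModel) -> float:
    """Polymer/drug molar volume ratio lambda = Mw_p rho_d / (rho_p M_d)."""
    return model.mw_polymer * model.rho_drug / (model.rho_polymer * model.m_drug)


def fh_residual(x, temperature_C, model: FloryHugginsModel,
                chi: float | None = None) -> np.ndarray | float:
    """LHS - RHS of the implicit solubility equation at (x, T).

    Vanishes identically at (x = 1, T = Tm).  At fixed (x, T) it is
    affine in chi with slope -(1 - phi)^2.
    """
    if chi is None:
        chi = model.chi
    if chi is None:
        raise ConfigError("chi not set on the model and not supplied")
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0) or np.any(xa > 1):
        raise DomainError("x must be in (0, 1] (ln(phi) diverges at 0)")
    t_K = np.asarray(temperature_C, dtype=float) + KELVIN
    phi = volume_fraction(xa, model)
    lam = model.lam
    lhs = model.dhm_J_mol / GAS_CONSTANT * (1.0 / model.tm_K - 1.0 / t_K)
    rhs = np.log(phi) + (1.0 - 1.0 / lam) * (1.0 - phi) + chi * (1.0 - phi) ** 2
    out = lhs - rhs
    if np.isscalar(x) and np.isscalar(temperature_C):
        return float(out)
    return out


def solve_solubility_temperature(x: float, model: FloryHugginsModel,
                                 t_low_C: float | None = None,
                                 t_high_C: float | None = None) -> float:
    """Temperature (deg C) at which ``x`` is the saturation composition.

    The residual is scanned on a 0.5 deg C grid over the bracket
    (default [0, Tm + 50] deg C; pass the blend Tg - 50 as ``t_low_C`` to
    mirror the physically relevant window) and each sign change is
    refined by Brent's method; the root nearest Tm is returned, so the
    liquidus branch anchored at (x -> 1, T -> Tm) is selected.
    """
    if not (0 < x < 1):
        raise DomainError("x must be in (0, 1)")
    if model.chi is None:
        raise ConfigError("model.chi must be set before solving")
    lo = 0.0 if t_low_C is None else t_low_C
    hi = model.tm_C + 50.0 if t_high_C is None else t_high_C
    grid = np.arange(lo, hi + 0.5, 0.5)
    vals = fh_residual(x, grid, model)
    roots = []
    for i in range(grid.size - 1):
        a, b = vals[i], vals[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(brentq(lambda tt: fh_residual(x, tt, model),
                                grid[i], grid[i + 1], xtol=1e-10))
    if not roots:
        raise NoSolutionError(
            f"no sign change of the solubility residual for x = {x} "
            f"in [{lo}, {hi}] deg C")
    return min(roots, key=lambda r: abs(r - model.tm_C))


def fit_chi(points, model: FloryHugginsModel) -> FloryHugginsModel:
    """Fit chi to saturation points by least squares on the residual.

    Because the residual is affine in chi with slope -(1 - phi)^2, the
    minimiser is closed-form:
    chi = sum(b_i a_i) / sum(b_i^2) with b = (1 - phi)^2 and
    a = LHS - ln(phi) - (1 - 1/lambda)(1 - phi).  The standard error
    follows from the residual variance.
    """
    pts = list(points)
    if len(pts) < 2:
        raise InsufficientDataError("need >= 2 saturation points")
    x = np.array([p.x_sat for p in pts])
    t_K = np.array([p.t_anneal for p in pts]) + KELVIN
    if np.unique(np.round(x, 12)).size < 2:
        raise DomainError("degenerate saturation points: rank-deficient fit")
    phi = volume_fraction(x, model)
    lam = model.lam
    a = (model.dhm_J_mol / GAS_CONSTANT * (1.0 / model.tm_K - 1.0 / t_K)
         - np.log(phi) - (1.0 - 1.0 / lam) * (1.0 - phi))
    b = (1.0 - phi) ** 2
    chi = float(np.sum(b * a) / np.sum(b * b))
    resid = a - chi * b
    dof = max(len(pts) - 1, 1)
    s2 = float(np.sum(resid ** 2)) / dof
    se = math.sqrt(s2 / float(np.sum(b * b)))
    return model.with_chi(chi, se_chi=se)


def latreche_points(records, gt_model: GordonTaylorModel):
    """Convert annealing (T_a, measured Tg) records into saturation points.

    Each annealing temperature dissolves crystallites until the amorphous
    phase saturates; quenching and re-measuring its Tg, then inverting the
    Gordon-Taylor rule, yields the saturation composition at T_a.
    Records whose Tg falls outside the open (Tg_drug, Tg_polymer)
    interval produce error entries instead of points.

    Returns ``(points, errors)`` with points ordered by T_a.
    """
    points, errors = [], []
    for t_a, tg in records:
        try:
            x = gt_invert(gt_model, tg)
            points.append(SolubilityPoint(t_anneal=float(t_a),
                                          tg_measured=float(tg), x_sat=x))
        except DomainError as exc:
            errors.append({"t_anneal": float(t_a), "tg": float(tg),
                           "error": str(exc)})
    points.sort(key=lambda p: p.t_anneal)
    return points, errors


@dataclass(frozen=True)
class PhaseDiagram:
    """Gordon-Taylor state curve + Flory-Huggins solubility curve.

    ``grid`` tabulates both curves on a composition grid; experimental
    overlays (measured (x, Tg) pairs and saturation points) ride along
    for plotting and serialisation.
    """

    gt_model: GordonTaylorModel
    fh_model: FloryHugginsModel
    grid: pd.DataFrame
    gt_band: tuple[float, float] | None = None
    tg_points: tuple = ()
    solubility_points: tuple = ()

    def tg_at(self, x: float) -> float:
        return gt_eval(self.gt_model, x)

    def solubility_at(self, x: float) -> float:
        return solve_solubility_temperature(x, self.fh_model)

    def to_json(self) -> str:
        payload = {
            "schema": "diagram.v1",
            "gt_model": {"tg_drug_C": self.gt_model.tg_drug,
                         "tg_polymer_C": self.gt_model.tg_polymer,
                         "k": self.gt_model.k, "se_k": self.gt_model.se_k},
            "fh_model": {"tm_C": self.fh_model.tm_C,
                         "dhm_J_mol": self.fh_model.dhm_J_mol,
                         "rho_drug": self.fh_model.rho_drug,
                         "rho_polymer": self.fh_model.rho_polymer,
                         "m_drug": self.fh_model.m_drug,
                         "mw_polymer": self.fh_model.mw_polymer,
                         "chi": self.fh_model.chi,
                         "se_chi": self.fh_model.se_chi},
            "gt_band": list(self.gt_band) if self.gt_band else None,
            "tg_points": [list(p) for p in self.tg_points],
            "solubility_points": [
                {"t_anneal_C": p.t_anneal, "tg_C": p.tg_measured,
                 "x_sat": p.x_sat} for p in self.solubility_points],
            "grid": self.grid.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PhaseDiagram":
        d = json.loads(text)
        if d.get("schema") != "diagram.v1":
            raise ConfigError(f"unexpected diagram schema: {d.get('schema')}")
        gt = GordonTaylorModel(tg_drug=d["gt_model"]["tg_drug_C"],
                               tg_polymer=d["gt_model"]["tg_polymer_C"],
                               k=d["gt_model"]["k"],
                               se_k=d["gt_model"]["se_k"])
        fm = d["fh_model"]
        fh = FloryHugginsModel(tm_C=fm["tm_C"], dhm_J_mol=fm["dhm_J_mol"],
                               rho_drug=fm["rho_drug"],
                               rho_polymer=fm["rho_polymer"],
                               m_drug=fm["m_drug"],
                               mw_polymer=fm["mw_polymer"],
                               chi=fm["chi"], se_chi=fm["se_chi"])
        pts = tuple(SolubilityPoint(t_anneal=p["t_anneal_C"],
                                    tg_measured=p["tg_C"], x_sat=p["x_sat"])
                    for p in d["solubility_points"])
        return cls(gt_model=gt, fh_model=fh,
                   grid=pd.DataFrame(d["grid"]),
                   gt_band=tuple(d["gt_band"]) if d["gt_band"] else None,
                   tg_points=tuple(tuple(p) for p in d["tg_points"]),
                   solubility_points=pts)


def build_phase_diagram(gt_model: GordonTaylorModel,
                        fh_model: FloryHugginsModel,
                        tg_points=(), solubility_points=(),
                        gt_band: tuple[float, float] | None = None,
                        x_step: float = 0.01) -> PhaseDiagram:
    """Tabulate both curves on an x grid and assemble the diagram.

    Solubility temperatures below the lowest measurable annealing
    temperature are computed but flagged ``extrapolated`` (equilibrium is
    unreachable there on laboratory timescales).
    """
    if fh_model.chi is None:
        raise ConfigError("fit or set chi before building the diagram")
    xs = np.round(np.arange(x_step, 1.0 + x_step / 2, x_step), 10)
    rows = []
    for x in xs:
        tg = gt_eval(gt_model, float(x))
        if x >= 1.0:
            tsol = fh_model.tm_C
        else:
            try:
                tsol = solve_solubility_temperature(float(x), fh_model)
            except NoSolutionError:
                tsol = np.nan
        rows.append({"x_drug": float(x), "tg_C": tg, "t_solubility_C": tsol,
                     "extrapolated": bool(np.isnan(tsol)
                                          or tsol < EXTRAPOLATION_LIMIT_C)})
    grid = pd.DataFrame(rows)
    return PhaseDiagram(gt_model=gt_model, fh_model=fh_model, grid=grid,
                        gt_band=gt_band, tg_points=tuple(map(tuple, tg_points)),
                        solubility_points=tuple(solubility_points))


def classify_state(x: float, temperature_C: float,
                   diagram: PhaseDiagram) -> StateLabel:
    """Classify one (composition, temperature) point of the diagram.

    Above the solubility curve the matrix is undersaturated (stable
    single-phase liquid); between Tg(x) and the solubility curve it is a
    supersaturated liquid in which excess drug tends to recrystallise;
    below Tg(x) it is a glass, flagged supersaturated when it also sits
    below the solubility curve.  Ties within 0.05 deg C of a curve are
    reported as boundaries.
    """
    if x == 0.0:
        return StateLabel(primary="pure-polymer")
    if x == 1.0:
        return StateLabel(primary="pure-drug")
    if not (0 < x < 1):
        raise DomainError("x must be in [0, 1]")
    tg = gt_eval(diagram.gt_model, x)
    try:
        tsol = solve_solubility_temperature(x, diagram.fh_model)
    except NoSolutionError:
        tsol = -np.inf
    extrapolated = tsol < EXTRAPOLATION_LIMIT_C
    on_tg = abs(temperature_C - tg) <= BOUNDARY_TOL_C
    on_sol = abs(temperature_C - tsol) <= BOUNDARY_TOL_C
    if on_sol and temperature_C > tg:
        return StateLabel(primary="boundary", extrapolated=extrapolated,
                          boundary_between=("supersaturated-liquid",
                                            "undersaturated-liquid"))
    if on_tg:
        upper = ("supersaturated-liquid" if temperature_C < tsol
                 else "undersaturated-liquid")
        return StateLabel(primary="boundary", extrapolated=extrapolated,
                          supersaturated=temperature_C < tsol,
                          boundary_between=("glassy", upper))
    if temperature_C > tg and temperature_C > tsol:
        return StateLabel(primary="undersaturated-liquid",
                          extrapolated=extrapolated)
    if temperature_C > tg:
        return StateLabel(primary="supersaturated-liquid", supersaturated=True,
                          extrapolated=extrapolated)
    return StateLabel(primary="glassy", supersaturated=temperature_C < tsol,
                      extrapolated=extrapolated)
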