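"""End-to-end orchestration of the two analysis workflows.

* dynamics workflow: dielectric isotherms -> derivative loss -> HN fits
  -> relaxation-time table -> VTFH fit -> dynamic Tg and fragility;
* diagram workflow: thermogram glass transitions -> Gordon-Taylor fit ->
  annealing Tg readback -> Flory-Huggins chi fit -> phase/state diagram.

Both entry points accept in-memory objects (the analysis scripts use
them that way) and can persist every artefact plus a manifest capturing
the configuration, seed and per-stage status, so a run can be re-executed
from its manifest alone.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as aio
from .calorimetry import Thermogram, extract_glass_transition, gt_fit
from .dynamics import (
    VTFHParams,
    derived_dynamics,
    fit_vtfh,
)
from .errors import ConfigError
from .solubility import (
    FloryHugginsModel,
    build_phase_diagram,
    fit_chi,
    latreche_points,
)
from .spectra import fit_hn, hn_peak_tau, log_derivative

__all__ = ["RunConfig", "run_dynamics_pipeline", "run_diagram_pipeline",
           "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters steering a full pipeline run."""

    # dielectric stage
    n_modes: int = 1
    fit_target: str = "eps_der"
    freq_window: tuple[float, float] | None = None
    smoothing_window: int = 5
    fix_log_tau_inf: bool = True
    log_tau_inf: float = -14.0
    # diagram stage
    tg_drug: float | None = None
    tg_polymer: float | None = None
    fh_constants: dict | None = None   # tm_C, dhm_J_mol, rho_*, m_drug, mw_polymer
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None
    verbosity: int = 0


def _out(config: RunConfig):
    if config.output_dir is None:
        return None
    p = Path(config.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _manifest(out: Path | None, name: str, config: RunConfig, stages: list[dict]):
    if out is None:
        return
    payload = {
        "workflow": name,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "numpy": np.__version__,
        "python": platform.python_version(),
        "stages": stages,
    }
    (out / f"{name}_manifest.json").write_text(json.dumps(payload, indent=1,
                                                          default=str))


def run_dynamics_pipeline(spectra, config: RunConfig) -> dict:
    """Spectra -> derivative loss -> HN fits -> VTFH -> Tg_DRS and m.

    Returns a dict with the per-isotherm fits, the relaxation-point
    table, the VTFH parameters and the derived dynamics.  Isotherms whose
    fits fail are recorded in the manifest and skipped.
    """
    spectra = list(spectra)
    if not spectra:
        raise ConfigError("no input spectra")
    out = _out(config)
    stages: list[dict] = []

    processed, fits, points = [], [], []
    failures = []
    prev_fit = None
    for spec in sorted(spectra, key=lambda s: s.temperature):
        try:
            spec = log_derivative(spec, smoothing_window=config.smoothing_window)
            processed.append(spec)
            # warm start from the neighbouring isotherm keeps mode identity
            # stable as the two components shift through the window
            fit = fit_hn(spec, n_modes=config.n_modes,
                         fit_target=config.fit_target,
                         freq_window=config.freq_window, seed=config.seed,
                         init=prev_fit)
            prev_fit = fit
            fits.append(fit)
            # keep only modes whose loss peak lies inside the measured
            # window; an extrapolated peak position is not a data point
            f_lo, f_hi = spec.frequencies[0], spec.frequencies[-1]
            for k in range(fit.n_modes):
                pt = hn_peak_tau(fit, k)
                f_max = 1.0 / (2.0 * np.pi * 10.0 ** pt.log10_tau)
                if f_lo <= f_max <= f_hi:
                    points.append(pt)
        except Exception as exc:
            failures.append({"temperature_C": spec.temperature,
                             "error": f"{type(exc).__name__}: {exc}"})
    stages.append({"stage": "hn-fits", "status": "ok" if fits else "failed",
                   "n_fits": len(fits), "failures": failures})

    results: dict = {"spectra": processed, "hn_fits": fits,
                     "relaxation_points": points}
    labels = sorted({p.label for p in points})
    vtfh: dict[str, VTFHParams] = {}
    derived: dict[str, dict] = {}
    vtfh_failures = []
    for label in labels:
        pts = [p for p in points if p.label == label]
        try:
            params = fit_vtfh(pts, fix_log_tau_inf=config.fix_log_tau_inf,
                              log_tau_inf=config.log_tau_inf)
            vtfh[label] = params
            dd = derived_dynamics(params)
            derived[label] = {"tg_drs_C": dd.tg_drs_C,
                              "fragility_m": dd.fragility_m}
        except Exception as exc:
            vtfh_failures.append({"label": label,
                                  "error": f"{type(exc).__name__}: {exc}"})
    stages.append({"stage": "vtfh", "status": "ok" if vtfh else "failed",
                   "failures": vtfh_failures})
    results["vtfh"] = vtfh
    results["derived"] = derived

    if out is not None:
        aio.write_relaxation_table(out / "relaxation_times.csv", points)
        for i, fit in enumerate(fits):
            (out / f"hn_fit_{i:03d}.json").write_text(aio.hn_fit_to_json(fit))
        for label, params in vtfh.items():
            (out / f"vtfh_{label}.json").write_text(aio.vtfh_to_json(params))
        _manifest(out, "dynamics", config, stages)
    return results


def run_diagram_pipeline(thermograms: dict[float, Thermogram],
                         annealing_records,
                         config: RunConfig) -> dict:
    """Thermograms -> GT fit -> saturation readback -> chi -> diagram.

    ``thermograms`` maps drug weight fraction -> thermogram;
    ``annealing_records`` is an iterable of (T_anneal, measured Tg).
    """
    if not thermograms:
        raise ConfigError("no input thermograms")
    if config.fh_constants is None:
        raise ConfigError("fh_constants required for the diagram workflow")
    out = _out(config)
    stages: list[dict] = []

    glass_transitions = {}
    failures = []
    for x, tg in sorted(thermograms.items()):
        try:
            glass_transitions[x] = extract_glass_transition(tg)
        except Exception as exc:
            failures.append({"x_drug": x, "error": f"{type(exc).__name__}: {exc}"})
    stages.append({"stage": "dsc", "status": "ok" if glass_transitions else "failed",
                   "failures": failures})

    tg_points = [(x, g.tg_midpoint) for x, g in glass_transitions.items()]
    tg_drug = config.tg_drug
    tg_polymer = config.tg_polymer
    if tg_drug is None and 1.0 in glass_transitions:
        tg_drug = glass_transitions[1.0].tg_midpoint
    if tg_polymer is None and 0.0 in glass_transitions:
        tg_polymer = glass_transitions[0.0].tg_midpoint
    if tg_drug is None or tg_polymer is None:
        raise ConfigError("pure-component Tg endpoints unavailable")
    gt_model = gt_fit(tg_points, tg_drug=tg_drug, tg_polymer=tg_polymer)
    stages.append({"stage": "gordon-taylor", "status": "ok",
                   "k": gt_model.k})

    points, point_errors = latreche_points(annealing_records, gt_model)
    stages.append({"stage": "saturation-readback", "status": "ok" if points
                   else "failed", "errors": point_errors})

    fh = FloryHugginsModel(**config.fh_constants)
    fh = fit_chi(points, fh)
    stages.append({"stage": "flory-huggins", "status": "ok", "chi": fh.chi})

    diagram = build_phase_diagram(gt_model, fh, tg_points=tg_points,
                                  solubility_points=points)
    stages.append({"stage": "diagram", "status": "ok"})

    if out is not None:
        for x, g in glass_transitions.items():
            (out / f"dsc_x{int(round(100 * x)):03d}.json").write_text(
                aio.glass_transition_to_json(g))
        diagram.grid.to_csv(out / "diagram_grid.csv", index=False,
                            float_format="%.17g")
        (out / "diagram.json").write_text(diagram.to_json())
        _manifest(out, "diagram", config, stages)
    return {"glass_transitions": glass_transitions, "gt_model": gt_model,
            "solubility_points": points, "point_errors": point_errors,
            "fh_model": fh, "diagram": diagram}


def run_pipeline(config: RunConfig, spectra=None, thermograms=None,
                 annealing_records=None) -> dict:
    """Dispatch whichever workflows the supplied inputs allow."""
    if spectra is None and thermograms is None:
        raise ConfigError("supply spectra and/or thermograms")
    results = {}
    if spectra is not None:
        results["dynamics"] = run_dynamics_pipeline(spectra, config)
    if thermograms is not None:
        if annealing_records is None:
            raise ConfigError("annealing_records required with thermograms")
        results["diagram"] = run_diagram_pipeline(thermograms,
                                                  annealing_records, config)
    return results
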