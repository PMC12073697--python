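"""Delimited-text and JSON readers/writers for all pipeline artefacts.

Text schemas (comma- or tab-delimited, decimal point, full double
precision):

* spectra:          ``temperature_C,frequency_Hz,eps_real,eps_imag[,eps_der]``
* thermograms:      ``temperature_C,rev_cp_J_per_gC``
* relaxation table: ``temperature_C,log10_tau_s,label,method``

JSON result schemas: ``hn_fit.v1``, ``vtfh.v1``, ``dsc.v1`` (the
``diagram.v1`` serialisation lives on :class:`~asdkit.solubility.PhaseDiagram`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calorimetry import GlassTransition, Thermogram
from .dynamics import VTFHParams, derived_dynamics
from .errors import DuplicateRowError, ParseError, SchemaError
from .spectra import DielectricSpectrum, HNFit, HNMode, RelaxationPoint

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_thermogram",
    "write_thermogram",
    "read_relaxation_table",
    "write_relaxation_table",
    "hn_fit_to_json",
    "hn_fit_from_json",
    "vtfh_to_json",
    "vtfh_from_json",
    "glass_transition_to_json",
    "glass_transition_from_json",
]

_FLOAT_FMT = "%.17g"


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if df[col].dtype == object:
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                # +2: header line and 1-based numbering
                lines = [int(i) + 2 for i in bad[:5]]
                raise ParseError(
                    f"{path}: non-numeric value in column '{col}' at "
                    f"line(s) {lines}")
        df[col] = coerced
    return df


def read_spectra(path) -> list[DielectricSpectrum]:
    """Read one or more isotherms from a delimited spectrum file.

    Rows are grouped by temperature and sorted by frequency; duplicated
    (temperature, frequency) pairs are an error naming the offending row.
    """
    df = _read_table(path, ("temperature_C", "frequency_Hz",
                            "eps_real", "eps_imag"))
    dup = df.duplicated(subset=["temperature_C", "frequency_Hz"])
    if dup.any():
        i = int(df.index[dup][0])
        raise DuplicateRowError(
            f"{path}: duplicated (temperature, frequency) pair at line "
            f"{i + 2}: T={df.temperature_C[i]}, F={df.frequency_Hz[i]}")
    has_der = "eps_der" in df.columns
    out = []
    for temp, grp in df.groupby("temperature_C", sort=True):
        grp = grp.sort_values("frequency_Hz")
        out.append(DielectricSpectrum(
            temperature=float(temp),
            frequencies=grp.frequency_Hz.to_numpy(),
            eps_real=grp.eps_real.to_numpy(),
            eps_imag=grp.eps_imag.to_numpy(),
            eps_der=grp.eps_der.to_numpy() if has_der else None))
    return out


def write_spectra(path, spectra) -> None:
    frames = []
    for s in spectra:
        d = {"temperature_C": np.full(s.n_points, s.temperature),
             "frequency_Hz": s.frequencies,
             "eps_real": s.eps_real, "eps_imag": s.eps_imag}
        if s.eps_der is not None:
            d["eps_der"] = s.eps_der
        frames.append(pd.DataFrame(d))
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_thermogram(path, heat_flow_scale: float = 1.0) -> Thermogram:
    """Read a thermogram; ``heat_flow_scale`` converts raw heat-flow
    recordings (mW/mg at a known heating rate) into specific heat."""
    df = _read_table(path, ("temperature_C", "rev_cp_J_per_gC"))
    df = df.sort_values("temperature_C")
    return Thermogram(temperatures=df.temperature_C.to_numpy(),
                      rev_cp=df.rev_cp_J_per_gC.to_numpy() * heat_flow_scale)


def write_thermogram(path, tg: Thermogram) -> None:
    pd.DataFrame({"temperature_C": tg.temperatures,
                  "rev_cp_J_per_gC": tg.rev_cp}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_relaxation_table(path) -> list[RelaxationPoint]:
    df = _read_table(path, ("temperature_C", "log10_tau_s"))
    for col in ("label", "method"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column '{col}'")
    return [RelaxationPoint(temperature=float(r.temperature_C),
                            log10_tau=float(r.log10_tau_s),
                            label=str(r.label), method=str(r.method))
            for r in df.itertuples()]


def write_relaxation_table(path, points) -> None:
    pd.DataFrame({
        "temperature_C": [p.temperature for p in points],
        "log10_tau_s": [p.log10_tau for p in points],
        "label": [p.label for p in points],
        "method": [p.method for p in points],
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# JSON result schemas
# ---------------------------------------------------------------------------

def hn_fit_to_json(fit: HNFit) -> str:
    return json.dumps({
        "schema": "hn_fit.v1",
        "eps_inf": fit.eps_inf,
        "modes": [{"delta_eps": m.delta_eps, "tau_hn_s": m.tau_hn,
                   "alpha_hn": m.alpha_hn, "beta_hn": m.beta_hn}
                  for m in fit.modes],
        "residual_rms": fit.residual_rms,
        "converged": fit.converged,
        "temperature_C": fit.temperature,
        "target": fit.fit_target,
        "window_Hz": list(fit.freq_window) if fit.freq_window else None,
        "boundary_warning": fit.boundary_warning,
    }, indent=1)


def hn_fit_from_json(text: str) -> HNFit:
    d = json.loads(text)
    if d.get("schema") != "hn_fit.v1":
        raise SchemaError(f"unexpected schema: {d.get('schema')}")
    return HNFit(
        eps_inf=d["eps_inf"],
        modes=tuple(HNMode(delta_eps=m["delta_eps"], tau_hn=m["tau_hn_s"],
                           alpha_hn=m["alpha_hn"], beta_hn=m["beta_hn"])
                    for m in d["modes"]),
        residual_rms=d["residual_rms"], converged=d["converged"],
        temperature=d.get("temperature_C"), fit_target=d.get("target", "eps_der"),
        freq_window=tuple(d["window_Hz"]) if d.get("window_Hz") else None,
        boundary_warning=d.get("boundary_warning", False))


def vtfh_to_json(params: VTFHParams) -> str:
    dd = derived_dynamics(params)
    return json.dumps({
        "schema": "vtfh.v1",
        "B_K": params.b_K, "T0_C": params.t0_C,
        "log_tau_inf": params.log_tau_inf,
        "se_B_K": params.se_b_K, "se_T0_C": params.se_t0_C,
        "tg_drs_C": dd.tg_drs_C, "fragility_m": dd.fragility_m,
    }, indent=1)


def vtfh_from_json(text: str) -> VTFHParams:
    d = json.loads(text)
    if d.get("schema") != "vtfh.v1":
        raise SchemaError(f"unexpected schema: {d.get('schema')}")
    return VTFHParams(b_K=d["B_K"], t0_C=d["T0_C"],
                      log_tau_inf=d["log_tau_inf"],
                      se_b_K=d.get("se_B_K"), se_t0_C=d.get("se_T0_C"))


def glass_transition_to_json(gt: GlassTransition) -> str:
    return json.dumps({
        "schema": "dsc.v1",
        "tg_onset_C": gt.tg_onset, "tg_midpoint_C": gt.tg_midpoint,
        "tg_end_C": gt.tg_end, "delta_cp_J_per_gC": gt.delta_cp,
    }, indent=1)


def glass_transition_from_json(text: str) -> GlassTransition:
    d = json.loads(text)
    if d.get("schema") != "dsc.v1":
        raise SchemaError(f"unexpected schema: {d.get('schema')}")
    return GlassTransition(tg_onset=d["tg_onset_C"],
                           tg_midpoint=d["tg_midpoint_C"],
                           tg_end=d["tg_end_C"],
                           delta_cp=d["delta_cp_J_per_gC"])
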