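#!/usr/bin/env python
"""Generate the synthetic instrument recordings used by the later stages.

Writes, under results/data/:
  * dielectric isotherm sweeps (0.1 Hz - 1 MHz, 10 pts/decade) for a
    single-relaxation blend (ohmic conductivity + mild multiplicative
    noise) and for a split-relaxation high-drug blend patterned on the
    published 90 wt.% VTFH parameters (conductivity, noise-free: the
    deconvolution of a weak slow mode is ill-conditioned under noise
    once the fast component approaches the sweep edge);
  * MDSC-style thermograms for every composition of the reference table,
    each a logistic Cp step at the measured (Tg, delta_cp).
"""

from pathlib import Path

from asdkit import reference_data as rd
from asdkit.dynamics import VTFHParams
from asdkit.io import write_spectra, write_thermogram
from asdkit.synthetic import (
    SyntheticMode,
    SyntheticScenario,
    ThermoScenario,
    gen_isotherm_series,
    gen_thermogram,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260921

single = SyntheticScenario(
    seed=SEED,
    modes=(SyntheticMode(vtfh=VTFHParams(b_K=2657.0, t0_C=7.6),
                         delta_eps0=3.0, alpha_hn=0.85, beta_hn=0.8),),
    temperatures_C=tuple(float(t) for t in range(90, 151, 5)),
    c_cond=0.5, noise_rel_sd=0.002)
write_spectra(OUT / "spectra_single_mode.csv", gen_isotherm_series(single))

split = SyntheticScenario(
    seed=SEED + 1,
    modes=(SyntheticMode(vtfh=VTFHParams(b_K=2356.0, t0_C=2.0),
                         delta_eps0=1.0, alpha_hn=0.9, beta_hn=0.9),
           SyntheticMode(vtfh=VTFHParams(b_K=1759.0, t0_C=11.2),
                         delta_eps0=4.0, alpha_hn=0.85, beta_hn=0.8)),
    temperatures_C=tuple(float(t) for t in range(95, 136, 5)),
    c_cond=1.0)
write_spectra(OUT / "spectra_split_mode.csv", gen_isotherm_series(split))

for _, row in rd.GLASS_TRANSITIONS.iterrows():
    sc = ThermoScenario(seed=SEED, transitions=(
        (float(row.tg_midpoint_C), float(row.delta_cp), 3.0),))
    name = f"thermogram_x{int(round(100 * row.x_drug)):03d}.csv"
    write_thermogram(OUT / name, gen_thermogram(sc))

print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")
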