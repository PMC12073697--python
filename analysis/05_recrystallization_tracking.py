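#!/usr/bin/env python
"""Isothermal recrystallisation monitoring through dielectric spectra.

Simulates a 90 degC time series for a 90 wt.% drug blend whose fast
(alpha2) amorphous phase loses drug to crystallisation down to 65 wt.%,
then runs the two-mode tracker: warm-started HN fits per time point,
mode strengths and peak times, and the composition of the relaxing phase
read back from the reference VTFH family.

Writes results/tracking/recrystallization.csv and prints the trajectory.
"""

from pathlib import Path

import numpy as np

from asdkit import reference_data as rd
from asdkit.dynamics import VTFHParams, track_recrystallization
from asdkit.synthetic import (
    SyntheticMode,
    SyntheticScenario,
    gen_recrystallization_series,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "tracking"
OUT.mkdir(parents=True, exist_ok=True)

refs = rd.reference_vtfh_curves()
scenario = SyntheticScenario(
    seed=20260921,
    modes=(SyntheticMode(vtfh=VTFHParams(b_K=2356.0, t0_C=2.0),
                         delta_eps0=1.2, alpha_hn=0.9, beta_hn=0.9),
           SyntheticMode(vtfh=VTFHParams(b_K=1759.0, t0_C=11.2),
                         delta_eps0=4.0, alpha_hn=0.85, beta_hn=0.8)),
    c_cond=0.5, noise_rel_sd=0.002)

times = np.arange(0, 8 * 3600 + 1, 1800.0)
final_x = 0.65


def path(t):
    # saturating exponential decay of the fast phase's drug content
    return 0.90 - (0.90 - final_x) * (1 - np.exp(-t / 7200.0)) / \
        (1 - np.exp(-times[-1] / 7200.0))


series = gen_recrystallization_series(scenario, times, path, refs, 90.0,
                                      alpha1_composition=0.65)
tab = track_recrystallization(series, n_modes=2, references=refs)
tab.to_csv(OUT / "recrystallization.csv", index=False)

print("time[h]  modes  dEps(fast)  log10 tau(fast)  x_drug(est)  x_drug(truth)")
for _, row in tab.iterrows():
    t = row.time
    # after the components merge the tracker degrades to one mode
    de = row.delta_eps_alpha2 if np.isfinite(row.get("delta_eps_alpha2",
                                                     np.nan)) \
        else row.get("delta_eps_alpha", np.nan)
    lt = row.log10_tau_alpha2 if np.isfinite(row.get("log10_tau_alpha2",
                                                     np.nan)) \
        else row.get("log10_tau_alpha", np.nan)
    print(f"{t / 3600:6.1f}  {row.n_modes:5.0f}  {de:10.3f}  "
          f"{lt:15.3f}  {row.x_drug:10.3f}  {path(t):12.3f}")
print(f"\nfinal composition estimate {tab.x_drug.iloc[-1]:.3f} vs "
      f"ground truth {final_x:.2f}: the fast phase depletes towards the "
      f"~65 wt.% plateau where slowed dynamics arrest crystallisation")
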