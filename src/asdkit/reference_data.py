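"""Published reference measurements for terfenadine / PVP K12 dispersions.

These small tables hold the calorimetric and dielectric characterisation
of co-milled terfenadine (TFD) / polyvinylpyrrolidone K12 amorphous solid
dispersions that the analysis pipeline is validated against: MDSC glass
transitions across the composition range, annealing-derived saturation
points, and per-composition VTFH parameters of the alpha relaxation (with
its alpha1/alpha2 split at high drug content).  They double as package
fixtures so every stage can be exercised without instrument files.
"""

from __future__ import annotations

import pandas as pd

from .dynamics import VTFHParams

__all__ = [
    "GLASS_TRANSITIONS",
    "SOLUBILITY_ANNEALING",
    "VTFH_TABLE",
    "TFD",
    "PVP_K12",
    "RECRYSTALLIZATION_90WT",
    "reference_vtfh_curves",
]


class TFD:
    """Material constants of amorphous/crystalline terfenadine."""

    TG_MIDPOINT_C = 60.0
    TG_ONSET_C = 58.0
    DELTA_CP = 0.56          # J g^-1 degC^-1
    DELTA_CP_U = 0.01
    TM_C = 150.0             # melting temperature of the crystal
    DHM_KJ_MOL = 54.2        # melting enthalpy
    M_G_MOL = 471.7
    RHO_G_CM3 = 1.05
    DH_CR_MILLED = 76.0      # crystallisation enthalpy of milled amorphous TFD, J g^-1


class PVP_K12:
    """Material constants of polyvinylpyrrolidone K12."""

    TG_MIDPOINT_C = 106.0
    TG_ONSET_C = 96.0
    DELTA_CP = 0.34          # J g^-1 degC^-1
    DELTA_CP_U = 0.02
    MW_G_MOL = 2500.0
    RHO_G_CM3 = 1.17


#: MDSC glass transitions of the dispersions (second heating, 5 degC/min):
#: onset and midpoint temperatures and Cp-step magnitude per drug fraction.
GLASS_TRANSITIONS = pd.DataFrame(
    [
        (0.00, 96.0, 106.0, 0.34, 0.02),
        (0.10, 91.0, 99.0, 0.36, 0.01),
        (0.30, 82.0, 90.0, 0.40, 0.01),
        (0.49, 75.0, 81.0, 0.45, 0.01),
        (0.70, 67.0, 72.0, 0.51, 0.01),
        (0.90, 60.0, 64.0, 0.54, 0.01),
        (1.00, 58.0, 60.0, 0.56, 0.01),
    ],
    columns=["x_drug", "tg_onset_C", "tg_midpoint_C", "delta_cp", "delta_cp_u"],
)

#: Saturation of the amorphous matrix after 5 h annealing at T_a: the Tg
#: of the remaining blend and the drug fraction read off the
#: Gordon-Taylor diagram.
SOLUBILITY_ANNEALING = pd.DataFrame(
    [
        (120.0, 84.0, 0.42),
        (125.0, 83.0, 0.44),
        (130.0, 81.0, 0.48),
        (135.0, 77.0, 0.57),
        (140.0, 73.0, 0.66),
    ],
    columns=["t_anneal_C", "tg_C", "x_sat"],
)

#: VTFH parameters (log10 tau_inf fixed at -14) of the alpha relaxation
#: per composition, with the alpha1 (slow) / alpha2 (fast) split above
#: 70 wt.% drug, plus the derived dynamic Tg (tau = 100 s) and fragility.
VTFH_TABLE = pd.DataFrame(
    [
        (0.00, "alpha", 3145.0, 10.0, 14.2, 0.4, 99.5, 70.0, 3.0),
        (0.10, "alpha", 2950.0, 14.0, 17.3, 0.5, 97.5, 74.0, 3.0),
        (0.30, "alpha", 2851.0, 14.0, 11.1, 0.6, 88.5, 75.0, 3.0),
        (0.49, "alpha", 2657.0, 17.0, 7.6, 0.6, 79.5, 79.0, 4.0),
        (0.70, "alpha1", 2641.0, 21.0, 0.6, 0.8, 70.0, 82.0, 5.0),
        (0.70, "alpha2", 2006.0, 10.0, 12.7, 0.4, 67.0, 100.0, 5.0),
        (0.90, "alpha1", 2356.0, 19.0, 2.0, 0.6, 66.0, 85.0, 5.0),
        (0.90, "alpha2", 1759.0, 12.0, 11.2, 0.4, 59.0, 111.0, 7.0),
        (1.00, "alpha", 1729.0, 17.0, 10.0, 1.0, 56.5, 114.0, 7.0),
    ],
    columns=["x_drug", "mode", "b_K", "se_b_K", "t0_C", "se_t0_C",
             "tg_drs_C", "m", "se_m"],
)

#: Isothermal recrystallisation bookkeeping inputs for the 90 wt.% blend:
#: measured exotherm per gram of dispersion vs. the pure milled reference.
RECRYSTALLIZATION_90WT = {
    "x_drug": 0.90,
    "dh_cr_per_g_asd": 52.0,   # J g^-1 of dispersion
    "dh_cr_per_g_drug": 58.0,  # J g^-1 of drug
    "dh_ref_pure": TFD.DH_CR_MILLED,
}


def reference_vtfh_curves(prefer: str = "alpha2") -> dict[float, VTFHParams]:
    """Reference composition -> VTFH map for relaxation-time readback.

    Where a composition shows a split relaxation, ``prefer`` selects which
    component represents it ("alpha2", the majority fast phase, by
    default).
    """
    if prefer not in ("alpha1", "alpha2"):
        raise ValueError("prefer must be 'alpha1' or 'alpha2'")
    out: dict[float, VTFHParams] = {}
    for _, row in VTFH_TABLE.iterrows():
        x = float(row.x_drug)
        if x in out and row["mode"] != prefer:
            continue
        if row["mode"] in ("alpha", prefer):
            out[x] = VTFHParams(b_K=float(row.b_K), t0_C=float(row.t0_C),
                                log_tau_inf=-14.0,
                                se_b_K=float(row.se_b_K),
                                se_t0_C=float(row.se_t0_C))
    return out
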