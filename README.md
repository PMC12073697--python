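# asdkit

Thermal and dielectric analysis of drug/polymer **amorphous solid
dispersions** (ASDs), built around the terfenadine (TFD) / PVP K12 model
system. An ASD keeps a poorly soluble drug amorphous inside a polymer
matrix; whether it stays amorphous is governed by the interplay of the
blend's glass transition (kinetics) and the drug's solubility in the
polymer (thermodynamics). `asdkit` implements the full chain of analyses
that turns calorimetric and dielectric measurements into that picture,
for formulation scientists and physical chemists working on amorphous
pharmaceutics.

## What it computes

**Dielectric side** (`asdkit.spectra`, `asdkit.dynamics`). Broadband
sweeps of the complex permittivity ε\*(ω) = ε′ − iε″ hide the structural
α relaxation under ohmic conductivity and electrode polarisation. The
conduction-free loss

    ε″_der = −(π/2) ∂ε′/∂ln ω

suppresses both, because neither contributes to ε′. Relaxations are
modelled with Havriliak–Negami (HN) functions

    ε*(ω) = ε∞ + Δε / (1 + (iωτ_HN)^α)^β,

deconvoluting split α₁/α₂ modes at high drug content; peak times
τ_max = 1/(2πF_max) feed Vogel–Tammann–Fulcher–Hesse fits

    log₁₀ τ = log₁₀ τ∞ + B / (ln10 (T − T₀)),   log₁₀ τ∞ fixed at −14,

whose τ = 100 s extrapolation is the dynamic glass transition Tg_DRS and
whose steepness at Tg is the fragility m = B·Tg/(ln10·(Tg−T₀)²).
Because log₁₀ τ at fixed T is monotone in drug content, relaxation times
measured during isothermal annealing read back the composition of the
relaxing amorphous phase — tracking recrystallisation spectroscopically.

**Calorimetric side** (`asdkit.calorimetry`, `asdkit.solubility`). MDSC
thermograms yield Tg (onset/midpoint/end) and ΔCp per composition. The
Gordon–Taylor rule Tg(x) = [x·Tg_drug + K(1−x)·Tg_polymer]/[x + K(1−x)]
is fitted for K and compared with the Couchman–Karasz prediction
K_CK = ΔCp_polymer/ΔCp_drug (K_GT > K_CK ⇒ attractive interactions).
Annealing/quench/Tg-readback cycles give saturation compositions which a
Flory–Huggins fit,

    (ΔH_m/R)(1/T_m − 1/T) = ln φ + (1 − 1/λ)(1 − φ) + χ(1 − φ)²,

condenses into a single interaction parameter χ (linear least squares —
the residual is affine in χ). Together the Tg curve and the solubility
curve form the phase-and-state diagram, with a classifier labelling any
(x, T) point undersaturated-liquid / supersaturated-liquid / glassy.

Ground-truthed synthetic generators (`asdkit.synthetic`) emulate both
kinds of recordings, so every stage is exercised as a round trip without
instrument files; `asdkit.reference_data` ships the published TFD/PVP
characterisation tables used for validation.

## Worked example

```python
from asdkit import reference_data as rd
from asdkit.calorimetry import couchman_karasz, gt_fit
from asdkit.dynamics import VTFHParams, fragility_index, tg_from_vtfh
from asdkit.solubility import FloryHugginsModel, SolubilityPoint, fit_chi

gt = gt_fit(list(zip(rd.GLASS_TRANSITIONS.x_drug,
                     rd.GLASS_TRANSITIONS.tg_midpoint_C)),
            tg_drug=60.0, tg_polymer=106.0)
ck = couchman_karasz(0.34, 0.56, u_polymer=0.02, u_drug=0.01)
fh = fit_chi([SolubilityPoint(t, None, x) for t, x in
              zip(rd.SOLUBILITY_ANNEALING.t_anneal_C,
                  rd.SOLUBILITY_ANNEALING.x_sat)],
             FloryHugginsModel(tm_C=150.0, dhm_J_mol=54.2e3, rho_drug=1.05,
                               rho_polymer=1.17, m_drug=471.7,
                               mw_polymer=2500.0))
pvp = VTFHParams(b_K=3145.0, t0_C=14.2)
print(f"K_GT = {gt.k:.3f},  K_CK = {ck.k:.2f}")
print(f"chi = {fh.chi:.2f}")
print(f"Tg_DRS(PVP) = {tg_from_vtfh(pvp):.1f} C, "
      f"m(PVP) = {fragility_index(pvp, 99.5):.0f}")
```

prints

```
K_GT = 0.795,  K_CK = 0.61
chi = -2.31
Tg_DRS(PVP) = 99.6 C, m(PVP) = 70
```

K_GT above K_CK signals weak attractive drug–polymer interactions; the
negative χ says the same thermodynamically; the polymer is a moderately
fragile glass former whose dynamic Tg matches its calorimetric one.

The numbered scripts under `analysis/` run the two full workflows on
synthetic recordings (simulate → dielectric dynamics → thermal analysis
→ phase diagram → recrystallisation tracking), writing their tables
under `results/`.

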