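# Methods

## Scope and models

The package analyses two measurement families on drug/polymer amorphous
solid dispersions and joins them into a phase-and-state picture:

1. **Broadband dielectric spectroscopy.** Isothermal sweeps of
   ε*(ω) = ε′ − iε″ (0.1 Hz–1 MHz in the default scenarios) carry the
   structural α relaxation plus two low-frequency nuisances: ohmic
   conductivity, which adds σ-like loss ∝ 1/ω to ε″ only, and electrode
   polarisation (EP), a steep power-law rise in both parts. The
   conduction-free loss ε″_der = −(π/2)·∂ε′/∂lnω removes the ohmic term
   identically (it never touches ε′) and sharpens overlapping modes;
   EP is *not* removed and must be excluded by the fit window.
2. **Temperature-modulated DSC.** Reversible heat capacity vs.
   temperature shows the glass transition as a sigmoidal step; annealing
   protocols move the blend to its saturation composition, which is read
   back from the measured Tg through the fitted Gordon–Taylor rule.

Model assumptions, stated once: relaxations are Havriliak–Negami with
temperature-independent shape exponents over the fitted range; relaxation
times follow a VTFH law with the pre-exponent fixed at log₁₀τ∞ = −14
(phonon time scale) so that sparse per-mode datasets remain mutually
comparable; the Gordon–Taylor endpoints are constraints, not data; the
Flory–Huggins χ is temperature-independent over the 120–140 °C window it
is fitted on; densities entering volume fractions are exact constants.

## Numerical choices

**Derivative loss.** ε′ is resampled by cubic spline onto a uniform
log₁₀F grid (default 40 points/decade, never coarser than the data) and
differentiated with a Savitzky–Golay local quadratic over a 5-point
window (both configurable). The quadratic filter's truncation bias
scales with the squared grid step; at 40 pts/decade the Debye closed-form
check (ε″_der = πΔε/4 at ωτ = 1) is reproduced to ~0.4 % on a
20 pts/decade sweep, comfortably inside the 1 % the pipeline's round-trip
suite asserts. For noisy sweeps a wider window (9–15 points) trades bias
for variance; the pipeline exposes it as `smoothing_window`.

**HN fitting.** Loss curves are fitted in lmfit with bounded
least squares on (Δε, log₁₀τ_HN, α, β) per mode; when the target is
ε″_der the model curve is the *analytic* −(π/2)∂ε′_model/∂lnω, so model
and data are commensurate. ε∞ is not identifiable from a loss curve and
is recovered afterwards by matching the model ε′ to the measured ε′ in
the window (linear one-parameter problem). Initialisation seeds τ from
the highest loss peaks (one peak split by ±1 decade when two modes are
requested but only one peak is visible); three seeded perturbed restarts
guard against local minima; parameters pinned at bounds raise a boundary
flag. Two-mode fits are ordered by descending τ (slow = α₁, fast = α₂).

**Peak times.** Discrete maxima are refined with a 3-point parabola in
log₁₀F to decouple results from grid placement; τ_max = 1/(2πF_max).
For fitted HN modes the closed form
ω_max·τ_HN = [sin(πα/(2(β+1)))/sin(παβ/(2(β+1)))]^(1/α) is used (checked
against brute-force maximisation to 4+ digits). In temperature series,
modes whose peak falls outside the measured window are dropped from the
Arrhenius table: an extrapolated peak position is not a data point, and
retaining such points is the dominant error source near the sweep edges.
Neighbouring isotherms warm-start each other so mode identity survives
as the two components drift through the window.

**VTFH and derived quantities.** Unweighted least squares in log₁₀τ
(Kelvin internally, °C at every interface, offset 273.15); standard
errors from the Jacobian. Tg_DRS solves τ = 100 s in closed form — the
100 s convention is a named, overridable constant — and the fragility
m = B·Tg/(ln10·(Tg−T₀)²) agrees with the defining slope d log₁₀τ/d(Tg/T)
at Tg to 1e−6 (tested). A warning (not an error) flags m outside the
empirical 16–170 strong–fragile range.

**Composition readback.** Reference VTFH curves per composition are
interpolated linearly in log₁₀τ vs. x at fixed T and inverted on the
bracketing segment; the bracket (neighbouring reference compositions) is
reported alongside the estimate, and out-of-envelope queries clamp with
a warning. Linear interpolation is the simplest monotone choice and is
documented as such; any smooth monotone interpolant would be defensible.

**Glass-transition extraction.** The Cp derivative (Savitzky–Golay
smoothed, ~1 °C window) is scanned for peaks above 6× the median
absolute derivative; peaks closer than 5 °C merge. The midpoint is the
parabola-refined derivative maximum; linear baselines are fitted over
10 °C windows placed 5 half-widths away from the midpoint (far enough
that residual step tails ~e^(−margin/width) are negligible); onset/end
are the intersections of those baselines with the midpoint tangent and
ΔCp is the baseline gap at the midpoint. The construction is invariant
to uniform Cp offsets and to baseline slope. Zero detected steps raise
a no-transition error; two or more raise a multiple-transition report
carrying the per-step analyses.

**Mixing rules and solubility.** The Gordon–Taylor fit optimises K only,
on interior compositions (the rule passes through the fixed endpoints
identically for any K). Couchman–Karasz uncertainty uses min–max
propagation of the ΔCp uncertainties, symmetrised to a half-range. The
Flory–Huggins residual is affine in χ with slope −(1−φ)², so the χ fit
is solved in closed form (verified against an iterative minimiser to
1e−6); solubility temperatures come from a 0.5 °C grid scan with Brent
refinement, keeping the root nearest T_m (the liquidus branch anchored
at x→1, T→T_m). Solubility values below 120 °C are computed but flagged
`extrapolated`: below that, dissolution is too slow for equilibrium on
laboratory timescales. ΔH_m is accepted in kJ·mol⁻¹ at interfaces and
converted once.

**State classification.** Above both curves: undersaturated liquid.
Between Tg(x) and the solubility curve: supersaturated liquid. Below
Tg(x): glassy, additionally flagged supersaturated when below the
solubility curve. Points within 0.05 °C of a curve are labelled
`boundary` with both neighbouring states; x = 0/1 return pure-component
labels.

## Synthetic data

The generators are the package's study conditions, not tunable fixtures.
Dielectric scenarios default to the measured sweep (0.1 Hz–1 MHz,
10 pts/decade) and isotherm ladder (85–150 °C in 5 °C steps); each mode
carries its own VTFH law — interpreted as the law of τ_max, converted to
τ_HN through the shape factor so analysis recovers exactly the
prescribed parameters — an affine Δε(T), and fixed (α, β). Conductivity
is a single amplitude c_cond with ε″ += c_cond/ω; EP is a·(iω)^(−s)
(0 < s < 1) split into parts by the standard phase factor; noise is
multiplicative Gaussian with a per-(seed, temperature) substream, making
every generator a pure function of (scenario, seed). Thermogram
scenarios are logistic Cp steps (slope ΔCp/4w at the midpoint) plus
Gaussian peaks of prescribed signed enthalpy on affine baselines.
Recrystallisation series scale the fast mode's Δε by the uncrystallised
drug fraction implied by a monotone composition path and move both
modes' τ along the reference VTFH interpolation.

What the generators do **not** emulate — and hence what passing round
trips do not certify about real data: capacitance drift from powder
coalescence (only the ε″_der/ε′ normalisation addresses it),
Maxwell–Wagner interfacial polarisation, moisture effects, instrument
baseline curvature in DSC, and real nucleation-and-growth kinetics
(amplitude paths are prescribed, not physical).

## Known limitations

* Two-mode deconvolution under measurement noise is ill-conditioned once
  the fast component approaches the sweep edge: fits can relocate an
  out-of-window peak back inside it, and such points pass the in-window
  filter. Noiseless two-mode series recover (B, T₀) to ≲1–2 %; noisy
  claims are made only for single-mode pipelines (≤10 % at 1 % noise).
* Normalising ε″_der by ε′ shifts apparent peaks to higher frequency
  (as tan δ does); peak times from normalised curves are reported but
  systematically slightly short, so raw-curve times are preferred when
  amplitudes are trustworthy.
* The published VTFH table row for the 70 wt.% α₁ component is not
  internally consistent: its (B, T₀) give a τ = 100 s temperature of
  72.3 °C against the printed 70.0 °C (every other row agrees within
  0.5 °C). The corresponding consistency test documents this by failing;
  the fragility column is consistent for all rows.
* Secondary (β/γ) relaxations, Arrhenius sub-Tg fits, temperature-
  dependent χ(T), ternary (moisture) diagrams and crystallisation
  kinetics models are out of scope.

## Problem sizes

The test suite and the acceptance script run on desk-scale problems:
reference tables of ≤ 9 rows, synthetic sweeps of ~70 points per
isotherm, ladders of ≤ 13 isotherms, and time series of ≤ 17 spectra —
the full suite completes in well under a minute on one CPU.
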