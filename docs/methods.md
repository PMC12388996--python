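# Methods

## Models

**Saturation recovery.** After a saturating pulse train the longitudinal
magnetization regrows as M(t) = M₀(1 − e^(−t/T₁)). Both parameters are
estimated by unweighted nonlinear least squares; the initial T₁ guess is
the first time the signal crosses 63% of its plateau, with a log-spaced
grid restart (six decades around the sampled span) if the first attempt
fails. Standard errors come from the Jacobian-based covariance at the
optimum. A constant curve is rejected as unidentifiable rather than fitted.

**Gaussian+Lorentzian transverse decay.** The decay is modeled as two
coexisting proton pools, M(t) = M₀G·exp(−(t/T₂G)²) + M₀L·exp(−t/T₂L). The
squared-argument (Gaussian) kernel represents dephasing in rigid, dipolar-
broadened environments; the simple exponential (Lorentzian) kernel
represents mobile, motionally narrowed ones. The objective is multi-modal —
the kernels can swap roles in local minima — so the fit runs bounded least
squares (amplitudes ≥ 0) from a 5×5 log-spaced grid of time-constant pairs
spanning [min sampled t, 10 × span], with the amplitude split initialized
from the signal at the geometric-mean time, and keeps the lowest-cost
solution. Amplitudes are normalized to percentages after the fit, so they
sum to exactly 100 and the decomposition is invariant to the arbitrary
units of the magnetization axis. The component fitted with the Gaussian
kernel is always reported as G, whatever its time constant.

*Degeneracy tie-break.* If the two fitted time constants agree within 10%
the mixture is unidentifiable; both single-kernel fits are then tried and
the lower-RMS one is reported with 100% amplitude and a `degenerate` flag.
The kernel choice by residual was our decision; nothing in the two-pool
picture privileges either kernel when only one scale is present.

**Off-resonance rotating frame.** With an RF field B₁ applied at offset Δf
from resonance, the effective field has longitudinal component ΔB = 2πΔf/γ
and tilt θ = arctan(B₁/ΔB) (π/2 on resonance, → 0 at large positive
offsets; the implementation returns the obtuse angle for negative offsets).
The equilibrium ratio of locked to full magnetization follows

    Mρ/M₀ = Δf²/(Δf² + K·f₁²),   f₁ = (γ/2π)B₁,

and the dipolar dispersion law K(τc) = (10 + 37x + 12x²)/(10 + 16x),
x = (ωτc)². ω is taken as the Larmor angular frequency 2π·f₀: it is the
only reading under which the four reported (K, τc) pairs for these systems
are mutually consistent (each K(τc) lands within the reported ±; three of
four differ from the printed central value by 0.01–0.02, i.e. the source
table is itself rounded). K is strictly increasing in τc, so the inverse is
unique; it is found by Brent's method on [0, 1 µs] (xtol 1e-24, rtol 4·eps)
— liposomal lipid reorientation is nanoseconds, so the bracket is generous.
K = 1 maps to τc = 0 exactly; K < 1 is a domain error.

Near the fast-motion floor the inversion is ill-conditioned: δτ/τ ≈
δK/(2(K−1)), so for τc ≲ 2 ps (K−1 ≲ 10⁻⁷) double-precision rounding of K
alone caps round-trip accuracy near 2×10⁻⁹ relative. Everywhere in the
physically relevant range (≥ 0.01 ns) the round trip holds to 1e-9.

The fast-exchange condition ω_e·τc ≪ 1 behind the equilibrium-ratio model
is reported as a diagnostic (warning above 0.1) and never enforced: the
nanosecond correlation times of intact liposomes at 30.2 MHz sit at
ω₀τc ≈ 0.3–0.7, and the law is applied there as the experimental analysis
it reproduces did.

**K fitting.** One-parameter least squares of the saturation profile;
requires ≥ 6 offsets spanning a decade. A fully saturated profile (all
ratios > 0.99) carries no information about K and is a fit failure. Noise
can push the estimate below the physical floor of 1; such fits are flagged,
and the pipeline clamps K to 1 (τc = 0) before inversion while keeping the
raw value in the K result.

**Encapsulation efficiency and stability QC.** EE = 100·C_en/C_in; values
above 100% arise from HPLC noise and are flagged, never clamped. Stability
criteria: hydrodynamic diameter < 200 nm (injectability), PDI ≤ 0.3
(homogeneous population), |ζ| > 30 mV (electrostatic stability — the
criterion is on magnitude; cationic and anionic carriers both qualify).
The table loader flags any size exceeding 5× its formulation's median as a
probable missing-decimal transcription error and suggests division by 10;
the repair is opt-in. The built-in characterization table contains exactly
one such cell (1273 → 127.3 nm), kept verbatim with the flag.

**Dose–response.** Viability = 100·(A − blank)/(A̅_ctrl − blank). The
default model is a two-parameter logistic with asymptotes fixed at 100/0%
of control, under which the fitted midpoint is the absolute IC50. Rationale:
viability is already normalized to control, and reported IC50s for these
formulations are integers in µM — a two-parameter model matches that
precision without absorbing noise into free asymptotes. A 4PL variant is
available (`four_param=True`); its absolute IC50 is recovered from the
fitted curve in closed form and requires the asymptotes to straddle 50%.
Replicates are averaged with inverse-variance weights when replicate SDs
exist. Data that never cross 50% of control raise an error carrying the
nearest concentration bound instead of extrapolating.

## Synthetic data

Each generator evaluates the corresponding model and adds i.i.d. Gaussian
noise with SD = σ_rel × the signal amplitude (M₀ or total amplitude for
curves, 1 for the ratio profile, 100 points for viability). Gaussian i.i.d.
noise is the conventional receiver/plate-reader assumption; defaults are
σ_rel = 0.01 for NMR curves (measurement uncertainty of a few percent),
0.02 for off-resonance profiles and 0.05 for viability (typical triplicate
scatter). Sampling grids: T1 curves log-spaced on [0.01, 5]×T₁ (the signal
is at its plateau by 5·T₁); transverse decays log-spaced on
[0.1·min(T₂G,T₂L), 5·max(T₂G,T₂L)] so both scales are sampled; offsets
log-spaced on [0.05, 20]×f₁, bracketing half-saturation; 40 points per
curve, 12 offsets, 8 concentrations on 0.5–50 µM. Identical seed and
parameters give bit-identical output (numpy `default_rng`).

What the generators do **not** emulate: baseline drift, T₂-dependent echo
attenuation, receiver nonlinearity, correlated plate effects (edge wells,
evaporation), replicate heteroscedasticity, or DLS intensity-weighting
artifacts. Recovery tests therefore demonstrate estimator correctness and
noise robustness under the assumed model, not robustness to instrument
systematics.

## Pipeline and reproducibility

The end-to-end run generates inputs at the reported truth parameters of
the four liposomal systems, fits every model, screens the built-in
characterization table, and writes CSV/JSON artifacts plus a markdown
comparison report. Per-stage seeds are spawned from the master seed via
`SeedSequence` keyed by a CRC32 of the stage name (stable across
processes), so reruns are byte-identical. The report's pass/fail columns
use the reported ± for K and recovery tolerances of 5% (T₁, T₂G), 15%
(T₂L, IC50), 5 percentage points (amplitude fractions) and 0.3 ns (τc from
2%-noise profiles).

Problem sizes throughout (40-point curves, 12-offset profiles, 8-point dose
series, 10–40 seed repeats in tests, 100 simulations for the IC50 median-
error check) are desk-scale: the full test suite and the acceptance script
each run in seconds.

## Known limitations

- The reported (K, τc) table is internally consistent only to its own
  rounding: inverting K = 1.61 gives 3.27 ns against a printed 3.2, and
  K = 1.46 gives 2.75 ns against 2.8. The package reports the computed
  values; the comparison report judges K against its reported ±.
- The Lorentzian time constant of a minority pool (23% amplitude, 7.6 ms
  under a 232 ms majority) is the least-determined fit parameter; at 1%
  total-amplitude noise its seeded recovery error is typically ~6% and can
  reach ~20% on unlucky draws.
- No spectral-domain (linewidth) analysis is performed; T₂ ∝ 1/Δν½ is
  context, not code. No Bloch time-domain simulation of the pulse sequence;
  only the equilibrium ratio is modeled. No synergy index is computed for
  the co-formulations.
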