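# liporelax

Quantitative analysis toolkit for cationic liposomal nanoformulations:
proton NMR relaxometry, off-resonance rotating-frame correlation-time
analysis, DLS/zeta stability QC, and MTT dose–response fitting. It targets
the characterization workflow used for drug-delivery liposomes (here:
DOTAP:POPC carriers co-encapsulating acteoside with cannabidiol or
naringenin, tested against glioma cell lines), but every stage is generic.

## What it computes

**Laboratory-frame relaxation.** Spin-lattice recovery after saturation is
fitted with M(t) = M₀(1 − e^(−t/T₁)); transverse decays are decomposed into
a rigid and a mobile proton pool,

    M(t) = M₀G·exp(−(t/T₂G)²) + M₀L·exp(−t/T₂L),

with the Gaussian kernel capturing dipolar-broadened, ordered environments
and the Lorentzian (exponential) kernel motionally narrowed ones. Amplitudes
are reported as percentages of the summed amplitude; the fit is multi-start
to avoid the kernel-swap local minimum.

**Off-resonance rotating frame.** An RF field applied at offset Δf creates
an effective field tilted at θ = arctan(B₁/ΔB), ΔB = 2πΔf/γ. The locked
magnetization relaxes to an equilibrium ratio

    Mρ/M₀ = Δf² / (Δf² + K·((γ/2π)B₁)²),

a saturation curve with half-rise at Δf = (γ/2π)B₁·√K. The enhancement
factor K carries the rotational dynamics through

    K(τc) = (10 + 37x + 12x²)/(10 + 16x),   x = (ω₀τc)²,

which equals 1 for fast tumbling and grows monotonically, so a fitted K
inverts uniquely (Brent root search) to the rotational correlation time τc.

**Formulation QC.** Size/PDI/zeta tables are screened against the
injectability criteria (size < 200 nm, PDI ≤ 0.3, |ζ| > 30 mV);
encapsulation efficiency is EE = 100·C_en/C_in. A loader rule flags
probable missing-decimal transcription errors instead of silently editing.

**Dose–response.** MTT absorbances are normalized to untreated control and
fitted with a two-parameter logistic v(c) = 100/(1 + (c/IC50)^h) (free-
asymptote 4PL behind a flag), plus fibroblast/tumor selectivity ratios.

A seeded synthetic-data module generates every input the fitters consume,
so the whole chain is testable by parameter recovery without instrument
data.

## Worked example

```
$ python examples/correlation_time.py
half-saturation frequency scale (γ/2π)·B1 = 21.2887 kHz
tau_c = 1.8 ns  ->  K = 1.2202
tau_c = 2.8 ns  ->  K = 1.4742
tau_c = 3.2 ns  ->  K = 1.5896
tau_c = 3.6 ns  ->  K = 1.7107

fitted K = 1.5896 ± 0.0000
inverted tau_c = 3.200 ns  (omega*tau_c = 0.607)
```

On a 30.2 MHz spectrometer with a 5 G spin-lock, slower tumbling (larger
τc) raises K and shifts the saturation profile to larger offsets; fitting a
noiseless profile generated at τc = 3.2 ns returns K = 1.5896 and inverts
back to 3.200 ns exactly. The ω·τc ≈ 0.6 diagnostic marks these lipids at
the edge of the fast-motion regime.

```
$ python examples/relaxation_fitting.py
T1 = 2.608 s ± 0.032 (truth 2.6 s)
Gaussian pool: 76.3% at T2G = 234.5 ms (truth 77% at 232 ms)
Lorentzian pool: 23.7% at T2L = 7.85 ms (truth 23% at 7.6 ms)
```

The other examples cover QC screening (`formulation_qc.py`, which flags the
one 1273 nm transcription outlier and passes all four formulations over 21
days), IC50 fitting with selectivity (`dose_response_ic50.py`), and the
end-to-end seeded pipeline (`full_pipeline.py`), which writes fit CSVs, a
QC JSON and a markdown comparison report. The same stages are exposed as a
thin CLI: `liporelax simulate|t1|t2|offres|qc|ic50|report`.

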