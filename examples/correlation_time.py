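"""Rotational correlation time from an off-resonance saturation profile.

Generates a noiseless Mρ/M0 vs Δf profile for a lipid system tumbling with
τc = 3.2 ns on a 30.2 MHz spectrometer with a 5 G spin-lock, fits the
relaxation enhancement factor K, and inverts the dispersion law for τc.
"""

import warnings

from liporelax import (
    NoiseSpec,
    SpectrometerConfig,
    analyze_offresonance,
    compute_k_factor,
    gen_offres_profile,
)

warnings.filterwarnings("ignore", message=".*fast-motion regime.*")

config = SpectrometerConfig.from_gauss(larmor_mhz=30.2, b1_gauss=5.0)
print(f"half-saturation frequency scale (γ/2π)·B1 = {config.b1_frequency_hz / 1e3:.4f} kHz")

# forward: the dispersion law maps slower tumbling to larger K
for tau_ns in (1.8, 2.8, 3.2, 3.6):
    k = compute_k_factor(tau_ns * 1e-9, config)
    print(f"tau_c = {tau_ns} ns  ->  K = {k:.4f}")

# inverse: recover tau_c from a measured profile
profile = gen_offres_profile(3.2e-9, config, noise=NoiseSpec(0.0, 0))
kfit, tau = analyze_offresonance(profile, config)
print(f"\nfitted K = {kfit.k:.4f} ± {kfit.k_stderr:.4f}")
print(f"inverted tau_c = {tau.tau_c_ns:.3f} ns  (omega*tau_c = {tau.omega_tau:.3f})")
print("K grows monotonically with tau_c, so the inversion is unique;")
print("omega*tau_c ~ 0.6 says these lipids sit at the edge of the fast-motion regime.")
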