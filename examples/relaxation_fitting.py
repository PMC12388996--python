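"""Fitting T1 recovery and the two-component transverse decay.

Simulates 1%-noise curves at the parameters of the acteoside+cannabidiol
liposome system (T1 = 2.6 s; 77% Gaussian at 232 ms + 23% Lorentzian at
7.6 ms) and recovers them by least squares.
"""

from liporelax import NoiseSpec, fit_t1, fit_t2_mixture, gen_t1_curve, gen_t2_decay

# spin-lattice relaxation: saturation recovery toward equilibrium
curve = gen_t1_curve(t1_s=2.6, m0=1.0, noise=NoiseSpec(0.01, seed=1))
res = fit_t1(curve)
print(f"T1 = {res.t1_s:.3f} s ± {res.t1_stderr:.3f} (truth 2.6 s)")

# transverse decay: rigid (Gaussian) vs mobile (Lorentzian) proton pools
decay = gen_t2_decay(
    m0g_frac_percent=77.0, t2g_s=0.232, t2l_s=0.0076, noise=NoiseSpec(0.01, seed=1)
)
mix = fit_t2_mixture(decay)
print(
    f"Gaussian pool: {mix.m0g_percent:.1f}% at T2G = {mix.t2g_ms:.1f} ms"
    " (truth 77% at 232 ms)"
)
print(
    f"Lorentzian pool: {mix.m0l_percent:.1f}% at T2L = {mix.t2l_ms:.2f} ms"
    " (truth 23% at 7.6 ms)"
)
print(
    "\nThe large rigid fraction with a short Lorentzian tail is the signature of\n"
    "an ordered bilayer coexisting with a small, fast-dephasing mobile pool."
)
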