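"""Instrument configuration and shared physical constants.

All NMR stages share a single :class:`SpectrometerConfig` describing the
pulsed spectrometer: the proton Larmor frequency, the amplitude of the
radio-frequency field B1, the gyromagnetic ratio and the sample temperature.
Internally everything is SI (Hz, tesla, rad/s/T, kelvin); B1 may be supplied
in gauss at the interface since that is the unit instrument panels use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA).
PROTON_GAMMA = 2.6752218744e8

#: Tesla per gauss.
GAUSS_TO_TESLA = 1e-4


@dataclass(frozen=True)
class SpectrometerConfig:
    """Constants of the pulsed NMR spectrometer used throughout the analysis.

    Defaults describe the instrument the liposome measurements assume:
    30.2 MHz proton resonance, a 5 G spin-locking field, 303 K.

    Attributes
    ----------
    larmor_frequency_hz:
        Proton resonance frequency in the static field B0, Hz.
    b1_tesla:
        Amplitude of the rotating RF field B1, tesla.
    gyromagnetic_ratio:
        Nuclear gyromagnetic ratio γ, rad s^-1 T^-1 (proton by default).
    temperature_k:
        Sample temperature, kelvin.
    """

    larmor_frequency_hz: float = 3.02e7
    b1_tesla: float = 5e-4
    gyromagnetic_ratio: float = PROTON_GAMMA
    temperature_k: float = 303.0

    def __post_init__(self) -> None:
        for name in ("larmor_frequency_hz", "b1_tesla", "gyromagnetic_ratio", "temperature_k"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @classmethod
    def from_gauss(
        cls,
        larmor_mhz: float = 30.2,
        b1_gauss: float = 5.0,
        gyromagnetic_ratio: float = PROTON_GAMMA,
        temperature_k: float = 303.0,
    ) -> "SpectrometerConfig":
        """Build a config from panel units (MHz and gauss)."""
        return cls(
            larmor_frequency_hz=larmor_mhz * 1e6,
            b1_tesla=b1_gauss * GAUSS_TO_TESLA,
            gyromagnetic_ratio=gyromagnetic_ratio,
            temperature_k=temperature_k,
        )

    @property
    def omega0(self) -> float:
        """Larmor angular frequency ω0 = 2π·f0, rad/s."""
        return 2.0 * math.pi * self.larmor_frequency_hz

    @property
    def b1_frequency_hz(self) -> float:
        """B1 expressed as an equivalent precession frequency (γ/2π)·B1, Hz.

        This is the natural frequency scale of the off-resonance saturation
        profile: ~21.3 kHz for a 5 G proton spin-lock.
        """
        return self.gyromagnetic_ratio / (2.0 * math.pi) * self.b1_tesla


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise specification for the synthetic generators.

    ``sigma_relative`` scales the noise SD by the signal amplitude (the t=0
    magnetization, the saturation plateau, or 100% viability, depending on
    the generator). The same seed and parameters always reproduce the same
    draw bit-for-bit.
    """

    sigma_relative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_relative < 0:
            raise InvalidParameterError("sigma_relative must be non-negative")


@dataclass(frozen=True)
class QCCriteria:
    """Injectability/stability thresholds for liposome characterization.

    Defaults encode the accepted nanocarrier criteria: hydrodynamic diameter
    below 200 nm for injectable use, polydispersity index at or below 0.3
    for a homogeneous population, and |zeta potential| above 30 mV for
    electrostatic colloidal stability.
    """

    max_size_nm: float = 200.0
    max_pdi: float = 0.3
    min_abs_zeta_mv: float = 30.0

    def __post_init__(self) -> None:
        for name in ("max_size_nm", "max_pdi", "min_abs_zeta_mv"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
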