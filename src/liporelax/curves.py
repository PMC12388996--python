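"""In-memory containers for relaxation curves and off-resonance profiles.

CSV layouts:

* ``RelaxationCurve``: columns ``t_s`` (seconds) and ``M`` (arbitrary units).
* ``OffResonanceProfile``: columns ``delta_f_hz`` and ``ratio`` (Mρ/M0).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError


class CurveKind(str, enum.Enum):
    SATURATION_RECOVERY = "saturation_recovery"
    TRANSVERSE_DECAY = "transverse_decay"


@dataclass
class RelaxationCurve:
    """Time-stamped magnetization samples from a T1 or T2 experiment.

    ``times`` are in seconds and must be strictly increasing; at least
    8 points are required so a fit is meaningfully overdetermined.
    """

    times: np.ndarray
    magnetization: np.ndarray
    kind: CurveKind
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.magnetization = np.asarray(self.magnetization, dtype=float)
        self.kind = CurveKind(self.kind)
        if self.times.ndim != 1 or self.times.shape != self.magnetization.shape:
            raise InvalidParameterError("times and magnetization must be 1-D and equal length")
        if len(self.times) < 8:
            raise InvalidParameterError("a relaxation curve needs at least 8 samples")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise InvalidParameterError("times must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times, "M": self.magnetization})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: CurveKind | str, label: str = "") -> "RelaxationCurve":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["M"].to_numpy(), CurveKind(kind), label or str(path))


@dataclass
class OffResonanceProfile:
    """(Δf, Mρ/M0) pairs from the off-resonance rotating-frame experiment.

    Offsets are in Hz, nonzero, strictly increasing in magnitude; ratios are
    dimensionless and allowed to stray into [-0.1, 1.1] to accommodate noise.
    """

    offsets_hz: np.ndarray
    ratios: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.offsets_hz.ndim != 1 or self.offsets_hz.shape != self.ratios.shape:
            raise InvalidParameterError("offsets and ratios must be 1-D and equal length")
        if np.any(self.offsets_hz == 0):
            raise InvalidParameterError("offsets must be nonzero (Δf = 0 is on-resonance)")
        if np.any(np.diff(np.abs(self.offsets_hz)) <= 0):
            raise InvalidParameterError("offsets must be strictly increasing in magnitude")
        if np.any(self.ratios < -0.1) or np.any(self.ratios > 1.1):
            raise InvalidParameterError("ratios outside [-0.1, 1.1] are not physical Mρ/M0 values")

    def __len__(self) -> int:
        return len(self.offsets_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_f_hz": self.offsets_hz, "ratio": self.ratios})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "OffResonanceProfile":
        df = pd.read_csv(path)
        return cls(df["delta_f_hz"].to_numpy(), df["ratio"].to_numpy(), label or str(path))
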