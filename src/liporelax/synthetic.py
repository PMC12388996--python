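"""Seeded generators for every input the analysis pipeline consumes.

Each generator evaluates the closed-form model the corresponding fitter
assumes and adds i.i.d. Gaussian noise with SD = ``sigma_relative`` × the
signal amplitude (the saturation plateau, the t=0 magnetization, unity for
the off-resonance ratio, or 100% viability). With ``sigma_relative = 0`` the
output equals the model exactly; with identical seed and parameters the
output is bit-identical across runs.

Default sampling grids:

* T1 recovery — log-spaced over [0.01·T1, 5·T1] (the signal is within 1% of
  its plateau by 5·T1);
* transverse decay — log-spaced over [0.1·min(T2G, T2L), 5·max(T2G, T2L)] so
  both decay scales are sampled;
* off-resonance offsets — log-spaced over [0.05, 20] × (γ/2π)·B1, bracketing
  the half-saturation offset from well below to well above.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NoiseSpec, SpectrometerConfig
from .curves import CurveKind, OffResonanceProfile, RelaxationCurve
from .dose_response import DoseResponseSet, logistic2
from .errors import InvalidParameterError
from .offresonance import compute_k_factor, model_offres_ratio
from .qc import FormulationRecord
from .relaxometry import T2MixtureFitResult, model_t1, model_t2_mixture

DEFAULT_N_POINTS = 40


def _rng(noise: NoiseSpec) -> np.random.Generator:
    return np.random.default_rng(noise.seed)


def default_t1_times(t1_s: float, n: int = DEFAULT_N_POINTS) -> np.ndarray:
    return np.geomspace(0.01 * t1_s, 5.0 * t1_s, n)


def default_t2_times(t2g_s: float, t2l_s: float, n: int = DEFAULT_N_POINTS) -> np.ndarray:
    return np.geomspace(0.1 * min(t2g_s, t2l_s), 5.0 * max(t2g_s, t2l_s), n)


def default_offsets(config: SpectrometerConfig, n: int = 12) -> np.ndarray:
    f1 = config.b1_frequency_hz
    return np.geomspace(0.05 * f1, 20.0 * f1, n)


def gen_t1_curve(
    t1_s: float,
    m0: float = 1.0,
    times_s: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> RelaxationCurve:
    """Saturation-recovery curve M(t) = M0·(1 − exp(−t/T1)) + ε."""
    if t1_s <= 0 or m0 <= 0:
        raise InvalidParameterError("t1 and m0 must be positive")
    t = np.asarray(times_s, dtype=float) if times_s is not None else default_t1_times(t1_s)
    clean = model_t1(t, t1_s, m0)
    values = clean + _rng(noise).normal(0.0, noise.sigma_relative * m0, size=t.shape)
    return RelaxationCurve(
        t, values, CurveKind.SATURATION_RECOVERY,
        label=f"synthetic T1={t1_s:g}s seed={noise.seed}",
    )


def gen_t2_decay(
    m0g_frac_percent: float,
    t2g_s: float,
    t2l_s: float,
    m0_total: float = 1.0,
    times_s: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> RelaxationCurve:
    """Two-component transverse decay with the Gaussian fraction in percent."""
    if not 0.0 <= m0g_frac_percent <= 100.0:
        raise InvalidParameterError("m0g_frac_percent must lie in [0, 100]")
    if t2g_s <= 0 or t2l_s <= 0 or m0_total <= 0:
        raise InvalidParameterError("time constants and amplitude must be positive")
    t = (
        np.asarray(times_s, dtype=float)
        if times_s is not None
        else default_t2_times(t2g_s, t2l_s)
    )
    params = T2MixtureFitResult(
        m0g_percent=m0g_frac_percent,
        t2g_s=t2g_s,
        m0l_percent=100.0 - m0g_frac_percent,
        t2l_s=t2l_s,
        m0_total=m0_total,
    )
    clean = model_t2_mixture(t, params)
    values = clean + _rng(noise).normal(0.0, noise.sigma_relative * m0_total, size=t.shape)
    return RelaxationCurve(
        t, values, CurveKind.TRANSVERSE_DECAY,
        label=f"synthetic T2G={t2g_s:g}s/T2L={t2l_s:g}s seed={noise.seed}",
    )


def gen_offres_profile(
    tau_c_s: float,
    config: SpectrometerConfig = SpectrometerConfig(),
    offsets_hz: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> OffResonanceProfile:
    """Off-resonance saturation profile for a given correlation time.

    K is computed from τc, then Mρ/M0 evaluated at each offset; noise is
    added on the ratio scale (amplitude 1) and clipped to the container's
    physical allowance [-0.1, 1.1].
    """
    if tau_c_s < 0:
        raise InvalidParameterError("tau_c must be non-negative")
    offs = (
        np.asarray(offsets_hz, dtype=float)
        if offsets_hz is not None
        else default_offsets(config)
    )
    if np.any(offs == 0):
        raise InvalidParameterError("offsets must be nonzero")
    k = compute_k_factor(tau_c_s, config)
    clean = model_offres_ratio(offs, k, config)
    ratios = clean + _rng(noise).normal(0.0, noise.sigma_relative, size=offs.shape)
    ratios = np.clip(ratios, -0.1, 1.1)
    return OffResonanceProfile(
        offs, ratios, label=f"synthetic tau_c={tau_c_s:g}s seed={noise.seed}"
    )


def gen_dls_table(
    n_formulations: int,
    n_timepoints: int,
    size_mean_nm: float = 140.0,
    pdi_mean: float = 0.21,
    zeta_mean_mv: float = 36.0,
    noise: NoiseSpec = NoiseSpec(),
    timepoint_days: tuple[int, ...] = (0, 7, 14, 21),
) -> list[FormulationRecord]:
    """Characterization table with jittered means and populated replicate SDs.

    One record per formulation × timepoint; each mean is jittered by
    Gaussian noise of SD = sigma_relative × the column mean, and the SD
    fields carry that same scale (what triplicate scatter would show).
    """
    if n_formulations < 1 or n_timepoints < 1:
        raise InvalidParameterError("counts must be at least 1")
    rng = _rng(noise)
    days = list(timepoint_days[:n_timepoints])
    while len(days) < n_timepoints:
        days.append(days[-1] + 7)
    records = []
    for i in range(n_formulations):
        for day in days:
            s = noise.sigma_relative
            records.append(
                FormulationRecord(
                    formulation=f"F{i + 1}",
                    timepoint_days=day,
                    size_nm=size_mean_nm + rng.normal(0.0, s * size_mean_nm),
                    pdi=float(np.clip(pdi_mean + rng.normal(0.0, s * pdi_mean), 0.0, 1.0)),
                    zeta_mv=zeta_mean_mv + rng.normal(0.0, s * abs(zeta_mean_mv)),
                    size_sd=s * size_mean_nm,
                    pdi_sd=s * pdi_mean,
                    zeta_sd=s * abs(zeta_mean_mv),
                )
            )
    return records


def gen_dose_response(
    ic50_um: float,
    hill: float = 1.0,
    concentrations_um: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 1,
    **labels,
) -> DoseResponseSet:
    """Viability matrix from the fixed-asymptote logistic, percent of control.

    viability(c) = 100/(1 + (c/IC50)^h) + ε with ε of SD = sigma_relative ×
    100 (percentage points). c = 0 rows are exact controls before noise.
    """
    if ic50_um <= 0 or hill <= 0:
        raise InvalidParameterError("ic50 and hill must be positive")
    c = (
        np.asarray(concentrations_um, dtype=float)
        if concentrations_um is not None
        else np.geomspace(0.5, 50.0, 8)
    )
    clean = logistic2(c, ic50_um, hill)
    shape = (len(c), n_replicates) if n_replicates > 1 else (len(c),)
    values = (clean if n_replicates == 1 else clean[:, None]) + _rng(noise).normal(
        0.0, noise.sigma_relative * 100.0, size=shape
    )
    return DoseResponseSet(concentrations_um=c, viability_percent=values, **labels)


def to_long_frame(sample_id: str, x: np.ndarray, y: np.ndarray, y_sd=None) -> pd.DataFrame:
    """Long-format fixture table: sample_id, x, y, y_sd."""
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "y_sd": np.nan if y_sd is None else y_sd,
        }
    )


def write_fixture_json(
    path: str | Path, kind: str, params: dict, noise: NoiseSpec, x: np.ndarray, y: np.ndarray
) -> None:
    """Write a generator output plus its full provenance (seed included)."""
    payload = {
        "kind": kind,
        "params": params,
        "noise": asdict(noise),
        "x": np.asarray(x).tolist(),
        "y": np.asarray(y).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
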