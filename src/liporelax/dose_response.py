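"""MTT viability normalization and IC50 estimation by logistic fitting.

Raw formazan absorbances are normalized to the untreated control (and an
optional blank), giving viability as a percentage of control. The default
dose-response model is a two-parameter logistic with asymptotes fixed at
100% (no drug) and 0% (complete kill),

    v(c) = 100 / (1 + (c / IC50)^h),

whose IC50 is by construction the absolute IC50 — the concentration at 50%
of control. A four-parameter logistic with free asymptotes is available
behind a flag; its absolute IC50 is then recovered by root search on the
fitted curve rather than read off the inflection parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DomainError, InvalidParameterError, UnestimableIC50Error


@dataclass
class DoseResponseSet:
    """Concentration × viability data for one cell line / formulation / timepoint.

    ``viability_percent`` may be 1-D (one value per concentration) or 2-D
    with replicates along the second axis; NaNs mark missing replicates.
    """

    concentrations_um: np.ndarray
    viability_percent: np.ndarray
    cell_line: str = ""
    formulation: str = ""
    timepoint_h: float = math.nan

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        self.viability_percent = np.asarray(self.viability_percent, dtype=float)
        if self.concentrations_um.ndim != 1:
            raise InvalidParameterError("concentrations must be 1-D")
        if np.any(self.concentrations_um < 0):
            raise InvalidParameterError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations_um) <= 0):
            raise InvalidParameterError("concentrations must be strictly increasing")
        if self.viability_percent.shape[0] != len(self.concentrations_um):
            raise InvalidParameterError("viability rows must match concentrations")
        if len(np.unique(self.concentrations_um)) < 4:
            raise InvalidParameterError("IC50 fitting needs at least 4 distinct concentrations")

    def mean_viability(self) -> np.ndarray:
        v = self.viability_percent
        return v if v.ndim == 1 else np.nanmean(v, axis=1)

    def viability_sd(self) -> np.ndarray | None:
        v = self.viability_percent
        if v.ndim == 1 or v.shape[1] < 2:
            return None
        return np.nanstd(v, axis=1, ddof=1)


@dataclass(frozen=True)
class IC50Result:
    """Logistic fit of a dose-response set."""

    ic50_um: float
    hill: float
    ic50_stderr: float
    hill_stderr: float
    residual_rms: float
    model: str = "2PL"  # or "4PL"
    top: float = 100.0
    bottom: float = 0.0
    cell_line: str = ""
    formulation: str = ""
    timepoint_h: float = math.nan

    def __post_init__(self) -> None:
        if self.ic50_um <= 0:
            raise InvalidParameterError("fitted IC50 must be positive")


def logistic2(c: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    """Two-parameter logistic viability, asymptotes fixed at 100/0 %."""
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, 100.0)
    pos = c > 0
    out[pos] = 100.0 / (1.0 + (c[pos] / ic50) ** hill)
    return out


def logistic4(c: np.ndarray, ic50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    """Four-parameter logistic; ``ic50`` here is the relative inflection."""
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, top)
    pos = c > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (c[pos] / ic50) ** hill)
    return out


def normalize_to_control(
    raw_absorbance: np.ndarray,
    concentrations_um: np.ndarray,
    control_column: int = 0,
    blank: float = 0.0,
    **labels,
) -> DoseResponseSet:
    """Convert an absorbance matrix to percent-of-control viability.

    ``raw_absorbance`` has one row per concentration (replicates along axis
    1 if 2-D); the row indexed by ``control_column`` is the untreated
    control, which maps to exactly 100%. viability = 100·(A − blank)/(A̅_ctrl − blank).
    """
    a = np.asarray(raw_absorbance, dtype=float)
    ctrl = float(np.nanmean(a[control_column]))
    if ctrl <= blank:
        raise DomainError("control absorbance must exceed the blank")
    viability = 100.0 * (a - blank) / (ctrl - blank)
    return DoseResponseSet(
        concentrations_um=np.asarray(concentrations_um, dtype=float),
        viability_percent=viability,
        **labels,
    )


def fit_ic50(data: DoseResponseSet, four_param: bool = False) -> IC50Result:
    """Fit the logistic dose-response model and report the absolute IC50.

    Replicates are averaged with inverse-variance weights when replicate SDs
    are available. Data never crossing 50% of control cannot bound the IC50:
    an :class:`UnestimableIC50Error` carries the nearest concentration bound.
    """
    c = data.concentrations_um
    v = data.mean_viability()
    sd = data.viability_sd()

    if np.nanmin(v) > 50.0:
        raise UnestimableIC50Error(
            "viability never falls below 50% of control; IC50 exceeds the tested range",
            nearest_bound_um=float(c[-1]),
        )
    if np.nanmax(v) < 50.0:
        raise UnestimableIC50Error(
            "viability never rises above 50% of control; IC50 is below the tested range",
            nearest_bound_um=float(c[c > 0].min()),
        )

    sigma = None
    if sd is not None and np.all(np.isfinite(sd)) and np.all(sd > 0):
        sigma = sd

    # initial IC50: concentration where the mean response crosses 50
    below = np.nonzero(v <= 50.0)[0]
    ic50_0 = float(c[below[0]]) if len(below) and c[below[0]] > 0 else float(np.median(c[c > 0]))

    if four_param:
        p0 = [ic50_0, 1.0, float(np.nanmax(v)), float(max(np.nanmin(v), 0.0))]
        bounds = ([1e-9, 0.05, 50.0, 0.0], [np.inf, 20.0, 200.0, 50.0])
        model = logistic4
    else:
        p0 = [ic50_0, 1.0]
        bounds = ([1e-9, 0.05], [np.inf, 20.0])
        model = logistic2
    try:
        popt, pcov = optimize.curve_fit(
            model, c, v, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise UnestimableIC50Error(f"logistic fit did not converge: {exc}") from exc

    perr = np.sqrt(np.diag(pcov))
    rms = float(np.sqrt(np.mean((model(c, *popt) - v) ** 2)))
    if four_param:
        ic50_rel, hill, top, bottom = map(float, popt)
        ic50_abs = _absolute_ic50(ic50_rel, hill, top, bottom, c)
        return IC50Result(
            ic50_um=ic50_abs, hill=hill,
            ic50_stderr=float(perr[0]), hill_stderr=float(perr[1]),
            residual_rms=rms, model="4PL", top=top, bottom=bottom,
            cell_line=data.cell_line, formulation=data.formulation,
            timepoint_h=data.timepoint_h,
        )
    ic50, hill = map(float, popt)
    return IC50Result(
        ic50_um=ic50, hill=hill,
        ic50_stderr=float(perr[0]), hill_stderr=float(perr[1]),
        residual_rms=rms, model="2PL",
        cell_line=data.cell_line, formulation=data.formulation,
        timepoint_h=data.timepoint_h,
    )


def _absolute_ic50(ic50_rel, hill, top, bottom, c) -> float:
    """Concentration where the fitted 4PL crosses 50% of control."""
    if not (bottom < 50.0 < top):
        raise UnestimableIC50Error(
            "fitted 4PL asymptotes do not straddle 50% of control; absolute IC50 undefined"
        )
    # closed form: 50 = bottom + (top-bottom)/(1+(x/ic50)^h)
    ratio = (top - bottom) / (50.0 - bottom) - 1.0
    return float(ic50_rel * ratio ** (1.0 / hill))


def selectivity_summary(
    results: list[IC50Result], normal_line: str = "MRC-5"
) -> pd.DataFrame:
    """Selectivity indices: IC50(normal fibroblast) / IC50(tumor line).

    Pairs results by (formulation, timepoint); ratios above 1 mean the
    formulation spares the normal line relative to the tumor line. Tumor
    results lacking a matched fibroblast value are skipped with a warning.
    """
    import warnings

    normals = {
        (r.formulation, r.timepoint_h): r for r in results if r.cell_line == normal_line
    }
    rows = []
    for r in results:
        if r.cell_line == normal_line:
            continue
        key = (r.formulation, r.timepoint_h)
        ref = normals.get(key)
        if ref is None:
            warnings.warn(
                f"no {normal_line} IC50 for {key}; skipping selectivity ratio", stacklevel=2
            )
            continue
        rows.append(
            {
                "formulation": r.formulation,
                "timepoint_h": r.timepoint_h,
                "tumor_line": r.cell_line,
                "ic50_tumor_um": r.ic50_um,
                "ic50_normal_um": ref.ic50_um,
                "selectivity": ref.ic50_um / r.ic50_um,
            }
        )
    return pd.DataFrame(rows)
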