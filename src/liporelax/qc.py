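"""Formulation quality control: DLS/zeta characterization tables, stability
criteria, and encapsulation efficiency.

A characterization table holds one row per formulation × timepoint with mean
± SD of the hydrodynamic diameter (nm), polydispersity index and zeta
potential (mV). The stability screen applies three injectability criteria:
size below 200 nm, PDI at or below 0.3, |zeta| above 30 mV.

The loader guards against transcription slips of the "missing decimal
separator" kind (a 127.3 entered as 1273): values more than 5× the
formulation's median are flagged and a decimal repair (÷10) suggested, but
never applied silently.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QCCriteria
from .errors import DomainError, EmptyInputError, InvalidParameterError

#: Values beyond this multiple of the formulation median are flagged as
#: probable transcription errors.
OUTLIER_FOLD = 5.0


@dataclass(frozen=True)
class FormulationRecord:
    """One formulation × timepoint row of a characterization table."""

    formulation: str
    timepoint_days: int
    size_nm: float
    pdi: float
    zeta_mv: float
    size_sd: float = math.nan
    pdi_sd: float = math.nan
    zeta_sd: float = math.nan

    def __post_init__(self) -> None:
        if self.size_nm <= 0:
            raise InvalidParameterError("size_nm must be positive")
        if not 0.0 <= self.pdi <= 1.0:
            raise InvalidParameterError("pdi must lie in [0, 1]")
        if self.timepoint_days < 0:
            raise InvalidParameterError("timepoint_days must be non-negative")


@dataclass(frozen=True)
class EncapsulationInput:
    """Concentrations for the encapsulation-efficiency ratio.

    ``c_encapsulated`` is the compound actually recovered from disrupted
    liposomes (HPLC), ``c_initial`` the amount used in preparation; both in
    µg/mL (any shared unit works — the ratio is scale-invariant).
    """

    c_encapsulated: float
    c_initial: float
    compound: str = ""

    def __post_init__(self) -> None:
        if self.c_encapsulated < 0 or self.c_initial < 0:
            raise InvalidParameterError("concentrations must be non-negative")


_PM = re.compile(r"^\s*([-+]?[\d.]+)\s*(?:±|\+/-)\s*([\d.]+)\s*$")


def parse_mean_sd(cell: str | float) -> tuple[float, float]:
    """Parse an ``m ± s`` table cell; SD is optional (NaN when absent)."""
    if isinstance(cell, (int, float)):
        return float(cell), math.nan
    m = _PM.match(cell)
    if m:
        return float(m.group(1)), float(m.group(2))
    return float(cell), math.nan


def load_table(path: str | Path, repair_decimals: bool = False) -> list[FormulationRecord]:
    """Read a characterization CSV into records.

    Expected columns: formulation, timepoint_days, size_nm, size_sd, pdi,
    pdi_sd, zeta_mv, zeta_sd (SD columns optional). With
    ``repair_decimals=True``, flagged size outliers (> 5× the formulation
    median) are divided by 10; otherwise they are kept and reported by
    :func:`flag_outliers`.
    """
    df = pd.read_csv(path)
    records = [
        FormulationRecord(
            formulation=str(r["formulation"]),
            timepoint_days=int(r["timepoint_days"]),
            size_nm=float(r["size_nm"]),
            pdi=float(r["pdi"]),
            zeta_mv=float(r["zeta_mv"]),
            size_sd=float(r.get("size_sd", math.nan)),
            pdi_sd=float(r.get("pdi_sd", math.nan)),
            zeta_sd=float(r.get("zeta_sd", math.nan)),
        )
        for _, r in df.iterrows()
    ]
    if repair_decimals:
        records = apply_decimal_repair(records)
    return records


def flag_outliers(records: list[FormulationRecord]) -> list[tuple[FormulationRecord, float]]:
    """Detect probable missing-decimal transcription errors in sizes.

    Returns (record, suggested_size_nm) pairs for every record whose size
    exceeds 5× the median size of its own formulation series; the suggestion
    is the value divided by 10.
    """
    out = []
    by_form: dict[str, list[float]] = {}
    for rec in records:
        by_form.setdefault(rec.formulation, []).append(rec.size_nm)
    for rec in records:
        med = float(np.median(by_form[rec.formulation]))
        if rec.size_nm > OUTLIER_FOLD * med:
            out.append((rec, rec.size_nm / 10.0))
    return out


def apply_decimal_repair(records: list[FormulationRecord]) -> list[FormulationRecord]:
    """Apply the suggested ÷10 repair to every flagged size outlier."""
    flagged = {id(rec): fix for rec, fix in flag_outliers(records)}
    return [
        replace(rec, size_nm=flagged[id(rec)]) if id(rec) in flagged else rec
        for rec in records
    ]


def records_to_frame(records: list[FormulationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summarize_table(records: list[FormulationRecord]) -> dict:
    """Global min/max/mean per column plus per-formulation time trends."""
    if not records:
        raise EmptyInputError("summarize_table needs at least one record")
    df = records_to_frame(records)
    cols = ["size_nm", "pdi", "zeta_mv"]
    overall = {
        c: {"min": float(df[c].min()), "max": float(df[c].max()), "mean": float(df[c].mean())}
        for c in cols
    }
    trends = {
        name: grp.sort_values("timepoint_days")[["timepoint_days", *cols]]
        .set_index("timepoint_days")
        .to_dict("index")
        for name, grp in df.groupby("formulation")
    }
    return {"overall": overall, "by_formulation": trends, "n_records": len(records)}


def check_stability(
    records: list[FormulationRecord], criteria: QCCriteria | None = None
) -> pd.DataFrame:
    """Screen every record against the three injectability criteria.

    Returns a frame with per-criterion booleans (size_ok, pdi_ok, zeta_ok)
    and the conjunction ``all_ok``. A formulation is stable over the study
    window iff all of its records pass all three.
    """
    if not records:
        raise EmptyInputError("check_stability needs at least one record")
    criteria = criteria or QCCriteria()
    df = records_to_frame(records)
    df["size_ok"] = df["size_nm"] < criteria.max_size_nm
    df["pdi_ok"] = df["pdi"] <= criteria.max_pdi
    df["zeta_ok"] = df["zeta_mv"].abs() > criteria.min_abs_zeta_mv
    df["all_ok"] = df["size_ok"] & df["pdi_ok"] & df["zeta_ok"]
    return df


def formulation_verdicts(report: pd.DataFrame) -> dict[str, bool]:
    """Collapse a stability report to one pass/fail per formulation."""
    return report.groupby("formulation")["all_ok"].all().to_dict()


def encapsulation_efficiency(inp: EncapsulationInput) -> float:
    """EE = 100 × C_en / C_in, percent.

    Values above 100% are physically impossible but arise from HPLC
    measurement noise; they are returned as-is (a warning is the caller's
    concern via :func:`ee_flag`), never clamped.
    """
    if inp.c_initial == 0:
        raise DomainError("c_initial must be positive to form the EE ratio")
    return 100.0 * inp.c_encapsulated / inp.c_initial


def ee_flag(ee_percent: float) -> str | None:
    """Return a note when EE exceeds 100% (measurement noise), else None."""
    if ee_percent > 100.0:
        return f"EE of {ee_percent:.2f}% exceeds 100%; attributable to assay noise"
    return None
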