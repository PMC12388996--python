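"""Reported characterization values for the DOTAP:POPC acteoside
co-formulations that this package's analysis reproduces.

These are the study conditions: generator truth values for parameter-
recovery runs and baselines for the side-by-side comparison report. The
four liposomal systems are acteoside alone (ACT), acteoside co-encapsulated
with cannabidiol (ACT + CBD) or naringenin (ACT + NG), and the empty
DOTAP:POPC carrier.

``CHARACTERIZATION_TABLE`` carries one transcription slip in the source
records: the ACT + CBD day-0 size reads 1273 nm where every neighbouring
entry (and the day-0 size distribution) sits near 127–155 nm — a missing
decimal separator. It is kept verbatim here; the QC loader's outlier rule
flags it and suggests the ÷10 repair.
"""

from __future__ import annotations

from .qc import FormulationRecord

FORMULATIONS = ("DOTAP:POPC", "ACT", "ACT + CBD", "ACT + NG")

#: (formulation, day, size_nm, size_sd, pdi, pdi_sd, zeta_mv, zeta_sd)
_CHAR_ROWS = [
    ("DOTAP:POPC", 0, 128.9, 5.0, 0.21, 0.01, 34.3, 1.7),
    ("ACT", 0, 126.0, 7.7, 0.17, 0.07, 33.3, 3.6),
    ("ACT + CBD", 0, 1273.0, 6.0, 0.19, 0.05, 37.3, 0.6),  # flagged: 127.3 intended
    ("ACT + NG", 0, 129.3, 25.1, 0.17, 0.07, 33.9, 3.3),
    ("DOTAP:POPC", 7, 141.8, 40.3, 0.21, 0.04, 39.7, 0.4),
    ("ACT", 7, 133.4, 16.3, 0.21, 0.03, 37.3, 2.8),
    ("ACT + CBD", 7, 144.6, 9.6, 0.24, 0.02, 36.0, 2.5),
    ("ACT + NG", 7, 142.2, 28.7, 0.21, 0.07, 34.6, 3.9),
    ("DOTAP:POPC", 14, 154.3, 40.5, 0.25, 0.03, 38.6, 2.1),
    ("ACT", 14, 190.6, 54.5, 0.23, 0.03, 38.7, 1.3),
    ("ACT + CBD", 14, 153.4, 29.3, 0.25, 0.04, 37.3, 0.5),
    ("ACT + NG", 14, 182.1, 59.3, 0.23, 0.04, 37.2, 3.8),
    ("DOTAP:POPC", 21, 146.7, 39.1, 0.23, 0.06, 39.5, 4.1),
    ("ACT", 21, 136.9, 6.4, 0.21, 0.04, 39.9, 2.1),
    ("ACT + CBD", 21, 142.9, 18.5, 0.22, 0.03, 39.5, 3.2),
    ("ACT + NG", 21, 147.8, 6.6, 0.22, 0.08, 34.1, 2.6),
]


def characterization_records() -> list[FormulationRecord]:
    """Size/PDI/zeta table over the 21-day stability window, verbatim."""
    return [
        FormulationRecord(
            formulation=f, timepoint_days=d, size_nm=s, size_sd=ss,
            pdi=p, pdi_sd=ps, zeta_mv=z, zeta_sd=zs,
        )
        for f, d, s, ss, p, ps, z, zs in _CHAR_ROWS
    ]


#: Laboratory-frame relaxation parameters per system:
#: T1 (s), Gaussian amplitude fraction (%), T2G (ms), Lorentzian fraction (%), T2L (ms).
RELAXATION_PARAMS = {
    "ACT": {"t1_s": 2.5, "m0g_pct": 58.0, "t2g_ms": 184.0, "m0l_pct": 42.0, "t2l_ms": 300.0},
    "ACT + CBD": {"t1_s": 2.6, "m0g_pct": 77.0, "t2g_ms": 232.0, "m0l_pct": 23.0, "t2l_ms": 7.6},
    "ACT + NG": {"t1_s": 2.7, "m0g_pct": 86.0, "t2g_ms": 188.0, "m0l_pct": 14.0, "t2l_ms": 118.0},
    "DOTAP:POPC": {"t1_s": 2.6, "m0g_pct": 62.0, "t2g_ms": 186.0, "m0l_pct": 38.0, "t2l_ms": 352.0},
}

#: Off-resonance results per system: relaxation enhancement factor K with its
#: reported uncertainty, and the rotational correlation time in ns.
OFFRESONANCE_PARAMS = {
    "ACT": {"k": 1.22, "k_err": 0.17, "tau_c_ns": 1.8},
    "ACT + CBD": {"k": 1.46, "k_err": 0.27, "tau_c_ns": 2.8},
    "ACT + NG": {"k": 1.72, "k_err": 0.21, "tau_c_ns": 3.6},
    "DOTAP:POPC": {"k": 1.61, "k_err": 0.22, "tau_c_ns": 3.2},
}

#: IC50 values (µM) by formulation / cell line / exposure time. U-87 MG and
#: U-138 MG are glioma lines; MRC-5 is the normal lung-fibroblast control.
IC50_TABLE_UM = {
    ("DOTAP:POPC", "U-87 MG", 24): 18, ("DOTAP:POPC", "U-87 MG", 48): 16,
    ("DOTAP:POPC", "U-138 MG", 24): 17, ("DOTAP:POPC", "U-138 MG", 48): 15,
    ("DOTAP:POPC", "MRC-5", 24): 20, ("DOTAP:POPC", "MRC-5", 48): 19,
    ("ACT + CBD", "U-87 MG", 24): 11, ("ACT + CBD", "U-87 MG", 48): 7,
    ("ACT + CBD", "U-138 MG", 24): 10, ("ACT + CBD", "U-138 MG", 48): 6,
    ("ACT + CBD", "MRC-5", 24): 12, ("ACT + CBD", "MRC-5", 48): 9,
    ("ACT + NG", "U-87 MG", 24): 9, ("ACT + NG", "U-87 MG", 48): 6,
    ("ACT + NG", "U-138 MG", 24): 8, ("ACT + NG", "U-138 MG", 48): 5,
    ("ACT + NG", "MRC-5", 24): 10, ("ACT + NG", "MRC-5", 48): 8,
}

#: Encapsulation efficiencies (percent) with the loading concentrations
#: (µg/mL) used at preparation.
ENCAPSULATION = {
    ("ACT", "ACT"): {"ee_pct": 84.83, "ee_sd": 1.68, "c_in_ug_ml": 62.5},
    ("ACT + CBD", "ACT"): {"ee_pct": 85.23, "ee_sd": 0.81, "c_in_ug_ml": 31.2},
    ("ACT + CBD", "CBD"): {"ee_pct": 100.26, "ee_sd": 0.65, "c_in_ug_ml": 15.7},
    ("ACT + NG", "ACT"): {"ee_pct": 85.70, "ee_sd": 0.82, "c_in_ug_ml": 50.0},
    ("ACT + NG", "NG"): {"ee_pct": 99.19, "ee_sd": 0.33, "c_in_ug_ml": 5.4},
}
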