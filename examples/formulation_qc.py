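"""Stability screening and encapsulation efficiency for liposome batches.

Loads the built-in 21-day characterization table (size/PDI/zeta for four
DOTAP:POPC formulations), flags the one transcription outlier, screens the
repaired table against injectability criteria, and computes encapsulation
efficiencies from loading and recovered concentrations.
"""

from liporelax import (
    EncapsulationInput,
    apply_decimal_repair,
    check_stability,
    encapsulation_efficiency,
    flag_outliers,
    summarize_table,
)
from liporelax.qc import ee_flag, formulation_verdicts
from liporelax.reference import characterization_records

records = characterization_records()
for rec, suggestion in flag_outliers(records):
    print(
        f"outlier: {rec.formulation} day {rec.timepoint_days} size {rec.size_nm} nm"
        f" -> suggested decimal repair {suggestion} nm"
    )

repaired = apply_decimal_repair(records)
overall = summarize_table(repaired)["overall"]
print(f"\nPDI range  : {overall['pdi']['min']:.2f}-{overall['pdi']['max']:.2f} (<= 0.30 required)")
print(f"zeta range : {overall['zeta_mv']['min']:.1f} to {overall['zeta_mv']['max']:.1f} mV (|z| > 30 required)")
print(f"max size   : {overall['size_nm']['max']:.1f} nm (< 200 required)")

for name, ok in formulation_verdicts(check_stability(repaired)).items():
    print(f"stability over 21 days, {name}: {'pass' if ok else 'FAIL'}")

# encapsulation efficiency: recovered vs loaded acteoside
ee = encapsulation_efficiency(EncapsulationInput(53.019, 62.5, compound="ACT"))
print(f"\nacteoside EE = {ee:.2f}% (53.019 of 62.5 µg/mL recovered after disruption)")
ee_cbd = encapsulation_efficiency(EncapsulationInput(15.74, 15.7, compound="CBD"))
print(f"cannabidiol EE = {ee_cbd:.2f}%  [{ee_flag(ee_cbd)}]")
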