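"""Audit the shipped scoring rules and demonstrate lenient scoring.

The PI-RADS v2.1 rules ship as declarative JSON.  ``check_rule_table``
enumerates every applicable combination of the derived report features and
verifies that exactly one rule fires per target — the table is a partition,
so scoring is total and deterministic.  ``score_range`` shows the lenient
mode: the set of scores still compatible with a partially completed report.
"""

from pirads_cde import LesionReport, check_rule_table, default_rule_table
from pirads_cde.engine import score_range

table = default_rule_table()
report = check_rule_table(table)
for target, n in report.n_enumerated.items():
    print(f"{target:8s}: {n:5d} input combinations, "
          f"{len(report.gaps[target])} gaps, {len(report.conflicts[target])} conflicts")
print(f"partition OK: {report.ok}\n")

partial = LesionReport("L1", "reader1", 1, values={
    "adc_abnormality": "YES",
    "dwi_abnormality": "YES",
    "adc_signal_intensity": "Marked",
    "dwi_signal_intensity": "Marked",
    "adc_shape_category": "Round",
    "dwi_shape_category": "Round",
})
compatible = score_range(partial, zone="PZ", target="dwi")
print(f"DWI scores compatible with the partial report: {sorted(compatible)}")
# Marked restriction on both maps with round shape pins the DWI score to
# 3-5; focality, invasiveness and the size bin decide between them.
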