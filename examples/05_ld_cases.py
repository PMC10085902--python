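"""L/D ratios and diagnostic classes for the five validation cases.

The L/D ratio divides the diatom concentration per gram of lung tissue
by the concentration per millilitre of the putative drowning medium.
Active aspiration concentrates diatoms in the lung (L/D > 1, and > 2 is
strong evidence); passive post-mortem infiltration cannot exceed the
medium's own concentration (L/D <= 1).
"""

from diatomtest import (
    MediumMeasurement, TissueMeasurement, analyze_case, recommend_digestion,
)
from diatomtest.datasets import study_cases

print("case  per-g lung  per-ml medium   L/D  class")
for rec in study_cases().itertuples(index=False):
    record = analyze_case(
        rec.case_id,
        TissueMeasurement("lung", mass_g=1.0, diatom_count=rec.lung_per_gram),
        MediumMeasurement(volume_ml=1.0, diatom_count=rec.medium_per_ml),
        flags=tuple(f for f in rec.flags.split(";") if f == "debris"),
    )
    print(f"{record.case_id:<5} {record.lung_per_gram:>10.0f} "
          f"{record.medium_per_ml:>14.0f} {record.ld_reported:>5.1f}  "
          f"{record.diagnostic_class.value}")
    for flag in record.flags:
        print(f"      caveat: {flag}")

# Bench planning: reagent volumes for a 1.0 g lung sample
rec = recommend_digestion(1.0)
print(f"\ndigestion for 1.0 g lung tissue: {rec.total_volume_ml:.0f} ml "
      f"({rec.hno3_ml:.0f} ml HNO3 + {rec.h2o2_ml:.0f} ml H2O2)")
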