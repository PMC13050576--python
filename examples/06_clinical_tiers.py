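"""Deterministic clinical tier classification and a per-patient risk report.

Tier boundaries are inclusive and shared with the simulator's outcome
model, so a probability increment fires exactly when the tier is reached.
"""

import json

import pandas as pd

from gdmrisk import classify_lab, risk_report

for analyte, value in [
    ("rbs", 118.0), ("rbs", 131.0), ("rbs", 145.0),
    ("hba1c", 5.5), ("hba1c", 5.8), ("hba1c", 6.2), ("hba1c", 6.6),
    ("ogtt_fasting", 95.0),
]:
    tier = classify_lab(analyte, value)
    print(f"{analyte:13s} {value:6.1f} -> {tier.tier}"
          + (f" (boundary {tier.boundary})" if tier.boundary else ""))

patient = pd.Series(
    {
        "age": 36.0, "bmi": 31.5, "booking_ga": 9.5, "ethnicity": "Asian",
        "family_hx": 1, "prev_gdm": 0, "pcos": 1, "prev_macrosomia": 0,
        "rbs": 138.0, "ppbs": 171.0, "hba1c": 6.1,
    }
)
report = risk_report(patient, model_probability=0.83)
print()
print(json.dumps(report, indent=2))
print()
print(f"-> flagged analytes: {report['flagged_tiers']}; the model probability")
print("   (0.83) and the tier ladder together support escalation to a")
print("   diagnostic OGTT for this patient.")
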