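"""Shared clinical constants: laboratory ranges, tier boundaries and
outcome-probability increments.

These tables are the single source of truth for both the cohort simulator
(which adds probability increments when a lab crosses a boundary) and the
clinical tier classifier, so the two can never disagree on where a
boundary sits.  All boundaries are inclusive (``>=``).

Units: glucose analytes (RBS, PPBS, OGTT) in mg/dL; HbA1c in percent.
"""

from __future__ import annotations

ANALYTES = ("rbs", "ppbs", "hba1c", "ogtt_fasting", "ogtt_1h", "ogtt_2h")

#: Valid (clipping) range per analyte.
LAB_RANGES: dict[str, tuple[float, float]] = {
    "rbs": (70.0, 200.0),
    "ppbs": (90.0, 250.0),
    "hba1c": (4.0, 8.0),
    "ogtt_fasting": (70.0, 140.0),
    "ogtt_1h": (100.0, 250.0),
    "ogtt_2h": (90.0, 220.0),
}

#: Ordered tier boundaries per analyte: (boundary, tier name), ascending.
#: A value is assigned the highest tier whose boundary it meets; below the
#: lowest boundary the tier is "normal".
TIER_BOUNDARIES: dict[str, tuple[tuple[float, str], ...]] = {
    "rbs": ((125.0, "borderline"), (140.0, "concerning")),
    "ppbs": ((160.0, "borderline"), (180.0, "concerning")),
    "hba1c": ((5.7, "intermediate"), (6.0, "high"), (6.5, "diagnostic")),
    "ogtt_fasting": ((92.0, "diagnostic"),),
    "ogtt_1h": ((180.0, "diagnostic"),),
    "ogtt_2h": ((153.0, "diagnostic"),),
}

#: Absolute probability added to the GDM outcome probability per crossed
#: boundary.  Within one analyte only the highest crossed tier applies;
#: across analytes increments sum.
OUTCOME_INCREMENTS: dict[str, tuple[tuple[float, float], ...]] = {
    "rbs": ((125.0, 0.20), (140.0, 0.40)),
    "ppbs": ((160.0, 0.15), (180.0, 0.30)),
    "hba1c": ((5.7, 0.10), (6.0, 0.25), (6.5, 0.50)),
}

#: IADPSG-style early-OGTT criteria; meeting ANY one adds a single increment.
OGTT_CRITERIA: dict[str, float] = {
    "ogtt_fasting": 92.0,
    "ogtt_1h": 180.0,
    "ogtt_2h": 153.0,
}

#: Probability added when any OGTT criterion is met.
OGTT_INCREMENT: float = 0.40

ETHNICITIES = ("Caucasian", "Asian", "Hispanic", "African", "Other")
HIGH_RISK_ETHNICITIES = frozenset({"Asian", "Hispanic"})

RISK_FLAGS = ("family_hx", "prev_gdm", "pcos", "prev_macrosomia")
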