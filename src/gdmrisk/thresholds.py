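"""Clinical tier classification of first-trimester laboratory values.

Boundaries live in :mod:`gdmrisk.constants` and are shared with the
cohort simulator's outcome model, so an outcome-probability increment
fires exactly when the corresponding tier is reached.  All boundaries
are inclusive (``>=``); a value is assigned the highest tier it meets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Any

import pandas as pd

from .constants import ANALYTES, LAB_RANGES, RISK_FLAGS, TIER_BOUNDARIES

#: total tier order, lowest to highest severity
TIER_ORDER = ("normal", "borderline", "intermediate", "high", "concerning", "diagnostic")


@dataclass(frozen=True)
class LabTier:
    analyte: str
    value: float
    tier: str
    boundary: float | None  # highest boundary crossed, None when normal

    @property
    def severity(self) -> int:
        return TIER_ORDER.index(self.tier)


def classify_lab(analyte: str, value: float) -> LabTier:
    """Tier of one laboratory value; highest boundary met wins.

    The value must lie within the analyte's valid range; missing (NaN)
    values are not classifiable and raise.
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"cannot classify missing {analyte} value")
    lo, hi = LAB_RANGES[analyte]
    if not lo <= value <= hi:
        raise ValueError(f"{analyte} value {value} outside valid range [{lo}, {hi}]")
    tier, boundary = "normal", None
    for bound, name in TIER_BOUNDARIES[analyte]:  # ascending
        if value >= bound:
            tier, boundary = name, bound
    return LabTier(analyte=analyte, value=float(value), tier=tier, boundary=boundary)


def classify_record(record: pd.Series | dict) -> dict[str, LabTier]:
    """Tier every present, non-missing analyte of one patient record."""
    record = pd.Series(record)
    out = {}
    for analyte in ANALYTES:
        if analyte in record and not pd.isna(record[analyte]):
            out[analyte] = classify_lab(analyte, float(record[analyte]))
    return out


def risk_report(
    record: pd.Series | dict,
    model_probability: float,
    attributions: pd.Series | dict | None = None,
    top_attributions: int = 5,
) -> dict[str, Any]:
    """Structured per-patient risk report.

    Combines demographics, risk-factor flags, per-analyte tier
    classifications, the model's predicted GDM probability and (optionally)
    the top additive attributions.  Deterministic and JSON-serializable.
    """
    if not 0.0 <= model_probability <= 1.0:
        raise ValueError(f"model probability must be in [0,1], got {model_probability}")
    record = pd.Series(record)
    tiers = classify_record(record)
    report: dict[str, Any] = {
        "demographics": {
            k: (float(record[k]) if k != "ethnicity" else str(record[k]))
            for k in ("age", "bmi", "booking_ga", "ethnicity")
            if k in record
        },
        "risk_factors": {f: int(record[f]) for f in RISK_FLAGS if f in record},
        "lab_tiers": {
            a: {"value": t.value, "tier": t.tier, "boundary": t.boundary}
            for a, t in tiers.items()
        },
        "flagged_tiers": sorted(
            a for a, t in tiers.items() if t.tier != "normal"
        ),
        "model_probability": float(model_probability),
    }
    if attributions is not None:
        attr = pd.Series(attributions).astype(float)
        top = attr.reindex(attr.abs().sort_values(ascending=False, kind="stable").index)
        report["top_attributions"] = [
            {"feature": str(k), "contribution": float(v)}
            for k, v in top.head(top_attributions).items()
        ]
    return report


def report_to_json(report: dict[str, Any]) -> str:
    return json.dumps(report, sort_keys=True)
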