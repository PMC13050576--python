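"""Synthetic high-risk antenatal cohort generator.

The generative model is staged hierarchically:

1. demographics — age from a clipped Normal, BMI from an age-stratified
   clipped Normal, ethnicity categorical, booking gestational age clipped
   to a first-trimester window;
2. a composite clinical risk score from demographics and risk-factor flags;
3. binary risk factors drawn with individual probabilities tilted
   (logistically) by the demographic score, with the intercept re-solved
   so each configured marginal prevalence is preserved;
4. laboratory values coupled to the composite score, the OGTT triple
   drawn only for the highest-risk ~29.5% (plus selection noise);
5. a GDM outcome drawn from a probability built additively from a 10%
   base, a per-score-unit term, and fixed increments per crossed
   laboratory threshold.

One root seed fans out to independent named substreams per stage, so
changing one stage's draw count never perturbs the others.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import GeneratorConfig
from .constants import ETHNICITIES, HIGH_RISK_ETHNICITIES, OGTT_CRITERIA, RISK_FLAGS

OGTT_COLUMNS = ("ogtt_fasting", "ogtt_1h", "ogtt_2h")

#: fixed substream index per generation stage (stable across versions so
#: that adding a stage never re-seeds an existing one)
_STAGES = {
    "demographics": 0,
    "risk_factors": 1,
    "labs": 2,
    "ogtt_selection": 3,
    "outcome": 4,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, named random substream for one generation stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],)))


def _clipped_normal(
    rng: np.random.Generator, mean, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Normal draws clipped (not resampled) to [lo, hi].

    Clipping leaves a small point mass at the bounds but keeps the mean
    essentially at ``mean`` when the bounds sit >= 2 SD away, which is the
    regime every configured range is in.
    """
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


# ---------------------------------------------------------------------------
# stage 1: demographics


def sample_demographics(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw age, BMI, booking gestational age and ethnicity for a cohort."""
    n = cfg.n_patients
    age = _clipped_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, size=n)
    bmi_mean = np.where(age < 30.0, cfg.bmi_mean_young, cfg.bmi_mean_old)
    bmi = _clipped_normal(rng, bmi_mean, cfg.bmi_sd, *cfg.bmi_range, size=n)
    booking_ga = _clipped_normal(
        rng, cfg.booking_ga_mean, cfg.booking_ga_sd, *cfg.booking_ga_range, size=n
    )
    probs = [cfg.ethnicity_probs[e] for e in ETHNICITIES]
    ethnicity = rng.choice(ETHNICITIES, size=n, p=probs)
    return pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "booking_ga": booking_ga,
            "ethnicity": pd.Categorical(ethnicity, categories=ETHNICITIES),
        }
    )


# ---------------------------------------------------------------------------
# composite risk score


def demographic_score(records: pd.DataFrame, cfg: GeneratorConfig) -> pd.Series:
    """Demographic portion of the composite score (age, BMI, ethnicity)."""
    for col in ("age", "bmi", "ethnicity"):
        if col not in records.columns:
            raise KeyError(f"missing demographic field: {col!r}")
    high_risk = records["ethnicity"].astype(object).isin(HIGH_RISK_ETHNICITIES)
    score = (
        (records["age"] - cfg.age_ref) * cfg.age_coeff
        + (records["bmi"] - cfg.bmi_ref) * cfg.bmi_coeff
        + cfg.high_risk_ethnicity_weight * high_risk.to_numpy(dtype=float)
    )
    return pd.Series(np.asarray(score, dtype=float), index=records.index, name="risk_score")


def compute_risk_score(records: pd.DataFrame, cfg: GeneratorConfig) -> pd.Series:
    """Composite clinical risk score.

    score = (age - 25) * 0.1 + (BMI - 23) * 0.15
            + 1.5*family_hx + 2.0*prev_gdm + 1.0*pcos + 1.2*prev_macrosomia
            + 0.8*[ethnicity in {Asian, Hispanic}]

    (with all weights configurable).  Deterministic; may be negative for
    young, lean patients.
    """
    score = demographic_score(records, cfg)
    for flag in RISK_FLAGS:
        if flag not in records.columns:
            raise KeyError(f"missing demographic field: {flag!r}")
        score = score + cfg.flag_weights[flag] * records[flag].to_numpy(dtype=float)
    return score.rename("risk_score")


# ---------------------------------------------------------------------------
# stage 2: risk-factor flags


def assign_risk_factors(
    demographics: pd.DataFrame, cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the four binary risk factors, tilted by the demographic score.

    Each flag is Bernoulli with individual probability
    ``expit(a + flag_tilt * (s_i - mean(s)))`` where ``s`` is the
    demographic score; the intercept ``a`` is solved per cohort so the
    marginal prevalence equals the configured value.  ``flag_tilt = 0``
    makes flags independent of the score with probability exactly the
    configured prevalence.
    """
    n = len(demographics)
    out = pd.DataFrame(index=demographics.index)
    if n == 0:
        for flag in RISK_FLAGS:
            out[flag] = np.zeros(0, dtype=np.int64)
        return out
    s = demographic_score(demographics, cfg).to_numpy()
    centred = cfg.flag_tilt * (s - s.mean())
    for flag in RISK_FLAGS:
        prev = cfg.prevalences[flag]
        if prev in (0.0, 1.0) or cfg.flag_tilt == 0.0:
            p = np.full(n, prev)
        else:
            a = brentq(lambda a: expit(a + centred).mean() - prev, -40.0, 40.0, xtol=1e-12)
            p = expit(a + centred)
        out[flag] = (rng.random(n) < p).astype(np.int64)
    return out


def flag_probabilities(
    demographics: pd.DataFrame, cfg: GeneratorConfig, flag: str
) -> np.ndarray:
    """Individual Bernoulli probabilities used by :func:`assign_risk_factors`."""
    s = demographic_score(demographics, cfg).to_numpy()
    centred = cfg.flag_tilt * (s - s.mean())
    prev = cfg.prevalences[flag]
    if prev in (0.0, 1.0) or cfg.flag_tilt == 0.0:
        return np.full(len(demographics), prev)
    a = brentq(lambda a: expit(a + centred).mean() - prev, -40.0, 40.0, xtol=1e-12)
    return expit(a + centred)


# ---------------------------------------------------------------------------
# stage 3: laboratory values with selective OGTT


def sample_lab_values(
    records: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    selection_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw risk-coupled laboratory values; OGTT only for the tested subset.

    Each analyte is ``Normal(base_mean + shift * risk_score, base_sd)``
    clipped to its valid range.  The OGTT triple is drawn for the top
    ``ogtt_tested_fraction`` of patients ranked by risk score plus Gumbel
    selection noise, and left missing (NaN) otherwise.
    """
    if "risk_score" not in records.columns:
        raise KeyError("records must carry a 'risk_score' column")
    if selection_rng is None:
        selection_rng = rng
    n = len(records)
    score = records["risk_score"].to_numpy(dtype=float)
    out = pd.DataFrame(index=records.index)

    for name in ("rbs", "ppbs", "hba1c"):
        lab = cfg.labs[name]
        out[name] = _clipped_normal(
            rng, lab.base_mean + lab.shift * score, lab.base_sd, *lab.range_, size=n
        )

    # selective testing: highest risk tested first, softened by Gumbel noise
    n_tested = int(round(n * cfg.ogtt_tested_fraction))
    sel = score + selection_rng.gumbel(0.0, cfg.ogtt_selection_noise, size=n)
    tested = np.zeros(n, dtype=bool)
    if n_tested > 0:
        tested[np.argsort(sel)[::-1][:n_tested]] = True
    out["ogtt_tested"] = tested

    for name in OGTT_COLUMNS:
        lab = cfg.labs[name]
        values = _clipped_normal(
            rng, lab.base_mean + lab.shift * score, lab.base_sd, *lab.range_, size=n
        )
        out[name] = np.where(tested, values, np.nan)
    return out


# ---------------------------------------------------------------------------
# stage 4: outcome model


def _validate_lab_ranges(records: pd.DataFrame, cfg: GeneratorConfig) -> None:
    for name, lab in cfg.labs.items():
        if name not in records.columns:
            raise KeyError(f"missing lab column: {name!r}")
        values = records[name].to_numpy(dtype=float)
        finite = values[~np.isnan(values)]
        lo, hi = lab.range_
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(f"lab {name!r} outside declared range {lab.range_}")


def _threshold_increment(values: np.ndarray, tiers) -> np.ndarray:
    """Highest applicable increment per value (tiers are non-cumulative)."""
    inc = np.zeros_like(values, dtype=float)
    for boundary, bump in tiers:  # ascending boundaries: later tiers overwrite
        inc = np.where(values >= boundary, bump, inc)
    return inc


def compute_outcome_probability(records: pd.DataFrame, cfg: GeneratorConfig) -> pd.Series:
    """GDM outcome probability for each record.

    p = clip(base + coeff * score + RBS tier + PPBS tier + HbA1c tier
             + 0.40 * [any OGTT criterion met], 0, prob_cap)

    Within one analyte only the single highest crossed tier applies; a
    missing OGTT contributes nothing.  Deterministic given the record.
    """
    if "risk_score" not in records.columns:
        raise KeyError("records must carry a 'risk_score' column")
    _validate_lab_ranges(records, cfg)
    p = cfg.base_outcome_prob + cfg.score_to_prob_coeff * records["risk_score"].to_numpy(
        dtype=float
    )
    for analyte, tiers in cfg.outcome_increments.items():
        p = p + _threshold_increment(records[analyte].to_numpy(dtype=float), tiers)
    any_ogtt = np.zeros(len(records), dtype=bool)
    for analyte, criterion in OGTT_CRITERIA.items():
        values = records[analyte].to_numpy(dtype=float)
        any_ogtt |= np.nan_to_num(values, nan=-np.inf) >= criterion
    p = p + cfg.ogtt_increment * any_ogtt
    return pd.Series(np.clip(p, 0.0, cfg.prob_cap), index=records.index, name="outcome_prob")


# ---------------------------------------------------------------------------
# orchestration


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Run all generation stages and return the full cohort table.

    Columns: demographics, risk-factor flags, labs (OGTT NaN when not
    tested), ``ogtt_tested``, ``risk_score``, ``outcome_prob`` and the
    binary ``gdm`` label.  Identical config (including seed) yields a
    byte-identical table.
    """
    cfg.validate()
    demo = sample_demographics(cfg, stage_rng(cfg.seed, "demographics"))
    flags = assign_risk_factors(demo, cfg, stage_rng(cfg.seed, "risk_factors"))
    cohort = pd.concat([demo, flags], axis=1)
    cohort["risk_score"] = compute_risk_score(cohort, cfg)
    labs = sample_lab_values(
        cohort,
        cfg,
        stage_rng(cfg.seed, "labs"),
        selection_rng=stage_rng(cfg.seed, "ogtt_selection"),
    )
    cohort = pd.concat([cohort, labs], axis=1)
    cohort["outcome_prob"] = compute_outcome_probability(cohort, cfg)
    outcome_rng = stage_rng(cfg.seed, "outcome")
    cohort["gdm"] = (outcome_rng.random(len(cohort)) < cohort["outcome_prob"]).astype(np.int64)
    return cohort


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Marginal summary statistics of a generated cohort."""
    tested = cohort["ogtt_tested"].astype(bool)
    summary = {
        "n": int(len(cohort)),
        "gdm_positive_fraction": float(cohort["gdm"].mean()) if len(cohort) else float("nan"),
        "age_mean": float(cohort["age"].mean()),
        "age_sd": float(cohort["age"].std()),
        "bmi_mean": float(cohort["bmi"].mean()),
        "bmi_sd": float(cohort["bmi"].std()),
        "ogtt_tested_fraction": float(tested.mean()) if len(cohort) else float("nan"),
        "ethnicity_fractions": {
            e: float((cohort["ethnicity"] == e).mean()) for e in ETHNICITIES
        },
        "prevalences": {f: float(cohort[f].mean()) for f in RISK_FLAGS},
        "lab_means": {
            name: float(cohort.loc[tested, name].mean() if name in OGTT_COLUMNS
                        else cohort[name].mean())
            for name in ("rbs", "ppbs", "hba1c", *OGTT_COLUMNS)
        },
        "lab_sds": {
            name: float(cohort.loc[tested, name].std() if name in OGTT_COLUMNS
                        else cohort[name].std())
            for name in ("rbs", "ppbs", "hba1c", *OGTT_COLUMNS)
        },
    }
    return summary


def write_cohort(cohort: pd.DataFrame, path: str | Path, cfg: GeneratorConfig | None = None) -> None:
    """Write the cohort CSV (missing OGTT as empty fields) plus a JSON sidecar."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    sidecar = {"summary": cohort_summary(cohort)}
    if cfg is not None:
        sidecar["config"] = cfg.to_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    df["ethnicity"] = pd.Categorical(df["ethnicity"], categories=ETHNICITIES)
    return df
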