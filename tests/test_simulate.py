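"""Cohort simulator: score arithmetic, outcome model, marginal recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmrisk import (
    GeneratorConfig,
    assign_risk_factors,
    compute_outcome_probability,
    compute_risk_score,
    generate_cohort,
    sample_demographics,
    sample_lab_values,
)
from gdmrisk.constants import ETHNICITIES, LAB_RANGES, RISK_FLAGS
from gdmrisk.simulate import (
    OGTT_COLUMNS,
    cohort_summary,
    demographic_score,
    flag_probabilities,
    stage_rng,
)

from conftest import make_record

CFG = GeneratorConfig(n_patients=10, seed=0)


class TestRiskScore:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # all reference offsets zero
            (dict(age=25, bmi=23, ethnicity="Caucasian"), 0.0),
            # 1.0 (age) + 1.05 (bmi) + 1.5 (family hx)
            (dict(age=35, bmi=30, family_hx=1, ethnicity="Caucasian"), 3.55),
            # 0.5 + 0.6 + 2.0 + 1.0 + 0.8 (high-risk ethnicity)
            (dict(age=30, bmi=27, prev_gdm=1, pcos=1, ethnicity="Asian"), 4.9),
            # negative contributions below the reference points
            (dict(age=20, bmi=20, ethnicity="African"), -0.95),
        ],
    )
    def test_hand_computed_scores(self, kwargs, expected):
        record = make_record(**kwargs)
        assert compute_risk_score(record, CFG).iloc[0] == pytest.approx(expected)

    def test_missing_field_named_in_error(self):
        record = make_record().drop(columns=["bmi"])
        with pytest.raises(KeyError, match="bmi"):
            compute_risk_score(record, CFG)
        record = make_record().drop(columns=["pcos"])
        with pytest.raises(KeyError, match="pcos"):
            compute_risk_score(record, CFG)

    def test_deterministic(self):
        record = make_record(age=33, bmi=28, pcos=1, ethnicity="Hispanic")
        a = compute_risk_score(record, CFG)
        b = compute_risk_score(record, CFG)
        pd.testing.assert_series_equal(a, b)


class TestOutcomeProbability:
    def _prob(self, record, cfg=None, score=0.0):
        record = record.assign(risk_score=score)
        return compute_outcome_probability(record, cfg or CFG).iloc[0]

    def test_base_rate_when_everything_subthreshold(self):
        assert self._prob(make_record()) == pytest.approx(0.10)

    def test_diagnostic_hba1c_adds_half(self):
        # only the single highest HbA1c tier fires: 0.10 + 0.50
        assert self._prob(make_record(hba1c=6.6)) == pytest.approx(0.60)

    def test_score_term_plus_rbs_tier(self):
        cfg = GeneratorConfig(n_patients=1, seed=0, score_to_prob_coeff=0.05)
        # 0.10 + 0.05*4.9 + 0.40 (RBS >= 140 tier only)
        assert self._prob(make_record(rbs=145.0), cfg, score=4.9) == pytest.approx(0.745)

    def test_tiers_within_analyte_not_cumulative(self):
        p_low = self._prob(make_record(rbs=130.0))  # borderline +0.20
        p_high = self._prob(make_record(rbs=150.0))  # concerning +0.40 only
        assert p_low == pytest.approx(0.30)
        assert p_high == pytest.approx(0.50)

    def test_ogtt_single_increment_for_any_criterion(self):
        one = self._prob(make_record(ogtt_fasting=95.0, ogtt_1h=150.0, ogtt_2h=100.0))
        all_three = self._prob(make_record(ogtt_fasting=95.0, ogtt_1h=185.0, ogtt_2h=160.0))
        assert one == pytest.approx(0.50)
        assert all_three == pytest.approx(0.50)  # still one +0.40

    def test_missing_ogtt_contributes_zero(self):
        assert self._prob(make_record()) == self._prob(
            make_record(ogtt_fasting=np.nan, ogtt_1h=np.nan, ogtt_2h=np.nan)
        )

    def test_out_of_range_lab_rejected(self):
        with pytest.raises(ValueError, match="rbs"):
            self._prob(make_record(rbs=500.0))

    def test_cap_binds(self):
        record = make_record(rbs=150, ppbs=200, hba1c=7.5, ogtt_fasting=100,
                             ogtt_1h=200, ogtt_2h=180)
        assert self._prob(record, score=10.0) == pytest.approx(CFG.prob_cap)

    @given(
        rbs=st.floats(70, 200),
        ppbs=st.floats(90, 250),
        hba1c=st.floats(4.0, 8.0),
        flag=st.sampled_from(RISK_FLAGS),
        bump=st.sampled_from(["rbs", "ppbs", "hba1c"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_flags_and_labs(self, rbs, ppbs, hba1c, flag, bump):
        """Setting a risk flag or raising a lab never decreases probability."""
        base = make_record(rbs=rbs, ppbs=ppbs, hba1c=hba1c)
        with_flag = base.copy()
        with_flag[flag] = 1
        p0 = self._prob(base, score=compute_risk_score(base, CFG).iloc[0])
        p1 = self._prob(with_flag, score=compute_risk_score(with_flag, CFG).iloc[0])
        assert p1 >= p0 - 1e-12
        hi, _ = LAB_RANGES[bump], None
        bumped = base.copy()
        bumped[bump] = min(base[bump].iloc[0] * 1.2, LAB_RANGES[bump][1])
        p2 = self._prob(bumped, score=compute_risk_score(bumped, CFG).iloc[0])
        assert p2 >= p0 - 1e-12

    def test_probability_bounds_on_extreme_grid(self):
        """Brute force over a grid of extreme inputs: p always in [0, cap]."""
        cfg = GeneratorConfig(n_patients=1, seed=0)
        grid = []
        for age in (18, 45):
            for bmi in (16, 45):
                for flags in ((0, 0, 0, 0), (1, 1, 1, 1)):
                    for rbs in (70, 124.9, 125, 140, 200):
                        for hba1c in (4.0, 5.7, 6.0, 6.5, 8.0):
                            for ogtt in (np.nan, 92.0, 140.0):
                                grid.append(
                                    make_record(
                                        age=age, bmi=bmi,
                                        family_hx=flags[0], prev_gdm=flags[1],
                                        pcos=flags[2], prev_macrosomia=flags[3],
                                        ethnicity="Asian", rbs=rbs, hba1c=hba1c,
                                        ogtt_fasting=ogtt,
                                        ogtt_1h=200.0 if not np.isnan(ogtt) else np.nan,
                                        ogtt_2h=160.0 if not np.isnan(ogtt) else np.nan,
                                    )
                                )
        records = pd.concat(grid, ignore_index=True)
        records["risk_score"] = compute_risk_score(records, cfg)
        p = compute_outcome_probability(records, cfg)
        assert (p >= 0).all() and (p <= cfg.prob_cap).all()


class TestDemographics:
    def test_marginals_at_10k(self, cohort_10k):
        n = len(cohort_10k)
        age = cohort_10k["age"]
        assert abs(age.mean() - 28.0) < 3 * age.std() / np.sqrt(n) + 0.05
        assert age.std() == pytest.approx(4.9, abs=0.15)  # clipping shrinks the SD
        frac = (cohort_10k["ethnicity"] == "Caucasian").mean()
        assert abs(frac - 0.40) < 3 * np.sqrt(0.4 * 0.6 / n)
        assert cohort_10k["age"].between(18, 45).all()
        assert cohort_10k["bmi"].between(16, 45).all()

    def test_bmi_age_stratification(self, cohort_10k):
        young = cohort_10k.loc[cohort_10k["age"] < 30, "bmi"]
        old = cohort_10k.loc[cohort_10k["age"] >= 30, "bmi"]
        assert old.mean() - young.mean() == pytest.approx(2.0, abs=0.3)

    def test_seeded_reproducibility(self):
        cfg = GeneratorConfig(n_patients=200, seed=5)
        a = sample_demographics(cfg, stage_rng(5, "demographics"))
        b = sample_demographics(cfg, stage_rng(5, "demographics"))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort_ok(self):
        cfg = GeneratorConfig(n_patients=0, seed=1)
        out = sample_demographics(cfg, stage_rng(1, "demographics"))
        assert len(out) == 0

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(
                n_patients=10,
                ethnicity_probs={e: 0.5 for e in ETHNICITIES},
            )


class TestRiskFactors:
    def test_prevalences_at_10k(self, cohort_10k, default_cfg):
        n = len(cohort_10k)
        for flag, prev in default_cfg.prevalences.items():
            se = np.sqrt(prev * (1 - prev) / n)
            assert abs(cohort_10k[flag].mean() - prev) < 3 * se, flag

    def test_zero_tilt_gives_exact_marginal_probability(self):
        cfg = GeneratorConfig(n_patients=500, seed=3, flag_tilt=0.0)
        demo = sample_demographics(cfg, stage_rng(3, "demographics"))
        p = flag_probabilities(demo, cfg, "family_hx")
        assert np.allclose(p, cfg.prevalences["family_hx"])

    def test_tilt_monotone_in_score(self):
        cfg = GeneratorConfig(n_patients=400, seed=9)
        demo = sample_demographics(cfg, stage_rng(9, "demographics"))
        score = demographic_score(demo, cfg).to_numpy()
        p = flag_probabilities(demo, cfg, "pcos")
        order = np.argsort(score)
        assert (np.diff(p[order]) >= -1e-12).all()

    def test_tilt_preserves_mean_probability(self):
        cfg = GeneratorConfig(n_patients=1000, seed=4)
        demo = sample_demographics(cfg, stage_rng(4, "demographics"))
        for flag, prev in cfg.prevalences.items():
            assert flag_probabilities(demo, cfg, flag).mean() == pytest.approx(prev, abs=1e-9)


class TestLabs:
    def test_hba1c_marginal(self, cohort_10k):
        n = len(cohort_10k)
        hba1c = cohort_10k["hba1c"]
        assert abs(hba1c.mean() - 5.72) < 3 * hba1c.std() / np.sqrt(n) + 0.005
        assert hba1c.std() == pytest.approx(0.58, abs=0.03)

    def test_ogtt_tested_fraction(self, cohort_10k, default_cfg):
        assert cohort_10k["ogtt_tested"].mean() == pytest.approx(
            default_cfg.ogtt_tested_fraction, abs=3 * np.sqrt(0.295 * 0.705 / len(cohort_10k))
        )

    def test_ogtt_all_or_none(self, cohort_10k):
        missing = cohort_10k[list(OGTT_COLUMNS)].isna()
        assert (missing.all(axis=1) | (~missing.any(axis=1))).all()
        assert (~missing.any(axis=1) == cohort_10k["ogtt_tested"]).all()

    def test_zero_shift_decouples_labs_from_score(self):
        cfg = GeneratorConfig(n_patients=4000, seed=6)
        for lab in cfg.labs.values():
            lab.shift = 0.0
        cohort = generate_cohort(cfg)
        r = np.corrcoef(cohort["risk_score"], cohort["hba1c"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(cohort))

    def test_risk_coupling_positive(self, cohort_10k):
        r = np.corrcoef(cohort_10k["risk_score"], cohort_10k["hba1c"])[0, 1]
        assert r > 3 / np.sqrt(len(cohort_10k))

    def test_all_labs_within_ranges(self, cohort_10k):
        for name, (lo, hi) in LAB_RANGES.items():
            values = cohort_10k[name].dropna()
            assert values.between(lo, hi).all(), name

    def test_negative_sd_rejected(self):
        cfg = GeneratorConfig(n_patients=10, seed=0)
        cfg.labs["rbs"].base_sd = -1.0
        with pytest.raises(ValueError, match="rbs"):
            cfg.validate()


class TestGenerateCohort:
    def test_positive_fraction_near_65_percent(self, cohort_10k):
        n = len(cohort_10k)
        assert abs(cohort_10k["gdm"].mean() - 0.65) < 3 * np.sqrt(0.65 * 0.35 / n) + 0.005

    def test_base_rate_only_limit(self):
        cfg = GeneratorConfig(
            n_patients=10_000,
            seed=13,
            score_to_prob_coeff=0.0,
            outcome_increments={k: tuple((b, 0.0) for b, _ in v)
                                for k, v in GeneratorConfig().outcome_increments.items()},
            ogtt_increment=0.0,
        )
        cohort = generate_cohort(cfg)
        assert (cohort["outcome_prob"] == 0.10).all()
        assert abs(cohort["gdm"].mean() - 0.10) < 3 * np.sqrt(0.1 * 0.9 / len(cohort))

    def test_byte_identical_csv_on_same_seed(self, tmp_path):
        cfg = GeneratorConfig(n_patients=300, seed=21)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_cohort(cfg).to_csv(a, index=False)
        generate_cohort(GeneratorConfig(n_patients=300, seed=21)).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_adding_stage_draws_does_not_perturb_demographics(self):
        """Named substreams: demographics identical whatever other stages consume."""
        cfg = GeneratorConfig(n_patients=100, seed=17)
        cohort = generate_cohort(cfg)
        demo = sample_demographics(cfg, stage_rng(17, "demographics"))
        pd.testing.assert_series_equal(cohort["age"], demo["age"])

    def test_summary_keys(self, cohort_small):
        s = cohort_summary(cohort_small)
        assert s["n"] == 800
        assert set(s["prevalences"]) == set(RISK_FLAGS)
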