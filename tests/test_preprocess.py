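"""Preprocessing chain: encoding, imputation, split, scaling, SMOTE."""

import numpy as np
import pandas as pd
import pytest

from gdmrisk import (
    FeatureMatrix,
    encode_ethnicity,
    impute_ogtt_zero,
    smote_balance,
    standardize,
    stratified_split,
)
from gdmrisk.preprocess import ETHNICITY_DUMMIES, cohort_to_matrix

from conftest import make_record


def _matrix(values: np.ndarray, labels, columns=None) -> FeatureMatrix:
    columns = columns or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(
        pd.DataFrame(values, columns=columns), pd.Series(labels, dtype=np.int64)
    )


class TestEncodeEthnicity:
    @pytest.mark.parametrize(
        "category, expected",
        [
            ("African", (0, 0, 0, 0)),  # reference category
            ("Asian", (1, 0, 0, 0)),
            ("Caucasian", (0, 1, 0, 0)),
            ("Hispanic", (0, 0, 1, 0)),
            ("Other", (0, 0, 0, 1)),
        ],
    )
    def test_indicator_patterns(self, category, expected):
        out = encode_ethnicity(make_record(ethnicity=category))
        assert tuple(out[list(ETHNICITY_DUMMIES)].iloc[0]) == expected
        assert "ethnicity" not in out.columns

    def test_unknown_category_listed_in_error(self):
        with pytest.raises(ValueError, match="Martian"):
            encode_ethnicity(make_record(ethnicity="Martian"))


class TestImputeOgtt:
    def test_missing_triple_becomes_zeros(self):
        out, n = impute_ogtt_zero(make_record())
        assert n == 3
        assert tuple(out[["ogtt_fasting", "ogtt_1h", "ogtt_2h"]].iloc[0]) == (0, 0, 0)

    def test_present_values_unchanged(self):
        record = make_record(ogtt_fasting=95.0, ogtt_1h=185.0, ogtt_2h=150.0)
        out, n = impute_ogtt_zero(record)
        assert n == 0
        pd.testing.assert_frame_equal(out, record)

    def test_three_state_encoding_zero_exactly_where_missing(self, cohort_small):
        frame = cohort_small.drop(columns=["ethnicity"])
        was_missing = frame["ogtt_fasting"].isna()
        out, _ = impute_ogtt_zero(frame)
        assert ((out["ogtt_fasting"] == 0.0) == was_missing).all()

    def test_missing_outside_ogtt_rejected(self):
        record = make_record()
        record.loc[0, "bmi"] = np.nan
        with pytest.raises(ValueError, match="bmi"):
            impute_ogtt_zero(record)


class TestStratifiedSplit:
    def test_exact_proportionality(self):
        m = _matrix(np.arange(200).reshape(100, 2), [0] * 50 + [1] * 50)
        split = stratified_split(m, train_fraction=0.8, seed=1)
        assert len(split.train.values) == 80 and len(split.test.values) == 20
        assert split.train.labels.value_counts().to_dict() == {0: 40, 1: 40}
        assert split.test.labels.value_counts().to_dict() == {0: 10, 1: 10}

    def test_10k_cohort_splits_8000_2000(self, cohort_10k):
        split = stratified_split(cohort_to_matrix(cohort_10k), 0.8, seed=42)
        assert len(split.train.values) == 8000
        assert len(split.test.values) == 2000
        # class proportions preserved within one record per class
        full = cohort_10k["gdm"].mean()
        assert split.train.labels.mean() == pytest.approx(full, abs=1.5 / 8000)
        assert split.test.labels.mean() == pytest.approx(full, abs=1.5 / 2000)

    def test_disjoint_and_exhaustive(self):
        values = np.random.default_rng(0).normal(size=(37, 3))
        m = _matrix(values, [0] * 17 + [1] * 20)
        split = stratified_split(m, 0.7, seed=2)
        train_rows = {tuple(r) for r in split.train.values.to_numpy()}
        test_rows = {tuple(r) for r in split.test.values.to_numpy()}
        assert not train_rows & test_rows
        assert len(split.train.values) + len(split.test.values) == 37

    def test_deterministic(self):
        m = _matrix(np.arange(60).reshape(30, 2), [0] * 12 + [1] * 18)
        a = stratified_split(m, 0.8, seed=9)
        b = stratified_split(m, 0.8, seed=9)
        pd.testing.assert_frame_equal(a.train.values, b.train.values)
        pd.testing.assert_frame_equal(a.test.values, b.test.values)

    def test_tiny_class_rejected(self):
        m = _matrix(np.zeros((5, 1)), [0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(m, 0.8, seed=0)

    def test_bad_fraction_rejected(self):
        m = _matrix(np.zeros((10, 1)), [0] * 5 + [1] * 5)
        with pytest.raises(ValueError, match="train_fraction"):
            stratified_split(m, 1.2, seed=0)


class TestStandardize:
    def _split(self, train_col, test_col, extra_binary=False):
        train = np.array(train_col, dtype=float).reshape(-1, 1)
        test = np.array(test_col, dtype=float).reshape(-1, 1)
        if extra_binary:
            train = np.hstack([train, np.array([[0], [1]])])
            test = np.hstack([test, np.array([[1]])])
        cols = ["x"] + (["flag"] if extra_binary else [])
        from gdmrisk.preprocess import SplitPair

        return SplitPair(
            train=_matrix(train, [0, 1][: len(train)], cols),
            test=_matrix(test, [0] * len(test), cols),
        )

    def test_hand_zscore(self):
        split = self._split([0.0, 2.0], [3.0])
        out = standardize(split, ["x"])
        assert list(out.train.values["x"]) == [-1.0, 1.0]
        assert list(out.test.values["x"]) == [2.0]
        assert out.train.scaling_params["x"] == (1.0, 1.0)

    def test_unlisted_columns_untouched(self):
        split = self._split([0.0, 2.0], [3.0], extra_binary=True)
        out = standardize(split, ["x"])
        assert list(out.train.values["flag"]) == [0, 1]
        assert list(out.test.values["flag"]) == [1]

    def test_train_columns_centred_unit_variance(self, prepared_small):
        _, _, split = prepared_small
        scaled = split.train.values
        for col in split.train.scaling_params:
            assert abs(scaled[col].mean()) < 1e-9
            assert scaled[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_leakage_guard_params_ignore_test_rows(self, cohort_small):
        from gdmrisk.preprocess import SplitPair

        raw = stratified_split(cohort_to_matrix(cohort_small), 0.8, seed=42)
        permuted = SplitPair(
            train=raw.train,
            test=FeatureMatrix(
                raw.test.values.sample(frac=1.0, random_state=0).reset_index(drop=True),
                raw.test.labels.sample(frac=1.0, random_state=0).reset_index(drop=True),
            ),
        )
        # params must depend on train rows only
        assert standardize(permuted).train.scaling_params == standardize(raw).train.scaling_params

    def test_constant_feature_named_in_error(self):
        split = self._split([5.0, 5.0], [5.0])
        with pytest.raises(ValueError, match="'x'"):
            standardize(split, ["x"])


class TestSmote:
    def test_balanced_input_returned_unchanged(self):
        m = _matrix(np.random.default_rng(1).normal(size=(20, 2)), [0] * 10 + [1] * 10)
        out = smote_balance(m, k_neighbors=3, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_exact_parity_and_originals_preserved(self, prepared_small):
        balanced, _, split = prepared_small
        counts = balanced.labels.value_counts()
        assert counts.iloc[0] == counts.iloc[1]
        n_orig = len(split.train.values)
        # synthetic rows may carry fractional flags, so flag columns upcast
        # to float; the original rows themselves are bitwise-preserved
        pd.testing.assert_frame_equal(
            balanced.values.iloc[:n_orig], split.train.values, check_dtype=False
        )

    def test_two_point_minority_interpolates_on_segment(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, 5.0]] * 6)
        m = _matrix(values, [1, 1, 0, 0, 0, 0, 0, 0])
        out = smote_balance(m, k_neighbors=1, seed=3)
        synthetic = out.values.iloc[8:].to_numpy()
        # x + u*(x_nn - x) with minority {(0,0),(1,1)}: points (u,u), 0<=u<=1
        assert np.allclose(synthetic[:, 0], synthetic[:, 1])
        assert ((synthetic >= 0.0) & (synthetic <= 1.0)).all()

    def test_every_synthetic_row_is_convex_combination_of_minority_pair(self):
        """Exhaustive pair search over the original minority rows."""
        rng = np.random.default_rng(5)
        minority = rng.normal(size=(12, 3))
        majority = rng.normal(size=(30, 3)) + 4.0
        m = _matrix(np.vstack([minority, majority]), [1] * 12 + [0] * 30)
        out = smote_balance(m, k_neighbors=5, seed=8)
        synthetic = out.values.iloc[42:].to_numpy()
        assert len(synthetic) == 18
        for x in synthetic:
            found = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    d = b - a
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((x - a) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(a + u * d, x, atol=1e-9):
                        found = True
                        break
                if found:
                    break
            assert found, f"synthetic row {x} is not on any minority segment"

    def test_deterministic(self):
        m = _matrix(np.random.default_rng(2).normal(size=(30, 2)), [1] * 10 + [0] * 20)
        a = smote_balance(m, seed=4)
        b = smote_balance(m, seed=4)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_minority_smaller_than_k_rejected(self):
        m = _matrix(np.random.default_rng(3).normal(size=(10, 2)), [1] * 3 + [0] * 7)
        with pytest.raises(ValueError, match="smaller k"):
            smote_balance(m, k_neighbors=5, seed=0)


class TestCohortToMatrix:
    def test_no_missing_and_no_latent_columns(self, cohort_small):
        m = cohort_to_matrix(cohort_small)
        assert not m.values.isna().any().any()
        for latent in ("risk_score", "outcome_prob", "gdm", "ogtt_tested", "ethnicity"):
            assert latent not in m.values.columns
        assert len(m.values) == len(cohort_small)
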