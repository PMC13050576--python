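"""Leakage-safe preprocessing: encode -> impute -> split -> scale -> SMOTE.

The pipeline order is fixed: ethnicity one-hot encoding (drop-first,
African as the all-zeros reference), zero-imputation of missing OGTT
values (a deliberate three-state encoding: elevated / normal / not
tested), stratified 80/20 split (seed 42), standardization of continuous
features fitted on the training partition only, then SMOTE rebalancing of
the training partition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .constants import ETHNICITIES, RISK_FLAGS
from .simulate import OGTT_COLUMNS

#: columns standardized by default: continuous measurements only; binary
#: flags and one-hot ethnicity indicators keep their interpretable 0/1 states.
CONTINUOUS_FEATURES = (
    "age",
    "bmi",
    "booking_ga",
    "rbs",
    "ppbs",
    "hba1c",
    "ogtt_fasting",
    "ogtt_1h",
    "ogtt_2h",
)

ETHNICITY_DUMMIES = tuple(
    f"ethnicity_{e}" for e in sorted(e for e in ETHNICITIES if e != "African")
)  # African = reference (all zeros)

#: simulator columns that are latent (never model features)
NON_FEATURE_COLUMNS = ("risk_score", "outcome_prob", "gdm", "ogtt_tested")


@dataclass
class FeatureMatrix:
    """Model-ready matrix: features, aligned labels, optional scaling params."""

    values: pd.DataFrame
    labels: pd.Series
    scaling_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("labels length must equal row count")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureMatrix":
        params = dict(self.scaling_params) if self.scaling_params else None
        return FeatureMatrix(self.values.copy(), self.labels.copy(), params)


@dataclass
class SplitPair:
    train: FeatureMatrix
    test: FeatureMatrix
    split_seed: int = 42
    train_fraction: float = 0.8


def encode_ethnicity(cohort: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode ethnicity, dropping the African reference category.

    Adds ethnicity_Asian / _Caucasian / _Hispanic / _Other indicator
    columns (African encodes as all zeros) and drops the original column.
    """
    if "ethnicity" not in cohort.columns:
        raise KeyError("cohort has no 'ethnicity' column")
    values = cohort["ethnicity"].astype(object)
    unknown = sorted(set(values.dropna()) - set(ETHNICITIES))
    if unknown:
        raise ValueError(f"unknown ethnicity categories: {unknown}")
    out = cohort.drop(columns=["ethnicity"])
    for name in ETHNICITY_DUMMIES:
        category = name.removeprefix("ethnicity_")
        out[name] = (values == category).astype(np.int64)
    return out


def impute_ogtt_zero(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace missing OGTT cells with 0; returns (frame, n cells imputed).

    Missingness anywhere outside the three OGTT columns is an error: the
    simulator guarantees complete data elsewhere, so a NaN there signals
    upstream corruption rather than an untested patient.
    """
    non_ogtt = [c for c in frame.columns if c not in OGTT_COLUMNS]
    bad = [c for c in non_ogtt if frame[c].isna().any()]
    if bad:
        raise ValueError(f"MISSING values outside OGTT columns: {bad}")
    out = frame.copy()
    n_imputed = 0
    for col in OGTT_COLUMNS:
        if col in out.columns:
            missing = out[col].isna()
            n_imputed += int(missing.sum())
            out[col] = out[col].fillna(0.0)
    return out, n_imputed


def cohort_to_matrix(cohort: pd.DataFrame, label_column: str = "gdm") -> FeatureMatrix:
    """Encode and impute a raw simulated cohort into a FeatureMatrix."""
    labels = cohort[label_column].astype(np.int64)
    features = cohort.drop(columns=[c for c in NON_FEATURE_COLUMNS if c in cohort.columns])
    features = encode_ethnicity(features)
    features, _ = impute_ogtt_zero(features)
    return FeatureMatrix(features.reset_index(drop=True), labels.reset_index(drop=True))


def _largest_remainder_counts(class_sizes: dict, fraction: float) -> dict:
    """Per-class train allocation, rounded by largest remainder.

    Ties in remainders are broken by class label order.
    """
    exact = {c: n * fraction for c, n in class_sizes.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    total_target = int(round(sum(class_sizes.values()) * fraction))
    leftover = total_target - sum(counts.values())
    order = sorted(exact, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def stratified_split(
    matrix: FeatureMatrix, train_fraction: float = 0.8, seed: int = 42
) -> SplitPair:
    """Stratified train/test split preserving class proportions.

    Per-class allocation is proportional to ``train_fraction`` with
    largest-remainder rounding; row assignment within a class is a seeded
    shuffle.  The two partitions are disjoint and exhaustive.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    labels = matrix.labels
    class_sizes = labels.value_counts().to_dict()
    if len(class_sizes) < 2:
        raise ValueError("need at least two classes to split")
    tiny = [c for c, n in class_sizes.items() if n < 2]
    if tiny:
        raise ValueError(f"classes with fewer than 2 records: {tiny}")
    counts = _largest_remainder_counts(class_sizes, train_fraction)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in sorted(class_sizes):
        idx = np.flatnonzero(labels.to_numpy() == cls)
        perm = rng.permutation(idx)
        train_idx.append(np.sort(perm[: counts[cls]]))
        test_idx.append(np.sort(perm[counts[cls]:]))
    train_rows = np.sort(np.concatenate(train_idx))
    test_rows = np.sort(np.concatenate(test_idx))
    train = FeatureMatrix(
        matrix.values.iloc[train_rows].reset_index(drop=True),
        labels.iloc[train_rows].reset_index(drop=True),
    )
    test = FeatureMatrix(
        matrix.values.iloc[test_rows].reset_index(drop=True),
        labels.iloc[test_rows].reset_index(drop=True),
    )
    return SplitPair(train=train, test=test, split_seed=seed, train_fraction=train_fraction)


def standardize(
    split: SplitPair, continuous_features: tuple[str, ...] | list[str] = CONTINUOUS_FEATURES
) -> SplitPair:
    """z-score the listed features using means/SDs fitted on train only.

    Population (ddof=0) moments; unlisted columns pass through untouched.
    A constant training feature (zero SD) is an error naming the feature.
    """
    if len(split.train.values) == 0:
        raise ValueError("train partition is empty")
    present = [c for c in continuous_features if c in split.train.values.columns]
    params: dict[str, tuple[float, float]] = {}
    train_values = split.train.values.copy()
    test_values = split.test.values.copy()
    for col in present:
        mean = float(train_values[col].mean())
        sd = float(train_values[col].std(ddof=0))
        if sd == 0.0:
            raise ValueError(f"constant training feature (zero SD): {col!r}")
        params[col] = (mean, sd)
        train_values[col] = (train_values[col] - mean) / sd
        test_values[col] = (test_values[col] - mean) / sd
    train = FeatureMatrix(train_values, split.train.labels.copy(), params)
    test = FeatureMatrix(test_values, split.test.labels.copy(), params)
    return SplitPair(train=train, test=test, split_seed=split.split_seed,
                     train_fraction=split.train_fraction)


def smote_balance(
    train: FeatureMatrix, k_neighbors: int = 5, seed: int = 42
) -> FeatureMatrix:
    """SMOTE: oversample the minority class to exact parity.

    Each synthetic row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0,1)``
    and ``x_nn`` one of the ``k_neighbors`` nearest minority neighbours of
    ``x`` (Euclidean, in the post-scaling feature space).  Original rows
    are preserved verbatim and synthetic rows are appended; the output has
    exactly equal class counts.  Already balanced input is returned as-is.
    """
    labels = train.labels
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return train.copy()
    minority_rows = train.values.loc[labels == minority].to_numpy(dtype=float)
    if len(minority_rows) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(minority_rows)} rows <= k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority_rows)
    # drop self-neighbour (column 0)
    neighbour_idx = nn.kneighbors(minority_rows, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(minority_rows), size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    u = rng.random(n_needed)
    x = minority_rows[base]
    x_nn = minority_rows[neighbour_idx[base, pick]]
    synthetic = x + u[:, None] * (x_nn - x)
    values = pd.concat(
        [train.values, pd.DataFrame(synthetic, columns=train.values.columns)],
        ignore_index=True,
    )
    new_labels = pd.concat(
        [labels, pd.Series(np.full(n_needed, minority), dtype=labels.dtype)],
        ignore_index=True,
    )
    return FeatureMatrix(values, new_labels, train.scaling_params)


def prepare(
    cohort: pd.DataFrame,
    train_fraction: float = 0.8,
    split_seed: int = 42,
    smote_k: int = 5,
    smote_seed: int = 42,
) -> tuple[FeatureMatrix, FeatureMatrix, SplitPair]:
    """Full chain: encode -> impute -> split -> standardize -> SMOTE(train).

    Returns ``(balanced_train, test, scaled_split)`` where the scaled split
    holds the pre-SMOTE training partition for audit.
    """
    matrix = cohort_to_matrix(cohort)
    split = stratified_split(matrix, train_fraction=train_fraction, seed=split_seed)
    split = standardize(split)
    balanced = smote_balance(split.train, k_neighbors=smote_k, seed=smote_seed)
    return balanced, split.test, split
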