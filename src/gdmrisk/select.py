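"""Seven-method consensus feature importance.

Each method produces per-feature raw importances that are min–max
normalized to [0, 1]; the consensus table averages normalized scores
across methods and reports the standard deviation of each feature's
(fractional) rank as a cross-method stability measure.

Methods: Gini importance from a random forest and from extra-randomized
trees, ANOVA F-score, mutual information (k-NN estimator), permutation
importance (accuracy decrease under shuffling, random-forest base model),
recursive feature elimination with a logistic base estimator (scores from
elimination order), and absolute Pearson correlation with the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif, mutual_info_classif
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression

from .preprocess import FeatureMatrix

METHODS = (
    "forest",
    "extra_random_trees",
    "f_score",
    "mutual_information",
    "permutation",
    "recursive_elimination",
    "correlation",
)


@dataclass
class ImportanceVector:
    """Normalized per-feature importances from one selection method."""

    method: str
    features: list[str]
    scores: np.ndarray  # normalized to [0, 1]
    raw_scores: np.ndarray

    @property
    def ranks(self) -> np.ndarray:
        """Integer ranks, 1 = most important; ties broken by feature name."""
        order = sorted(range(len(self.features)), key=lambda i: (-self.scores[i], self.features[i]))
        ranks = np.empty(len(self.features), dtype=int)
        for position, i in enumerate(order, start=1):
            ranks[i] = position
        return ranks

    @property
    def fractional_ranks(self) -> np.ndarray:
        """Average (fractional) ranks, ties shared; used for rank-SD."""
        return rankdata(-self.scores, method="average")


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Scale raw scores to [0, 1]; an all-equal vector maps to all ones."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


def _correlation_scores(X: np.ndarray, y: np.ndarray, feature_names) -> np.ndarray:
    """|Pearson r| per feature; constant features score 0 with a warning."""
    scores = np.zeros(X.shape[1])
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    for j in range(X.shape[1]):
        xc = X[:, j] - X[:, j].mean()
        x_ss = float(xc @ xc)
        if x_ss == 0.0 or y_ss == 0.0:
            warnings.warn(
                f"constant feature {feature_names[j]!r} under correlation; score set to 0",
                stacklevel=2,
            )
            continue
        scores[j] = abs(float(xc @ yc) / np.sqrt(x_ss * y_ss))
    return scores


def compute_importance(
    train: FeatureMatrix,
    method: str,
    seed: int = 42,
    n_estimators: int = 100,
    permutation_repeats: int = 10,
    permutation_eval_cap: int = 2500,
    mi_neighbors: int = 3,
) -> ImportanceVector:
    """Per-feature importance by one named method, min–max normalized."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    X = train.values.to_numpy(dtype=float)
    y = train.labels.to_numpy()
    names = train.feature_names
    p = X.shape[1]

    if method == "forest":
        model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        raw = model.fit(X, y).feature_importances_
    elif method == "extra_random_trees":
        model = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        raw = model.fit(X, y).feature_importances_
    elif method == "f_score":
        raw, _ = f_classif(X, y)
        raw = np.nan_to_num(raw, nan=0.0)
    elif method == "mutual_information":
        raw = mutual_info_classif(X, y, n_neighbors=mi_neighbors, random_state=seed)
    elif method == "permutation":
        model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        model.fit(X, y)
        # accuracy decrease is measured on a seeded subsample: the estimate
        # stays unbiased and the shuffle evaluations stay affordable
        if len(X) > permutation_eval_cap:
            idx = np.random.default_rng(seed).choice(len(X), permutation_eval_cap, replace=False)
            X_eval, y_eval = X[idx], y[idx]
        else:
            X_eval, y_eval = X, y
        result = permutation_importance(
            model, X_eval, y_eval, scoring="accuracy",
            n_repeats=permutation_repeats, random_state=seed,
        )
        raw = result.importances_mean
    elif method == "recursive_elimination":
        # run elimination down to a single feature so every feature gets a
        # distinct elimination position; score = (p - position + 1) / p
        rfe = RFE(LogisticRegression(max_iter=1000), n_features_to_select=1, step=1)
        rfe.fit(X, y)
        raw = (p - rfe.ranking_ + 1) / p
    else:  # correlation
        raw = _correlation_scores(X, y, names)

    return ImportanceVector(method=method, features=list(names), scores=minmax_normalize(raw),
                            raw_scores=np.asarray(raw, dtype=float))


def compute_all_importances(
    train: FeatureMatrix, seed: int = 42, methods=METHODS, **options
) -> list[ImportanceVector]:
    return [compute_importance(train, m, seed=seed, **options) for m in methods]


def consensus_rank(vectors: list[ImportanceVector]) -> pd.DataFrame:
    """Consensus table: mean normalized importance + rank SD per feature.

    Sorted by average importance descending.  Rank SD is the sample
    standard deviation of fractional per-method ranks (0 iff all methods
    agree).  Invariant to the order the vectors are supplied in.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 importance vectors")
    reference = sorted(vectors[0].features)
    for v in vectors[1:]:
        if sorted(v.features) != reference:
            diff = set(v.features) ^ set(reference)
            raise ValueError(f"mismatched feature sets; symmetric difference: {sorted(diff)}")
    features = vectors[0].features
    score_rows = {}
    rank_rows = {}
    for v in sorted(vectors, key=lambda v: v.method):
        aligned = pd.Series(v.scores, index=v.features).reindex(features)
        score_rows[v.method] = aligned.to_numpy()
        rank_rows[f"rank_{v.method}"] = (
            pd.Series(v.fractional_ranks, index=v.features).reindex(features).to_numpy()
        )
    ranks = np.column_stack(list(rank_rows.values()))
    table = pd.DataFrame(
        {
            "feature": features,
            "average": np.column_stack(list(score_rows.values())).mean(axis=1),
            "rank_sd": ranks.std(axis=1, ddof=1),
            **rank_rows,
        }
    )
    table = table.sort_values(
        ["average", "rank_sd", "feature"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return table


def select_top_k(table: pd.DataFrame, k: int) -> list[str]:
    """The k features with highest average importance.

    Ties by lower rank SD, then lexicographic feature name (the table is
    already sorted that way).
    """
    p = len(table)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return table["feature"].head(k).tolist()
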