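"""Additive per-feature attribution (Shapley values, kernel estimator).

Attributions are estimated model-agnostically: for an instance ``x`` and
a background sample ``B``, the value of a feature coalition ``S`` is the
model's mean output with the features in ``S`` taken from ``x`` and the
rest filled row-wise from ``B`` (the background-marginal value function).
Shapley values are recovered by weighted least squares over coalitions
with the Shapley kernel weights, constrained so attributions sum exactly
to ``f(x) - base`` (local accuracy).  When the coalition budget covers
the full ``2^p - 2`` non-trivial coalitions the estimate is exact; a
brute-force enumeration oracle over all coalitions is provided for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, factorial
from typing import Any, Callable

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix


def _as_function(model: Any) -> Callable[[np.ndarray], np.ndarray]:
    """Positive-class probability function from a model or plain callable."""
    if hasattr(model, "predict_proba"):
        from .bench import predict_proba

        return lambda X: predict_proba(model, X)
    if callable(model):
        return lambda X: np.asarray(model(X), dtype=float).reshape(-1)
    raise TypeError("model must expose predict_proba or be callable")


@dataclass
class AttributionSet:
    """Per-instance additive feature contributions plus the baseline."""

    base_value: float
    contributions: pd.DataFrame  # instances x features
    feature_values: pd.DataFrame  # same shape: the explained inputs
    predictions: np.ndarray  # model output per instance

    def __post_init__(self) -> None:
        if self.contributions.shape != self.feature_values.shape:
            raise ValueError("contributions and feature_values shapes differ")
        if len(self.predictions) != len(self.contributions):
            raise ValueError("one prediction per explained instance required")

    def additivity_gap(self) -> np.ndarray:
        """|base + sum(contributions) - prediction| per instance."""
        totals = self.base_value + self.contributions.to_numpy().sum(axis=1)
        return np.abs(totals - self.predictions)


# ---------------------------------------------------------------------------
# explain-set sampling


def sample_explain_sets(
    test: FeatureMatrix,
    n_background: int = 100,
    n_explain: int = 50,
    class_counts: dict[int, int] | None = None,
    seed: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Background (simple random) and explain (stratified) samples of the test set.

    Returns ``(background, explain, explain_labels)``.  The background is
    drawn without replacement; the explain set takes exactly the requested
    per-class counts (by default proportional to the test class mix,
    largest class rounded up).
    """
    y = test.labels
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("test set must contain both classes")
    if n_background > len(test.values):
        raise ValueError(f"n_background={n_background} exceeds test size {len(test.values)}")
    rng = np.random.default_rng(seed)
    bg_idx = np.sort(rng.choice(len(test.values), size=n_background, replace=False))

    if class_counts is None:
        counts = {c: int(round(n_explain * (y == c).mean())) for c in classes}
        # fix rounding drift on the largest class
        drift = n_explain - sum(counts.values())
        counts[max(counts, key=counts.get)] += drift
        class_counts = counts
    if sum(class_counts.values()) != n_explain:
        raise ValueError(f"class_counts {class_counts} do not sum to n_explain={n_explain}")
    explain_idx = []
    for cls in sorted(class_counts):
        pool = np.flatnonzero(y.to_numpy() == cls)
        want = class_counts[cls]
        if want > len(pool):
            raise ValueError(f"requested {want} of class {cls} but only {len(pool)} available")
        explain_idx.append(rng.choice(pool, size=want, replace=False))
    explain_idx = np.sort(np.concatenate(explain_idx))
    return (
        test.values.iloc[bg_idx].reset_index(drop=True),
        test.values.iloc[explain_idx].reset_index(drop=True),
        y.iloc[explain_idx].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# coalition machinery


def _coalition_values(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """v(S) for each mask row: mean model output with S from x, rest from background."""
    m, p = masks.shape
    n_b = background.shape[0]
    tiled = np.repeat(masks, n_b, axis=0).astype(bool)
    base = np.tile(background, (m, 1))
    data = np.where(tiled, x, base)
    return f(data).reshape(m, n_b).mean(axis=1)


def _enumerate_masks(p: int) -> np.ndarray:
    """All 2^p - 2 non-trivial coalition masks."""
    masks = []
    for s in range(1, p):
        for subset in combinations(range(p), s):
            row = np.zeros(p, dtype=bool)
            row[list(subset)] = True
            masks.append(row)
    return np.array(masks)


def _kernel_weight(p: int, s: int) -> float:
    """Shapley kernel weight of one coalition of size s (0 < s < p)."""
    return (p - 1) / (comb(p, s) * s * (p - s))


def _sample_masks(
    p: int, budget: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coalition masks + weights under a limited budget.

    Sizes are processed in Shapley-kernel weight order (outermost sizes
    first, in (s, p-s) pairs); a size is fully enumerated while the budget
    allows, remaining budget is sampled from the leftover sizes in
    proportion to their kernel weight mass.
    """
    size_mass = {s: 1.0 / (s * (p - s)) for s in range(1, p)}
    order: list[int] = []
    for s in range(1, p // 2 + 1):
        order.append(s)
        if p - s != s:
            order.append(p - s)
    masks: list[np.ndarray] = []
    weights: list[float] = []
    remaining = budget
    sampled_sizes = []
    for s in order:
        count = comb(p, s)
        if count <= remaining:
            for subset in combinations(range(p), s):
                row = np.zeros(p, dtype=bool)
                row[list(subset)] = True
                masks.append(row)
                weights.append(size_mass[s] / count)
            remaining -= count
        else:
            sampled_sizes.append(s)
    if sampled_sizes and remaining > 0:
        mass = np.array([size_mass[s] for s in sampled_sizes])
        mass = mass / mass.sum()
        total_sampled_mass = sum(size_mass[s] for s in sampled_sizes)
        draw = rng.choice(len(sampled_sizes), size=remaining, p=mass)
        for k in draw:
            s = sampled_sizes[k]
            row = np.zeros(p, dtype=bool)
            row[rng.choice(p, size=s, replace=False)] = True
            masks.append(row)
            # sampled coalitions share the leftover kernel mass uniformly
            weights.append(total_sampled_mass / remaining)
    return np.array(masks), np.array(weights)


def _solve_constrained_wls(
    masks: np.ndarray, weights: np.ndarray, values: np.ndarray, base: float, fx: float
) -> np.ndarray:
    """Weighted least squares for Shapley regression coefficients.

    Minimizes sum_i w_i (v_i - base - z_i . phi)^2 subject to
    sum(phi) = fx - base (local accuracy), by eliminating the last
    coefficient.
    """
    m, p = masks.shape
    z = masks.astype(float)
    total = fx - base
    if p == 1:
        return np.array([total])
    z_red = z[:, :-1] - z[:, [-1]]
    target = values - base - z[:, -1] * total
    w = np.sqrt(weights)
    phi_red, *_ = np.linalg.lstsq(z_red * w[:, None], target * w, rcond=None)
    return np.append(phi_red, total - phi_red.sum())


# ---------------------------------------------------------------------------
# public attribution API


def attribute(
    model: Any,
    background: pd.DataFrame | np.ndarray,
    instances: pd.DataFrame | np.ndarray,
    n_coalitions: int = 2048,
    seed: int = 42,
) -> AttributionSet:
    """Additive Shapley-style attributions for each instance.

    ``n_coalitions`` caps the number of feature coalitions evaluated per
    instance; when it covers all ``2^p - 2`` coalitions the result is the
    exact Shapley value under the background-marginal value function.
    Local accuracy (base + sum of contributions = prediction) holds by
    construction.
    """
    f = _as_function(model)
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a non-empty 2D array")
    if isinstance(instances, pd.DataFrame):
        columns = list(instances.columns)
        X = instances.to_numpy(dtype=float)
        index = instances.index
    else:
        X = np.asarray(instances, dtype=float)
        columns = [f"x{j}" for j in range(X.shape[1])]
        index = pd.RangeIndex(len(X))
    p = X.shape[1]
    if n_coalitions < p + 2:
        raise ValueError(f"n_coalitions={n_coalitions} underdetermines p={p} features (need >= p+2)")

    base_value = float(f(bg).mean())
    predictions = f(X)

    full = 2**p - 2
    rng = np.random.default_rng(seed)
    if full <= n_coalitions:
        masks = _enumerate_masks(p)
        weights = np.array([_kernel_weight(p, int(m.sum())) for m in masks])
    else:
        masks, weights = _sample_masks(p, n_coalitions, rng)

    rows = np.empty((len(X), p))
    for i, x in enumerate(X):
        values = _coalition_values(f, x, bg, masks)
        rows[i] = _solve_constrained_wls(masks, weights, values, base_value, float(predictions[i]))
    return AttributionSet(
        base_value=base_value,
        contributions=pd.DataFrame(rows, columns=columns, index=index),
        feature_values=pd.DataFrame(X, columns=columns, index=index),
        predictions=np.asarray(predictions, dtype=float),
    )


def shapley_brute_force(
    model: Any,
    background: pd.DataFrame | np.ndarray,
    instance: pd.Series | np.ndarray,
) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^p coalitions.

    Independent oracle for :func:`attribute`; cost grows as ``2^p`` so it
    is only practical for small feature counts.
    """
    f = _as_function(model)
    bg = np.asarray(background, dtype=float)
    x = np.asarray(instance, dtype=float).reshape(-1)
    p = x.size

    cache: dict[frozenset, float] = {}

    def value(subset: frozenset) -> float:
        if subset not in cache:
            mask = np.zeros(p, dtype=bool)
            mask[list(subset)] = True
            data = np.where(mask, x, bg)
            cache[subset] = float(f(data).mean())
        return cache[subset]

    phi = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [k for k in others if k != j]
        for s in range(p):
            coef = factorial(s) * factorial(p - s - 1) / factorial(p)
            for subset in combinations(rest, s):
                fs = frozenset(subset)
                phi[j] += coef * (value(fs | {j}) - value(fs))
    return phi


def global_importance(attributions: AttributionSet) -> pd.DataFrame:
    """Mean |contribution| per feature, sorted descending (ties by name)."""
    if len(attributions.contributions) == 0:
        raise ValueError("empty attribution set")
    means = attributions.contributions.abs().mean(axis=0)
    table = (
        means.rename("mean_abs_contribution")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["mean_abs_contribution", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return table


def waterfall(attributions: AttributionSet, instance: int | Any = 0) -> pd.DataFrame:
    """Ordered contribution ledger for one explained instance.

    Contributions sorted by |value| descending with a running cumulative
    sum from the baseline to the final prediction; drops exact-zero
    contributions (an all-zero attribution yields an empty ledger whose
    final value is the baseline).
    """
    row = attributions.contributions.loc[instance]
    values = attributions.feature_values.loc[instance]
    ordered = row.reindex(row.abs().sort_values(ascending=False, kind="stable").index)
    ordered = ordered[ordered != 0.0]
    ledger = pd.DataFrame(
        {
            "feature": ordered.index,
            "feature_value": values.reindex(ordered.index).to_numpy(),
            "contribution": ordered.to_numpy(),
        }
    )
    ledger["cumulative"] = attributions.base_value + ledger["contribution"].cumsum()
    return ledger
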