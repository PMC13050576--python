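"""Convenience plots for attribution output (the data behind them is the
primary artifact; these are deliberately plain renderings)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .explain import AttributionSet, global_importance, waterfall


def plot_global_importance(attributions: AttributionSet, path: str | Path) -> None:
    """Horizontal bar chart of mean |contribution| per feature."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = global_importance(attributions).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(table) + 1))
    ax.barh(table["feature"], table["mean_abs_contribution"], color="#4878d0")
    ax.set_xlabel("mean |contribution| to predicted GDM probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_waterfall(attributions: AttributionSet, path: str | Path, instance: int = 0) -> None:
    """Waterfall from the baseline expectation to one instance's prediction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ledger = waterfall(attributions, instance=instance)
    base = attributions.base_value
    starts = np.concatenate([[base], ledger["cumulative"].to_numpy()[:-1]])
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(ledger) + 1.5))
    for i, (_, row) in enumerate(ledger.iterrows()):
        color = "#d65f5f" if row["contribution"] > 0 else "#4878d0"
        ax.barh(i, row["contribution"], left=starts[i], color=color)
    ax.set_yticks(range(len(ledger)))
    ax.set_yticklabels(
        [f"{r.feature} = {r.feature_value:.2f}" for r in ledger.itertuples()]
    )
    ax.axvline(base, color="grey", lw=1, ls="--")
    ax.invert_yaxis()
    ax.set_xlabel(
        f"predicted probability (base {base:.3f} -> "
        f"{attributions.predictions[instance]:.3f})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
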