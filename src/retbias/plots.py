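"""Basic report plots (2D pathway-vs-pathway efficacy comparison)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_pathway_comparison"]


def plot_pathway_comparison(
    table: pd.DataFrame, pathway_a: str, pathway_b: str, path: str | Path
) -> None:
    """Scatter normalized efficacies of pathway A against pathway B with the
    identity line; discordance shows as points far off the diagonal."""
    col_a = f"efficacy_{pathway_a}"
    col_b = f"efficacy_{pathway_b}"
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(table[col_a], table[col_b], color="tab:blue", zorder=3)
    for row in table.itertuples():
        ax.annotate(
            row.agonist,
            (getattr(row, col_a), getattr(row, col_b)),
            textcoords="offset points",
            xytext=(4, 4),
            fontsize=8,
        )
    lim = max(float(table[col_a].max()), float(table[col_b].max()), 1.0) * 1.1
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8, zorder=1)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel(f"normalized efficacy ({pathway_a})")
    ax.set_ylabel(f"normalized efficacy ({pathway_b})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
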