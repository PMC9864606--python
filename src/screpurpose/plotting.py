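"""Report figures: occurrence bar chart and intersection matrix."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; reports are written, not shown

import matplotlib.pyplot as plt
import pandas as pd


def plot_occurrence(table: pd.DataFrame, display_min: int = 6, ax=None):
    """Horizontal bar chart of molecules occurring >= display_min times."""
    shown = table[table["count"] >= display_min]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(shown))))
    ax.barh(shown["molecule"][::-1], shown["count"][::-1], color="#4c72b0")
    ax.set_xlabel("occurrences across cell-type top lists")
    ax.set_title(f"molecules occurring ≥ {display_min} times")
    plt.tight_layout()
    return ax


def plot_intersections(table: pd.DataFrame, ax=None):
    """UpSet-style membership matrix: one column per exact-membership
    group (group size annotated), one row per cell type."""
    cell_types = sorted({ct for row in table["cell_types"] for ct in row.split("|")})
    if ax is None:
        _, ax = plt.subplots(figsize=(max(3, 0.5 * len(table)), 0.5 * len(cell_types) + 1.5))
    for j, (_, row) in enumerate(table.iterrows()):
        members = set(row["cell_types"].split("|"))
        for i, ct in enumerate(cell_types):
            filled = ct in members
            ax.scatter(j, i, s=60, c="#333333" if filled else "#dddddd", zorder=3)
        ax.annotate(
            str(row["size"]), (j, len(cell_types) - 0.4),
            ha="center", fontsize=8,
        )
    ax.set_yticks(range(len(cell_types)), cell_types)
    ax.set_xticks([])
    ax.set_xlabel("exact-membership molecule groups (size above)")
    ax.set_ylim(-0.5, len(cell_types) + 0.2)
    plt.tight_layout()
    return ax
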