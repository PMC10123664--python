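"""Small plotting helpers for accuracy-vs-condition curves and bias matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .transforms import SweepResult

__all__ = ["plot_sweep", "plot_cross_task"]


def plot_sweep(result: SweepResult, ax=None, label: str | None = None, chance: float = 0.5):
    """Accuracy versus condition with a ±1 sd band and a chance line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = result.conditions
    ax.plot(x, result.mean, marker="o", label=label)
    if result.n > 1:
        ax.fill_between(x, result.mean - result.sd, result.mean + result.sd, alpha=0.25)
    ax.axhline(chance, ls=":", color="gray")
    ax.set_xlabel(result.condition_name)
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.02)
    if label:
        ax.legend()
    return ax


def plot_cross_task(table: pd.DataFrame, ax=None):
    """Heatmap of a model x dataset accuracy grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    im = ax.imshow(table.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(table.index)), table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            ax.text(j, i, f"{table.iat[i, j]:.2f}", ha="center", va="center", color="w")
    ax.figure.colorbar(im, ax=ax, label="accuracy")
    return ax
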