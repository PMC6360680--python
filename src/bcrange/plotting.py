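"""Minimal plotting hooks for the rank-2 biplot."""

from __future__ import annotations

import numpy as np

from .decomposition import BiplotModel
from .selection import SelectionResult

__all__ = ["biplot"]


def biplot(
    model: BiplotModel,
    labels: np.ndarray | None = None,
    result: SelectionResult | None = None,
    score_scale: float = 0.001,
    ax=None,
):
    """Overlay scaled sample scores and loading arrows on shared axes.

    Scores are multiplied by ``score_scale`` (display only; selection is
    scale-invariant). Selected features, when a result is given, are drawn
    emphasized. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    scores = model.scores * score_scale
    if labels is None:
        ax.scatter(scores[:, 0], scores[:, 1], marker="+", c="gray")
    else:
        for value, marker in zip(np.unique(labels), ("+", "x")):
            mask = labels == value
            ax.scatter(
                scores[mask, 0], scores[mask, 1], marker=marker,
                label=f"label {value}",
            )
        ax.legend(loc="best", fontsize="small")
    arrows = model.arrows
    ax.scatter(arrows[:, 0], arrows[:, 1], s=4, c="lightgray", zorder=1)
    if result is not None and result.union_selected:
        idx = sorted(result.union_selected)
        ax.scatter(
            arrows[idx, 0], arrows[idx, 1], s=14, c="crimson", zorder=2,
            label="selected",
        )
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel("predictive component")
    ax.set_ylabel("orthogonal component")
    return ax
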