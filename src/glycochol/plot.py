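"""Minimal plotting: Kaplan-Meier step curves and a consensus heat map."""

from __future__ import annotations

import numpy as np

from .survival import SurvivalCurve

__all__ = ["plot_km_curves", "plot_consensus_heatmap"]


def plot_km_curves(curves: dict[str, SurvivalCurve], ax=None, title: str = ""):
    """Step plot of one KM curve per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival_probs])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_consensus_heatmap(M: np.ndarray, labels=None, ax=None, title: str = ""):
    """Heat map of the consensus matrix, optionally ordered by final labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    order = np.argsort(labels) if labels is not None else np.arange(M.shape[0])
    im = ax.imshow(M[np.ix_(order, order)], cmap="viridis", vmin=0, vmax=1)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    return ax
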