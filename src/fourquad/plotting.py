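"""Headless-safe plotting: four-quadrant scatter and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .data import DifferencePairs

__all__ = ["four_quadrant_plot", "roc_plot"]


def four_quadrant_plot(diffs: DifferencePairs, a: float, path=None, ax=None):
    """Scatter of the pooled difference pairs with the exclusion square.

    Agreement points are drawn red, disagreement blue, excluded points grey;
    the dotted line is the 45-degree identity reference.
    """
    x = diffs.x.ravel()
    y = diffs.y.ravel()
    agree = ((x >= 0) & (y >= 0)) | ((x < 0) & (y < 0))
    excl = (np.abs(x) <= a) & (np.abs(y) <= a)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x[agree & ~excl], y[agree & ~excl], c="tab:red", s=18, label="agreement")
    ax.scatter(
        x[~agree & ~excl], y[~agree & ~excl], c="tab:blue", s=18, label="disagreement"
    )
    ax.scatter(x[excl], y[excl], c="0.6", s=18, label="excluded")
    lim = 1.1 * max(np.abs(np.r_[x, y]).max(), a) or 1.0
    ax.plot([-lim, lim], [-lim, lim], ":", c="0.3", lw=1)
    if a > 0:
        ax.add_patch(
            plt.Rectangle((-a, -a), 2 * a, 2 * a, fill=False, ec="0.4", lw=1)
        )
    ax.axhline(0, c="0.2", lw=0.8)
    ax.axvline(0, c="0.2", lw=0.8)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("gold-standard difference x")
    ax.set_ylabel("experimental difference y")
    ax.legend(loc="upper left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def roc_plot(rocs: dict, path=None, ax=None):
    """Overlayed ROC curves, one per method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, roc in rocs.items():
        pts = np.asarray(roc.roc_points)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC={roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ":", c="0.5", lw=1)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
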