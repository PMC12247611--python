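"""Optional plotting helpers (centile plots, PR curves, correlation heatmap)."""

from __future__ import annotations

import numpy as np

from .model import NormativeModel, compute_centiles


def plot_centiles(model: NormativeModel, ages, y, ax=None, levels=(1, 5, 25, 50, 75, 95, 99), color_by=None):
    """Scatter a cohort over the model's centile curves.

    ``color_by`` optionally colors the points (e.g. by SNR or visual score),
    mirroring the usual normative-model diagnostic plot.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lo, hi = model.basis.domain
    grid = np.linspace(lo, hi, 200)
    for q, curve in compute_centiles(model, grid, levels).items():
        lw = 2.0 if q == 50 else 0.8
        ax.plot(grid, curve, color="k", lw=lw, alpha=0.7)
    sc = ax.scatter(ages, y, s=6, c=color_by, cmap="viridis", alpha=0.6)
    if color_by is not None:
        ax.figure.colorbar(sc, ax=ax)
    ax.set_xlabel("age (years)")
    return ax


def plot_pr_curves(sweep: dict, ax=None):
    """Plot the PR curves returned by :func:`nmqc.pr_threshold_sweep`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in sweep.items():
        if "precision" not in curve:
            continue
        ax.plot(curve["recall"], curve["precision"], label=f"{label} (AUC={curve['auc']:.2f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend(fontsize=7)
    return ax


def plot_correlation(labels, matrix, ax=None):
    """Heatmap of a QC correlation matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = np.asarray(matrix, dtype=float)
    im = ax.imshow(m, vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            ax.text(j, i, f"{m[i, j]:.2f}", ha="center", va="center", fontsize=6)
    ax.figure.colorbar(im, ax=ax)
    return ax
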