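"""Quick matplotlib views of pipeline outputs (not figure-exact graphics)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .association import CorrelationReport
from .surprisal import DecompositionResult

__all__ = ["plot_correlation_heatmap", "plot_amplitude_heatmap"]


def plot_correlation_heatmap(report: CorrelationReport, path=None, ax=None):
    """Clustered Pearson-correlation heatmap (blue/red diverging)."""
    mat = report.ordered()
    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.3 * mat.shape[1]), max(3, 0.3 * mat.shape[0]))
        )
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_amplitude_heatmap(
    result: DecompositionResult, path=None, ax=None, threshold=None
):
    """Per-sample amplitudes of the significant processes.

    If a threshold is given (or stored on the result), amplitudes beyond
    it — the "active" range — are marked with a dot.
    """
    k = result.K_significant or (result.n_components - 1)
    lam = result.lam.iloc[1 : k + 1]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.25 * lam.shape[1]), 1 + 0.5 * k))
    vmax = float(np.abs(lam.to_numpy()).max()) or 1.0
    im = ax.imshow(lam.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    thr = threshold if threshold is not None else result.null_threshold
    if thr:
        act = np.argwhere(np.abs(lam.to_numpy()) > thr)
        ax.scatter(act[:, 1], act[:, 0], s=4, c="k", label="active")
    ax.set_yticks(range(lam.shape[0]),
                  [f"process {a + 1}" for a in range(lam.shape[0])])
    ax.set_xticks(range(lam.shape[1]), lam.columns, rotation=90, fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="amplitude λ")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
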