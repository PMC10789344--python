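"""Headless-safe figures: agreement scatterplots, ROC curves, heatmap."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .classification import RocModelResult
from .group_stats import CorrelationMatrix

__all__ = ["agreement_scatter", "roc_figure", "heatmap_figure"]


def agreement_scatter(
    value_clinical: Sequence[float],
    value_asr: Sequence[float],
    measure: str,
    path: str | Path,
) -> None:
    """Clinical vs ASR scatter with the identity line."""
    a = np.asarray(value_clinical, dtype=float)
    b = np.asarray(value_asr, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lim = [0, max(1.0, np.nanmax(np.concatenate([a, b])) * 1.05)]
    ax.plot(lim, lim, color="grey", lw=1, ls="--", label="identity")
    ax.scatter(a, b, s=18, alpha=0.6, edgecolor="none")
    ax.set_xlabel(f"clinical {measure}")
    ax.set_ylabel(f"ASR {measure}")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.concatenate([[0], np.cumsum(y == 1)])
    fps = np.concatenate([[0], np.cumsum(y == 0)])
    return fps / max(1, (labels == 0).sum()), tps / max(1, (labels == 1).sum())


def roc_figure(results: Mapping[str, RocModelResult], subtest: str, path: str | Path) -> None:
    """ROC curves for the three tiers of one subtest family."""
    fig, ax = plt.subplots(figsize=(4.8, 4.5))
    ax.plot([0, 1], [0, 1], color="grey", lw=1, ls="--")
    for name, res in results.items():
        fpr, tpr = _roc_points(res.scores, res.labels)
        ax.plot(fpr, tpr, label=f"{name} (AUC {res.auc:.2f})")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{subtest} subtest")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_figure(corr: CorrelationMatrix, path: str | Path) -> None:
    """Sign-coded correlation heatmap (blue positive, red negative)."""
    r = corr.r.to_numpy(dtype=float)
    k = len(corr.variables)
    fig, ax = plt.subplots(figsize=(max(5.0, 0.45 * k + 2), max(4.5, 0.45 * k + 1.5)))
    im = ax.imshow(r, cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(k), corr.variables, rotation=90, fontsize=7)
    ax.set_yticks(range(k), corr.variables, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"complete cases: {corr.n_complete}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
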