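"""ROC overlays and stability-path plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .roc import roc_points
from .stability import StabilityProfile

__all__ = ["roc_overlay", "stability_path_plot"]


def roc_overlay(named_scores: dict, labels, path: str | Path, title: str = "ROC") -> None:
    """One ROC curve per named score vector, with AUCs in the legend."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, scores in named_scores.items():
        res = roc_points(scores, labels)
        ax.plot(res.points[:, 0], res.points[:, 1], label=f"{name} (AUC {res.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stability_path_plot(
    profile: StabilityProfile,
    path: str | Path,
    highlight: list[str] | None = None,
    max_background: int = 200,
) -> None:
    """Selection proportion vs lambda per feature (highlighted features in color).

    Background features are thinned to ``max_background`` for legibility.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    lam = profile.lambda_grid
    hi = set(highlight or [])
    shown = 0
    for j, name in enumerate(profile.feature_names):
        if name in hi:
            continue
        if shown >= max_background:
            break
        ax.plot(lam, profile.selection_proportions[j], c="lightgrey", lw=0.5)
        shown += 1
    for j, name in enumerate(profile.feature_names):
        if name in hi:
            ax.plot(lam, profile.selection_proportions[j], lw=1.5, label=name)
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("lambda")
    ax.set_ylabel("selection proportion")
    ax.set_ylim(-0.02, 1.02)
    if hi:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
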