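"""Minimal figure export: expression heat-maps and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def save_heatmap(m: pd.DataFrame, path, title: str = "",
                 cmap: str = "RdBu_r") -> None:
    """Write a features x samples heat-map (NaN cells left blank)."""
    fig, ax = plt.subplots(
        figsize=(max(4, m.shape[1] * 0.12), max(3, m.shape[0] * 0.12))
    )
    arr = np.ma.masked_invalid(m.to_numpy(float))
    vmax = float(np.nanmax(np.abs(m.to_numpy(float)))) or 1.0
    im = ax.imshow(arr, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xlabel("samples")
    ax.set_ylabel("features")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_roc_curves(roc_results, path) -> None:
    """Overlay ROC curves of several markers on one panel."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in roc_results:
        ax.plot(r.fpr, r.tpr, label=f"{r.symbol} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
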