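"""Optional graphical outputs (volcano, GC-dependence, pre/post scatter)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _ax():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def volcano(contrast: pd.DataFrame, path: str | Path, *, lfc=0.6, fdr=0.01) -> None:
    """Volcano plot of one dose contrast (log2FC vs -log10 FDR)."""
    plt = _ax()
    fig, ax = plt.subplots(figsize=(5, 4))
    x = contrast["log2fc"]
    y = -np.log10(contrast["fdr"])
    sig = (contrast["fdr"] <= fdr) & (x.abs() >= lfc)
    ax.scatter(x[~sig], y[~sig], s=4, c="0.7", linewidths=0)
    ax.scatter(x[sig], y[sig], s=6, c="crimson", linewidths=0)
    ax.axhline(-np.log10(fdr), ls="--", lw=0.5, c="k")
    for t in (-lfc, lfc):
        ax.axvline(t, ls="--", lw=0.5, c="k")
    ax.set_xlabel("log2 fold change (treated vs control)")
    ax.set_ylabel("-log10 FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gc_scatter(gc: pd.Series, abundance: pd.Series, path: str | Path) -> None:
    """Motif GC fraction vs mean log2-CPM."""
    plt = _ax()
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(gc, abundance, s=4, c="steelblue", linewidths=0, alpha=0.5)
    ax.set_xlabel("motif GC fraction")
    ax.set_ylabel("mean log2 CPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
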