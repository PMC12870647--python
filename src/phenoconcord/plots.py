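"""Figure emission. Figures are secondary outputs: every number a figure
shows is also written as CSV by the pipeline, and tests assert on the CSVs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def heatmap(df: pd.DataFrame, path: str | Path, title: str = "",
            vmin: float | None = None, vmax: float | None = None,
            cmap: str = "viridis") -> None:
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(df.columns) + 2),
                                    max(3, 0.5 * len(df) + 1.5)))
    im = ax.imshow(df.to_numpy(dtype=float), vmin=vmin, vmax=vmax, cmap=cmap)
    ax.set_xticks(range(len(df.columns)), [str(c) for c in df.columns],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(df.index)), [str(i) for i in df.index], fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def overlap_boxplot(long: pd.DataFrame, path: str | Path) -> None:
    """Box plot of bootstrap overlap distributions per instrument pair and k."""
    long = long.copy()
    long["pair"] = long["instrument_a"] + "/" + long["instrument_b"]
    pairs = sorted(long["pair"].unique())
    ks = sorted(long["k"].unique())
    fig, axes = plt.subplots(1, len(ks), figsize=(3 * len(ks), 3.2), sharey=True)
    if len(ks) == 1:
        axes = [axes]
    for ax, k in zip(axes, ks):
        data = [long.loc[(long["pair"] == p) & (long["k"] == k), "overlap_pct"]
                for p in pairs]
        ax.boxplot(data, tick_labels=pairs)
        ax.set_title(f"k={k}", fontsize=9)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    axes[0].set_ylabel("cluster overlap (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
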