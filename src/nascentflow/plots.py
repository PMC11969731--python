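"""Minimal figure writers (conveniences only; never a test surface)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def volcano(table: pd.DataFrame, path: str | Path, display_cap: float | None = None) -> None:
    """Volcano plot of a differential table (log2FC vs -log10 p).

    `display_cap` trims extreme |log2FC| from the display only; the table
    itself is never altered.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table
    if display_cap is not None:
        df = df[df["log2FC"].abs() <= display_cap]
    sig = df["significant"].astype(bool)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df.loc[~sig, "log2FC"], -np.log10(df.loc[~sig, "p_value"]), s=4, c="grey")
    ax.scatter(df.loc[sig, "log2FC"], -np.log10(df.loc[sig, "p_value"]), s=4, c="crimson")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stratum_box(table: pd.DataFrame, class_map: dict, path: str | Path) -> None:
    """Boxplots of log2FC per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = table["transcript_id"].map(class_map)
    groups = {lab: table.loc[labels == lab, "log2FC"] for lab in pd.unique(labels.dropna())}
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(list(groups.values()), tick_labels=list(groups.keys()))
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_ylabel("log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ipa_bar(counts: pd.Series, path: str | Path) -> None:
    """Bar plot of passed IPA events per sample/condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(counts.index.astype(str), counts.to_numpy())
    ax.set_ylabel("IPA events")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
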