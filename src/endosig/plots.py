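"""Minimal plotting helpers (violin summaries of per-cell ratios)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def violin_by_group(df: pd.DataFrame, value_col: str, group_col: str,
                    path: str | Path) -> Path:
    """Violin plot of one measurement per group, with median and quartiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(df[group_col].dropna().unique())
    data = [df.loc[df[group_col] == g, value_col].dropna().to_numpy()
            for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 + 1.2 * len(groups), 4))
    ax.violinplot(data, showmedians=True, quantiles=[[0.25, 0.75]] * len(data))
    ax.set_xticks(range(1, len(groups) + 1), groups, rotation=30, ha="right")
    ax.set_ylabel(value_col)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
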