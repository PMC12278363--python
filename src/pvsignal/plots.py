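"""Optional thin plotting layer over the exported tables (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def volcano(table: pd.DataFrame, path: str | Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    sig = table["is_signal"].astype(bool)
    ax.scatter(np.log2(table.loc[~sig, "ror"]),
               table.loc[~sig, "neg_log10_p_adjust"], s=12, c="grey")
    ax.scatter(np.log2(table.loc[sig, "ror"]),
               table.loc[sig, "neg_log10_p_adjust"], s=14, c="crimson")
    ax.set_xlabel("log2 ROR")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest(table: pd.DataFrame, path: str | Path) -> None:
    plt = _mpl()
    t = table.dropna(subset=["ci_lower"])
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(t) + 1.5))
    y = np.arange(len(t))[::-1]
    ax.errorbar(t["odds_ratio"], y,
                xerr=[t["odds_ratio"] - t["ci_lower"],
                      t["ci_upper"] - t["odds_ratio"]],
                fmt="o", ms=3, lw=1)
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(y, t["covariate"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def onset_violin(records: pd.DataFrame, path: str | Path) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(4, 4))
    if len(records):
        ax.violinplot([records["onset_days"].to_numpy(dtype=float)],
                      showmedians=True)
    ax.set_ylabel("days from therapy start to onset")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
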