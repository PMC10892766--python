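"""Optional figure output: genome track, Manhattan and QQ plots.

All functions write a file and return its path; they never show a GUI.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_TYPE_COLORS = {"loss": "0.45", "gain": "tab:red", "mixed": "tab:blue"}


def plot_genome_track(track: pd.DataFrame, chroms: pd.DataFrame,
                      path: str | Path) -> Path:
    """CNVR map: one horizontal lane per chromosome, segments colored by type."""
    order = list(chroms["chrom"])
    fig, ax = plt.subplots(figsize=(10, 0.22 * len(order) + 1.5))
    for yi, chrom in enumerate(order):
        clen = float(chroms.loc[chroms["chrom"] == chrom, "length"].iloc[0]) / 1e6
        ax.hlines(yi, 0, clen, color="0.85", lw=2, zorder=1)
        sub = track[track["chrom"] == chrom]
        for _, row in sub.iterrows():
            ax.plot(
                [row["start_mb"], max(row["end_mb"], row["start_mb"] + 0.3)],
                [yi, yi],
                color=_TYPE_COLORS.get(row["type"], "k"), lw=4,
                solid_capstyle="butt", zorder=2,
            )
    ax.set_yticks(range(len(order)), order)
    ax.invert_yaxis()
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_manhattan(mh: pd.DataFrame, threshold: float, path: str | Path) -> Path:
    """Manhattan plot of -log10 p against cumulative genome position."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(9, 3.2))
    for k, (chrom, sub) in enumerate(mh.groupby("chrom", sort=False)):
        ax.scatter(sub["cum_pos"], sub["minus_log10_p"], s=8,
                   color=["tab:blue", "tab:orange"][k % 2])
    if threshold > 0:
        ax.axhline(-np.log10(threshold), color="red", ls="--", lw=1)
    ax.set_xlabel("chromosome (cumulative position)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ticks = mh.groupby("chrom", sort=False)["cum_pos"].median()
    ax.set_xticks(ticks.to_numpy(), ticks.index)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_qq(qq: pd.DataFrame, lambda_gc: float, path: str | Path) -> Path:
    """QQ plot of observed vs expected -log10 p with the inflation factor."""
    fig, ax = plt.subplots(figsize=(3.4, 3.4))
    ax.scatter(qq["expected"], qq["observed"], s=8, color="tab:blue")
    lim = max(qq["expected"].max(), qq["observed"].max()) if len(qq) else 1.0
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.set_title(f"$\\lambda_{{GC}}$ = {lambda_gc:.3f}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
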