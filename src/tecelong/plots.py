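"""Figure helpers: stacked-bar bin compositions, waterfall traces, and
relative-rate dot plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["stacked_bars", "waterfall", "relative_rate_dots"]

_BIN_COLORS = plt.get_cmap("viridis")(np.linspace(0.05, 0.95, 7))


def stacked_bars(bin_table: pd.DataFrame, out: Path, title: str = "") -> Path:
    """One stacked bar per (condition, tfs, timepoint): replicate-mean bin
    fractions stacked bin1 (bottom) to bin7 (top)."""
    mean = (
        bin_table.groupby(["condition", "tfs", "time_s"], sort=False)[
            [f"bin{b}" for b in range(1, 8)]
        ]
        .mean()
        .reset_index()
    )
    groups = list(mean.groupby(["condition", "tfs"], sort=False))
    fig, axes = plt.subplots(
        1, len(groups), figsize=(2.2 * len(groups) + 1, 3.4),
        sharey=True, squeeze=False,
    )
    for ax, ((cond, tfs), grp) in zip(axes[0], groups):
        grp = grp.sort_values("time_s")
        x = np.arange(len(grp))
        bottom = np.zeros(len(grp))
        for b in range(7):
            vals = grp[f"bin{b+1}"].to_numpy()
            ax.bar(x, vals, bottom=bottom, color=_BIN_COLORS[b],
                   label=f"bin {b+1}" if ax is axes[0][0] else None)
            bottom += vals
        ax.set_xticks(x, [f"{t:g}" for t in grp["time_s"]], fontsize=7)
        ax.set_title(f"{cond}{' +TFS' if tfs else ''}", fontsize=8)
    axes[0][0].set_ylabel("fraction of transcripts")
    axes[0][0].legend(fontsize=6, loc="upper left")
    fig.suptitle(title)
    fig.supxlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def waterfall(
    normalized: list[np.ndarray],
    times: list[float],
    out: Path,
    title: str = "",
    offset: float = 0.02,
) -> Path:
    """Stacked lane traces (relative to starting material), one per time."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, (trace, t) in enumerate(zip(normalized, times)):
        ax.plot(trace + i * offset, lw=0.7, label=f"{t:g} s")
    ax.set_xlabel("pixel")
    ax.set_ylabel("relative intensity (offset per lane)")
    ax.legend(fontsize=7)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def relative_rate_dots(results: pd.DataFrame, out: Path, title: str = "") -> Path:
    """Relative elongation rate per condition; closed circles without TFS,
    open circles with."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    conds = list(dict.fromkeys(results["condition"]))
    for i, cond in enumerate(conds):
        for tfs, (mfc, lbl) in {0: ("k", "-TFS"), 1: ("none", "+TFS")}.items():
            sub = results[(results["condition"] == cond) & (results["tfs"] == tfs)]
            if len(sub) == 0:
                continue
            se = sub["rate_se"].to_numpy() / max(
                results[results["tfs"] == 0]["rate_nt_s"].max(), 1e-12
            )
            ax.errorbar(
                [i + (0.12 if tfs else -0.12)], sub["relative_rate"],
                yerr=se, fmt="o", mfc=mfc, color="k", capsize=2,
                label=lbl if i == 0 else None,
            )
    ax.set_xticks(range(len(conds)), conds, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("rate relative to histone-free")
    ax.axhline(1.0, color="grey", lw=0.5, ls="--")
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)
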