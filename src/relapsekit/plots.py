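"""Report figures: region contrasts, risk parameters, and the craving correlation."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

GROUP_ORDER = ("abstainer", "relapser")


def _group_box(ax, table: pd.DataFrame, col: str, title: str) -> None:
    data = [table.loc[table["group"] == g, col].dropna() for g in GROUP_ORDER]
    ax.boxplot(data, tick_labels=GROUP_ORDER)
    ax.set_title(title)


def write_report_figures(table: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write the three group-comparison figures as PNGs; returns the paths."""
    outdir = Path(outdir)
    written = []

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5), constrained_layout=True)
    for ax, region in zip(axes, ("frontopolar", "left_frontotemporal",
                                 "right_frontotemporal")):
        col = f"contrast_{region}"
        if col in table:
            _group_box(ax, table, col, region.replace("_", " "))
            ax.set_ylabel("integral oxy-Hb contrast")
    p = outdir / "region_contrasts.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(7, 3.5), constrained_layout=True)
    for ax, col, label in zip(axes, ("lambda", "gamma"), ("λ", "γ")):
        if col in table:
            _group_box(ax, table, col, label)
    p = outdir / "risk_params.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if {"contrast_right_frontotemporal", "arrs_sv"} <= set(table.columns):
        fig, ax = plt.subplots(figsize=(4.5, 3.5), constrained_layout=True)
        for g, marker in zip(GROUP_ORDER, ("o", "s")):
            sub = table[table["group"] == g]
            ax.scatter(sub["contrast_right_frontotemporal"], sub["arrs_sv"],
                       marker=marker, label=g, alpha=0.8)
        ax.set_xlabel("right FT contrast (integral oxy-Hb)")
        ax.set_ylabel("ARRS-SV")
        ax.legend()
        p = outdir / "arrs_correlation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
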