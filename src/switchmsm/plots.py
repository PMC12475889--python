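"""Figures: stratified Nelson-Aalen curves with at-risk tables, and
rejection-rate panels across the scenario grid.

Both plot functions consume the tidy CSV frames the pipeline stages emit,
so a figure can always be traced back to the data it renders.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_CURVE_COLORS = {
    "td_starter_failure": "tab:red",
    "switched_to_td_failure": "tab:blue",
    "cd_failure_censored_at_switch": "tab:orange",
    "cd_starter_failure": "tab:orange",
    "switched_to_cd_failure": "tab:cyan",
    "switch_cd_to_td": "lightblue",
    "switch_td_to_cd": "navajowhite",
}


def plot_transition_curves(
    curve_frame: pd.DataFrame,
    out_path: str | Path,
    *,
    at_risk_table: pd.DataFrame | None = None,
    title: str = "",
) -> Path:
    """Step plot of all cumulative transition-hazard curves.

    ``curve_frame`` is the long-format table from
    :meth:`TransitionCurveSet.curve_frame`; an optional at-risk table is
    printed beneath the axes at a coarse time grid.
    """
    fig, ax = plt.subplots(figsize=(8, 5.5))
    for label, grp in curve_frame.groupby("curve"):
        t = np.concatenate([[0.0], grp["time"].to_numpy()])
        a = np.concatenate([[0.0], grp["cumulative"].to_numpy()])
        ax.step(t, a, where="post", label=label, color=_CURVE_COLORS.get(label))
    ax.set_xlabel("time (years)")
    ax.set_ylabel("cumulative hazard")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    if at_risk_table is not None and len(at_risk_table):
        idx = np.linspace(0, len(at_risk_table) - 1, min(5, len(at_risk_table))).astype(int)
        sub = at_risk_table.iloc[idx]
        lines = ["at risk (t: total): " + "  ".join(
            f"{row.time:.1f}: {int(row.total)}" for row in sub.itertuples()
        )]
        fig.text(0.1, 0.0, "\n".join(lines), fontsize=8, va="bottom")
        fig.subplots_adjust(bottom=0.18)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_rejection_panels(
    results: pd.DataFrame,
    out_path: str | Path,
    *,
    approach: str | None = None,
    restart: bool | None = None,
    alpha: float = 0.05,
) -> Path:
    """Panel grid of empirical type-1-error by Weibull shape.

    One panel per (switching proportion, switching time) combination,
    rejection proportion against hazard shape with the nominal level and
    a 3-Monte-Carlo-SE band marked.  ``approach``/``restart`` filter the
    results table when it holds several variants.
    """
    df = results.copy()
    if approach is not None:
        df = df[df["approach"] == approach]
    if restart is not None:
        df = df[df["restart"] == restart]
    if df.empty:
        raise ValueError("no rows to plot after filtering")
    props = sorted(df["switch_prop"].unique())
    times = sorted(df["switch_time"].unique())
    fig, axes = plt.subplots(
        len(props), len(times), figsize=(4 * len(times), 3 * len(props)),
        squeeze=False, sharey=True,
    )
    for i, prop in enumerate(props):
        for j, st in enumerate(times):
            ax = axes[i][j]
            sub = df[(df["switch_prop"] == prop) & (df["switch_time"] == st)].sort_values("shape")
            ax.errorbar(
                sub["shape"], sub["rejection_prop"], yerr=3 * sub["mc_se"],
                marker="o", linestyle="-", capsize=3,
            )
            ax.axhline(alpha, color="grey", linestyle="--", linewidth=1)
            ax.set_title(f"switch {prop:.0%} at {st:g}y", fontsize=9)
            if i == len(props) - 1:
                ax.set_xlabel("Weibull shape")
            if j == 0:
                ax.set_ylabel("rejection proportion")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
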