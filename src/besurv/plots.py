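"""Simple figures: cost-effectiveness plane, acceptability curves, tornado."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def ce_plane_plot(plane: pd.DataFrame, wtp: float, ax=None):
    """Scatter of incremental cost vs incremental QALYs, one colour per
    strategy, with the willingness-to-pay line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for strat, sub in plane.groupby("strategy"):
        ax.scatter(sub["delta_qaly"], sub["delta_cost"], s=4, alpha=0.4, label=strat)
    qlim = max(abs(plane["delta_qaly"]).max(), 1e-6)
    ax.plot([-qlim, qlim], [-qlim * wtp, qlim * wtp], "k--", lw=1,
            label=f"λ = {wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (AUD)")
    ax.legend(fontsize=7)
    return ax


def ceac_plot(curves: pd.DataFrame, ax=None):
    """Probability each strategy is optimal as a function of λ."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in curves.columns:
        ax.plot(curves.index, curves[col], label=col)
    ax.set_xlabel("Willingness-to-pay (AUD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    return ax


def tornado_plot(entries: pd.DataFrame, base_icer: float, ax=None):
    """Horizontal-bar tornado of one-way ICER swings (largest on top)."""
    df = entries.dropna(subset=["swing"]).sort_values("swing")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * max(len(df), 4) + 1))
    for i, row in enumerate(df.itertuples()):
        lo = row.icer_at_low if isinstance(row.icer_at_low, (int, float)) else base_icer
        hi = row.icer_at_high if isinstance(row.icer_at_high, (int, float)) else base_icer
        ax.barh(i, hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["parameter_name"], fontsize=7)
    ax.set_xlabel("ICER (AUD/QALY)")
    return ax
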