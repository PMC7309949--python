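"""Plots for sensitivity-analysis outputs.

Each function draws on a provided matplotlib Axes (or a fresh one) and
returns it, so figures compose with user styling and save however the
caller prefers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sensitivity import PSAResult

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_ce_plane(result: PSAResult, wtp: float | None = 5_000_000, ax=None):
    """Incremental cost vs incremental QALY cloud, one point per PSA draw."""
    ax = _axes(ax)
    ax.scatter(result.delta_qaly, result.delta_cost, s=4, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    if wtp is not None:
        q = np.array(ax.get_xlim())
        ax.plot(q, wtp * q, color="crimson", lw=1.0, label=f"WTP {wtp:,.0f} yen/QALY")
        ax.legend(frameon=False)
    ax.set_xlabel("Incremental QALYs (TAI - SBC)")
    ax.set_ylabel("Incremental cost (yen)")
    ax.set_title("Cost-effectiveness plane")
    return ax


def plot_ceac(curve: pd.DataFrame, ax=None):
    """Probability cost-effective against willingness to pay."""
    ax = _axes(ax)
    ax.plot(curve["wtp"] / 1e6, curve["prob_cost_effective"])
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (million yen/QALY)")
    ax.set_ylabel("P(TAI cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    return ax


def plot_tornado(table: pd.DataFrame, top: int = 12, base_icer: float | None = None, ax=None):
    """Horizontal ICER ranges for the most influential parameters.

    Infinite sides (dominated directions) are drawn clipped to the plot
    edge; the bar annotation marks them.
    """
    ax = _axes(ax)
    sub = table.head(top).iloc[::-1]
    finite = np.concatenate(
        [sub["icer_low"].to_numpy(float), sub["icer_high"].to_numpy(float)]
    )
    finite = finite[np.isfinite(finite)]
    hi_clip = finite.max() * 1.1 if finite.size else 1.0
    lo_clip = min(0.0, finite.min() * 1.1) if finite.size else 0.0
    for y, (_, row) in enumerate(sub.iterrows()):
        lo = np.clip(row["icer_low"], lo_clip, hi_clip)
        hi = np.clip(row["icer_high"], lo_clip, hi_clip)
        ax.barh(y, hi - lo, left=lo, height=0.6, color="steelblue", alpha=0.8)
        if not np.isfinite(row["icer_low"]) or not np.isfinite(row["icer_high"]):
            ax.text(hi_clip, y, " >", va="center", fontsize=8)
    ax.set_yticks(range(len(sub)))
    ax.set_yticklabels(sub["parameter"])
    if base_icer is not None:
        ax.axvline(base_icer, color="crimson", lw=1.0)
    ax.set_xlabel("ICER (yen/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    return ax
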