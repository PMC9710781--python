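"""Minimal plotting helpers: forgetting curves and condition summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_forgetting_curves", "plot_condition_summary"]


def plot_forgetting_curves(table: pd.DataFrame, ax=None):
    """Mean per-lag rho^2 (with s.d. band) per condition from a results table.

    Expects memory-capacity rows with ``metric == "rho2"`` as produced by
    :func:`bioesn.experiments.run_replicates`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curves = table[table["metric"] == "rho2"]
    for condition, sub in curves.groupby("condition"):
        agg = sub.groupby("difficulty")["score"].agg(["mean", "std"])
        ax.plot(agg.index, agg["mean"], label=condition)
        ax.fill_between(
            agg.index,
            agg["mean"] - agg["std"].fillna(0.0),
            agg["mean"] + agg["std"].fillna(0.0),
            alpha=0.2,
        )
    ax.set_xlabel(r"lag $\tau$")
    ax.set_ylabel(r"$\rho^2$")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    return ax


def plot_condition_summary(table: pd.DataFrame, metric: str = "mc", ax=None):
    """Mean aggregate score (with s.d. error bars) per condition and size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = table[table["metric"] == metric]
    for condition, grp in sub.groupby("condition"):
        agg = grp.groupby("size")["score"].agg(["mean", "std"])
        ax.errorbar(
            agg.index, agg["mean"], yerr=agg["std"].fillna(0.0),
            marker="o", capsize=3, label=condition,
        )
    ax.set_xlabel("neurons per area")
    ax.set_ylabel(metric)
    if not sub.empty and np.ptp(sub["size"].to_numpy()) > 0:
        ax.set_xscale("log", base=2)
    ax.legend()
    return ax
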