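"""Minimal plotting helpers for traces, ARCs and sweep tables."""

from __future__ import annotations

import numpy as np


def plot_trace(trace, series=None, ax=None):
    """Tracked vs true optimal phase over optimization steps."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.step, trace.psi_true, "k.", ms=2, label=r"true optimum $\psi^*$")
    ax.plot(trace.step, trace.psi_target, ".", ms=3, alpha=0.6, label="tested phase")
    ax.set(xlabel="optimization step", ylabel="phase (rad)", ylim=(-np.pi * 1.05, np.pi * 1.05))
    ax.legend(loc="upper right", fontsize=8)
    if series is not None:
        ax2 = ax.twinx()
        ax2.plot(trace.step, series.cum_regret, "r-", lw=1, label="cumulative regret")
        ax2.set_ylabel("cumulative regret", color="r")
    return ax


def plot_arc(rows, ax=None):
    """Amplitude response curve from :func:`tvbopt.arc_scan` output."""
    import matplotlib.pyplot as plt

    rows = np.asarray(rows)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(rows[:, 0], rows[:, 1], "o-")
    ax.set(xlabel=r"target phase $\psi_{target}$ (rad)", ylabel=r"$\Delta\rho$")
    return ax


def plot_sweep(df, ax=None):
    """Mean AUC per sweep value and controller from a sweep table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for mode, sub in df.groupby("mode"):
        agg = sub.groupby("sweep_value").auc.mean()
        ax.plot(agg.index, agg.values, "o-", label=mode)
    ax.set(xlabel="sweep value", ylabel="cumulative-regret AUC")
    ax.legend(fontsize=8)
    return ax
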