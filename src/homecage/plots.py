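"""Optional matplotlib views of the standard metric tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax=None):
    if ax is not None:
        return ax.figure, ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.2))
    return fig, ax


def plot_daily_intake(daily: pd.DataFrame, ax=None):
    """Mean daily fentanyl mass across mice with an SEM band."""
    fig, ax = _axes(ax)
    g = daily.groupby("day")["fentanyl_mg"]
    mean, sem = g.mean(), g.sem()
    ax.plot(mean.index, mean.values, color="purple")
    ax.fill_between(mean.index, mean - sem.fillna(0), mean + sem.fillna(0),
                    color="purple", alpha=0.25)
    ax.set_xlabel("day")
    ax.set_ylabel("fentanyl (mg)")
    return fig


def plot_hourly_visits(profile: pd.DataFrame, lights_on_hour: int = 7, ax=None):
    """Average hourly visit count with the dark phase shaded."""
    fig, ax = _axes(ax)
    g = profile.groupby("hour_rel")["visits_per_day"]
    mean, sem = g.mean(), g.sem()
    ax.plot(mean.index, mean.values, color="k")
    ax.fill_between(mean.index, mean - sem.fillna(0), mean + sem.fillna(0),
                    color="gray", alpha=0.4)
    ax.axvspan(12, 24, color="lightgray", alpha=0.5)
    ax.set_xlabel(f"hours since lights-on ({lights_on_hour}:00)")
    ax.set_ylabel("visits/hour")
    return fig


def plot_iti_hist(iti_result, ax=None):
    """Inter-trial-interval histogram on a log x-axis, median marked."""
    fig, ax = _axes(ax)
    if iti_result.itis.size:
        ax.hist(iti_result.itis, bins=iti_result.bin_edges, color="steelblue")
        ax.axvline(iti_result.median, color="k", linestyle="--")
        ax.set_xscale("log")
    ax.set_xlabel("inter-trial interval (s)")
    ax.set_ylabel("trials")
    return fig


def plot_bout_cdf(curves: dict[str, tuple[np.ndarray, np.ndarray]], ax=None):
    """Cumulative consumption by bout size, one curve per labelled group."""
    fig, ax = _axes(ax)
    for label, (xs, cdf) in curves.items():
        if len(xs):
            ax.step(xs, cdf, where="post", label=label)
    ax.set_xlabel("bout size (rewards/visit)")
    ax.set_ylabel("cumulative fraction of rewards")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    return fig


def plot_pokes_hist(prob: pd.Series, fr: int, ax=None):
    """Pokes-per-trial probability histogram; reward multiples highlighted."""
    fig, ax = _axes(ax)
    if len(prob):
        colors = ["firebrick" if k % fr == 0 else "gray" for k in prob.index]
        ax.bar(prob.index, prob.values, color=colors)
    ax.set_xlabel(f"pokes per trial (FR{fr})")
    ax.set_ylabel("probability")
    return fig
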