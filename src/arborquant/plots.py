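"""Plotting helpers: directionality profiles, rose plots, habituation curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .behavior import FreezeBout  # noqa: F401  (re-export convenience)
from .branchmetrics import RoseHistogram
from .orientation import NormalizedProfile, OrientationProfile


def plot_profile(profile, ax=None, label=None, color=None):
    """Line plot of a directionality profile with its CI band if present."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    if isinstance(profile, NormalizedProfile):
        y, ylabel = profile.percent_per_bin, "% of total signal"
    else:
        y, ylabel = profile.signal_per_bin, "signal (a.u.)"
    x = profile.bin_centers_deg
    ax.plot(x, y, label=label, color=color, lw=1.0)
    if isinstance(profile, OrientationProfile) and profile.ci95 is not None:
        ax.fill_between(x, y - profile.ci95, y + profile.ci95, alpha=0.25,
                        color=color, lw=0)
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel(ylabel)
    ax.set_xlim(-90, 90)
    if label:
        ax.legend(frameon=False)
    return ax


def plot_rose(rose: RoseHistogram, ax=None):
    """Polar sector histogram of growth directions."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    widths = np.deg2rad(np.diff(rose.sector_edges_deg))
    theta = np.deg2rad(rose.sector_edges_deg[:-1]) + widths / 2
    ax.bar(theta, rose.counts, width=widths, align="center",
           edgecolor="k", lw=0.4, alpha=0.8)
    ax.set_theta_zero_location("E")
    return ax


def plot_habituation(curves, metric: str = "pct_froze", ax=None):
    """Per-exposure group curves with SEM error bars where available."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for g, sub in curves.groupby("group"):
        sub = sub.sort_values("exposure")
        yerr = sub.get(f"sem_{metric}")
        ax.errorbar(sub["exposure"], sub[metric],
                    yerr=None if yerr is None else yerr.to_numpy(),
                    marker="o", capsize=3, label=str(g))
    ax.set_xlabel("exposure")
    ax.set_ylabel(metric)
    ax.legend(frameon=False)
    return ax
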