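"""Headless-safe figures for the report bundle."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .decision import DecisionCurve  # noqa: E402
from .profiling import KINDS  # noqa: E402


def decision_curve_plot(curve: DecisionCurve):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.nb_model, label="model", lw=1.5)
    ax.plot(curve.thresholds, curve.nb_all, label="treat all", ls="--")
    ax.plot(curve.thresholds, curve.nb_none, label="treat none", ls=":")
    ax.set_ylim(-0.05, max(curve.prevalence * 1.3, 0.05))
    ax.set_xlabel("threshold probability (cost:benefit = t/(1−t))")
    ax.set_ylabel("net benefit")
    ax.legend()
    fig.tight_layout()
    return fig


def facility_rate_histograms(profiles: pd.DataFrame):
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, kind in zip(axes, KINDS):
        ax.hist(profiles[f"{kind}_rate"] * 100, bins=30, color="steelblue")
        ax.set_xlabel(f"{kind}-utilization rate (%)")
        ax.set_ylabel("facilities")
    fig.tight_layout()
    return fig


def bubble_plot(bubbles: pd.DataFrame, kind: str):
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(bubbles):
        ax.scatter(bubbles["actual"], bubbles["expected"],
                   s=20 * bubbles["log_volume"], alpha=0.5)
        lim = max(bubbles["actual"].max(), bubbles["expected"].max()) * 1.05
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel(f"actual {kind}-utilization count")
    ax.set_ylabel("expected count")
    fig.tight_layout()
    return fig


def forest_plot(forest: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(forest) + 1.5))
    ypos = np.arange(len(forest))[::-1]
    for y, (_, row) in zip(ypos, forest.iterrows()):
        if row["reference"]:
            ax.plot(0, y, marker="s", color="black")
        else:
            ax.plot(row["log_or"], y, marker="o", color="steelblue")
            if np.isfinite(row["lo"]):
                ax.plot([row["lo"], row["hi"]], [y, y], color="steelblue")
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(forest["outcome_kind"] + ": " + forest["level"])
    ax.set_xlabel("log odds ratio")
    fig.tight_layout()
    return fig


def volume_back_to_back(profiles: pd.DataFrame, flagged_ids):
    """Two-sided histogram of log volume: all facilities (up) vs flagged
    (down)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    logv = np.log(profiles["volume"].to_numpy(dtype=float))
    bins = np.histogram_bin_edges(logv, bins=30)
    all_c, _ = np.histogram(logv, bins=bins)
    fl = profiles["facility_id"].isin(flagged_ids)
    fl_c, _ = np.histogram(logv[fl.to_numpy()], bins=bins)
    centers = 0.5 * (bins[:-1] + bins[1:])
    width = bins[1] - bins[0]
    ax.bar(centers, all_c, width=width, color="steelblue", label="all facilities")
    ax.bar(centers, -fl_c, width=width, color="indianred", label="flagged (p < 0.01)")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("log(volume)")
    ax.set_ylabel("facilities")
    ax.legend()
    fig.tight_layout()
    return fig


def under_over_bubble(profiles: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(5.5, 5))
    logv = np.log(profiles["volume"].to_numpy(dtype=float))
    ax.scatter(profiles["over_rate"] * 100, profiles["under_rate"] * 100,
               s=10 * logv, alpha=0.4)
    ax.set_xlabel("over-utilization rate (%)")
    ax.set_ylabel("under-utilization rate (%)")
    fig.tight_layout()
    return fig
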