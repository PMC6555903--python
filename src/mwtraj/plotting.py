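"""Figure builders for the binned series and the 2D trajectory."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .trajectory import BinnedSeries, MWProbabilityResult, Trajectory
import pandas as pd


def fig_mw_probability(result: MWProbabilityResult):
    """Per-bin probability of a mind-wandering report, with SD error bars."""
    fig, ax = plt.subplots(figsize=(7, 4))
    bins = list(result.grand_average.index)
    ax.errorbar(bins, result.grand_average, yerr=result.sd, fmt="o-", capsize=3)
    ax.set_xlabel("time bin (h relative to mind-wandering report)")
    ax.set_ylabel("P(mind wandering)")
    ax.set_xticks(bins)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    fig.tight_layout()
    return fig


def fig_percentile_series(percentiles: pd.Series, label: str):
    """Percentile of a binned grand average over time bins."""
    fig, ax = plt.subplots(figsize=(7, 4))
    bins = list(percentiles.index)
    ax.plot(bins, percentiles, "o-")
    ax.axhline(50, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("time bin (h relative to mind-wandering report)")
    ax.set_ylabel(f"percentile of {label}")
    ax.set_ylim(-2, 102)
    ax.set_xticks(bins)
    fig.tight_layout()
    return fig


def fig_trajectory(traj: Trajectory):
    """2D trajectory: control (R) percentile vs thought-generation (NoT)
    percentile, point per bin, disk radius showing inter-individual
    variability."""
    fig, ax = plt.subplots(figsize=(6, 6))
    pts = traj.complete_points
    pre = pts[pts.index <= 0]
    post = pts[pts.index >= 0]
    ax.plot(pre["r_pct"], pre["not_pct"], "-", color="tab:blue", label="before MW")
    ax.plot(post["r_pct"], post["not_pct"], "-", color="tab:orange", label="after MW")
    radii = pts["radius"].to_numpy(dtype=float)
    sizes = np.where(np.isfinite(radii), radii, 0.0)
    ax.scatter(pts["r_pct"], pts["not_pct"], s=20 + 15 * sizes, alpha=0.45, color="tab:grey")
    for b, row in pts.iterrows():
        ax.annotate(str(b), (row["r_pct"], row["not_pct"]), fontsize=8,
                    textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel(f"R-score percentile ({traj.r_measure})  [cognitive control]")
    ax.set_ylabel(f"NoT percentile ({traj.not_measure})  [thought generation]")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    return fig


def fig_binned_counts(binned: BinnedSeries, label: str):
    fig, ax = plt.subplots(figsize=(7, 3))
    bins = list(binned.n_participants.index)
    ax.bar(bins, binned.n_participants)
    ax.set_xlabel("time bin")
    ax.set_ylabel(f"participants with data ({label})")
    ax.set_xticks(bins)
    fig.tight_layout()
    return fig
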