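"""Figure-style plots of the analysis outputs (targeted ratings, condition
surface, experience groups).  All functions return the matplotlib Figure and
optionally save a PNG."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import Target, add_target_column


def plot_targeted_ratings(trials: pd.DataFrame, summaries: pd.DataFrame, path=None):
    """Per-participant mean ratings on triple- vs quadruple-targeted trials."""
    per = (
        add_target_column(trials)
        .groupby(["participant", "target"])["rating"]
        .mean()
        .unstack("target")
    )
    switch = summaries.set_index("participant")["is_switcher"]
    fig, ax = plt.subplots(figsize=(4, 4))
    for pid, row in per.iterrows():
        color = "k" if switch.get(pid, True) else "0.6"
        ax.plot(
            [0, 1],
            [row[Target.TRIPLE_TARGETED.value], row[Target.QUADRUPLE_TARGETED.value]],
            "o-",
            color=color,
            alpha=0.6,
        )
    ax.set_xticks([0, 1], ["triple-targeted", "quadruple-targeted"])
    ax.set_ylabel("mean rating (1=triple ... 5=quadruple)")
    ax.set_ylim(0.8, 5.2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_condition_surface(diffs: pd.DataFrame, path=None):
    """Mean rating difference per grid condition as lines and a color map."""
    surface = (
        diffs.groupby(["freq_diff", "dur_diff"])["difference"].mean().unstack("dur_diff")
    )
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    for f, row in surface.iterrows():
        ax1.plot(row.index, row.to_numpy(), "o-", label=f"F{f:g}")
    ax1.set_xlabel("duration difference (ms)")
    ax1.set_ylabel("rating difference (points)")
    ax1.legend(fontsize=7)
    im = ax2.imshow(surface.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax2.set_xticks(range(surface.shape[1]), [f"D{d:g}" for d in surface.columns])
    ax2.set_yticks(range(surface.shape[0]), [f"F{f:g}" for f in surface.index])
    fig.colorbar(im, ax=ax2, label="rating difference")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_group_differences(summaries: pd.DataFrame, path=None):
    """Per-participant overall differences grouped by prior experience."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = 0
    for group, sub in summaries.groupby("group", sort=True):
        xs = np.arange(x, x + len(sub))
        ax.bar(
            xs,
            sub["overall_difference"],
            yerr=sub["se_conditions"],
            color="0.4",
            capsize=2,
        )
        ax.text(xs.mean(), -0.4, group, ha="center", fontsize=8)
        x += len(sub) + 1
    ax.set_ylabel("rating difference (points)")
    ax.set_xticks([])
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
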