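"""Summary figures: model-correlation bars with a noise-ceiling band, the
accuracy-versus-increment curve, and the conflict-proportion histogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_model_correlations(results: dict, ceiling=None, path=None):
    """Bar plot of per-model r with bootstrap-SE error bars.

    ``results`` maps model name -> CorrelationResult; ``ceiling`` is an
    optional NoiseCeiling drawn as a horizontal band of width 2 SE.
    """
    names = list(results)
    rs = [results[n].r for n in names]
    ses = [results[n].se for n in names]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 1.5, 3.2))
    ax.bar(names, rs, yerr=ses, color="#5a7db8", capsize=3)
    if ceiling is not None:
        ax.axhspan(
            ceiling.mean_r - ceiling.se,
            ceiling.mean_r + ceiling.se,
            color="0.3",
            alpha=0.5,
            label="noise ceiling",
        )
        ax.legend(frameon=False)
    ax.set_ylabel("correlation with judgments (r)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_increment_accuracy(jt: pd.DataFrame, path=None):
    """Mean same-trial accuracy per skeletal increment with +-1 SE bars."""
    same = jt[jt["trial_type"] == "same"]
    per = same.groupby(["participant_id", "increment"])["correct"].mean().reset_index()
    g = per.groupby("increment")["correct"]
    mean, se = g.mean(), g.std(ddof=1) / np.sqrt(g.size())
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.errorbar(mean.index * 100, mean, yerr=se, marker="o", color="#5a7db8")
    ax.axhline(0.5, ls=":", color="0.4")
    ax.set_xlabel("skeletal change (%)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.4, 1.0)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_conflict_histogram(per_participant: pd.DataFrame, path=None):
    """Histogram of per-participant skeleton-choice proportions (conflict)."""
    vals = per_participant["conflict_skeleton_proportion"]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.hist(vals, bins=np.linspace(0, 1, 21), color="#5a7db8")
    ax.axvline(0.5, ls=":", color="0.4")
    ax.set_xlabel("proportion of skeleton choices")
    ax.set_ylabel("participants")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
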