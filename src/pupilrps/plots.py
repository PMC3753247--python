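"""Matplotlib views of a study report: group performance bars and
per-player cumulative-win learning curves against the exact-binomial
significance boundary."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .experiment import StudyReport  # noqa: E402
from .stats import CHANCE, significance_boundary  # noqa: E402

__all__ = ["plot_group_performance", "plot_learning_curves"]


def plot_group_performance(report: StudyReport, path=None):
    """Mean win percentage per condition (bars) with individual players
    (circles), chance and decoder-ceiling reference lines."""
    names = list(report.conditions)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, name in enumerate(names):
        r = report.conditions[name]
        ax.bar(i, r.group_mean_pct, color="0.75", edgecolor="black", zorder=1)
        pct = 100.0 * r.win_fractions
        ax.scatter(np.full(pct.size, i) + np.linspace(-0.15, 0.15, pct.size),
                   pct, facecolors="none", edgecolors="black", zorder=2)
    ax.axhline(100 * CHANCE, ls="--", color="red", lw=1, label="chance (33%)")
    ax.axhline(report.fixture_validity_pct, ls="--", color="blue", lw=1,
               label="decoder ceiling")
    ax.set_xticks(range(len(names)), names, rotation=20, ha="right")
    ax.set_ylabel("games won (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_learning_curves(report: StudyReport, path=None):
    """Cumulative wins per player and condition; red line: chance; green
    line: 5% exact-binomial significance boundary at each game count."""
    names = list(report.conditions)
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 3),
                             sharey=False)
    for ax, name in zip(np.atleast_1d(axes), names):
        r = report.conditions[name]
        n = r.sessions[0].n_games
        for s in r.sessions:
            ax.plot(np.arange(1, n + 1), s.cumulative_wins, color="black",
                    lw=0.8, alpha=0.7)
        ns = np.arange(1, n + 1)
        ax.plot(ns, ns * CHANCE, color="red", lw=1)
        b = significance_boundary(n, alpha=0.05)
        k = b.k_min.astype(float)
        k[k < 0] = np.nan
        ax.plot(ns, k, color="green", lw=1)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("game")
    np.atleast_1d(axes)[0].set_ylabel("cumulative wins")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
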