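"""Summary figures: influence-trajectory bands and paired effect bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import TrajectoryEstimate

__all__ = ["plot_trajectory", "plot_effect_bars"]


def plot_trajectory(traj: TrajectoryEstimate, path, title: str = "") -> None:
    """Posterior mean and 95% band of the influence function L(y)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(traj.grid, traj.q025_L, traj.q975_L, alpha=0.3, color="tab:red")
    ax.plot(traj.grid, traj.mean_L, color="tab:red", lw=1.5)
    ax.axhline(0.0, ls=":", color="k", lw=0.8)
    ax.set_xlabel("phenological trait (centered days)")
    ax.set_ylabel("influence L(y) (cm/day)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_effect_bars(effects_a, effects_b, labels, path,
                     names=("model A", "model B")) -> None:
    """Paired bars comparing one effect vector across two fits."""
    x = np.arange(len(labels))
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(labels)), 3.5))
    ax.bar(x - 0.2, effects_a, width=0.4, color="tab:red", label=names[0])
    ax.bar(x + 0.2, effects_b, width=0.4, color="gray", label=names[1])
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(x, labels, rotation=60, ha="right", fontsize=7)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
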