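"""Figure helpers for the ensemble experiments (Agg backend, file output)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import Trajectory
from .universality import EnsembleResult

_COLORS = {"s": "tab:blue", "e": "tab:orange", "i": "tab:red", "r": "tab:green"}


def plot_collapse(
    raw: Sequence[Trajectory],
    scaled: Sequence[Trajectory],
    path,
    compartments: str = "seir",
) -> None:
    """Two panels: ensemble curves vs time and vs alpha*gamma*t."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, trajs, xlabel in (
        (axes[0], raw, "time (days)"),
        (axes[1], scaled, r"time scaled by $\alpha\gamma$"),
    ):
        for tr in trajs:
            for c in compartments:
                ax.plot(tr.times, tr.compartment(c), color=_COLORS[c],
                        alpha=0.15, lw=0.7)
        ax.set_xlabel(xlabel)
    axes[0].set_ylabel("population fraction")
    for c in compartments:
        axes[1].plot([], [], color=_COLORS[c], label=c.upper())
    axes[1].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_peak_curve(results: Sequence[EnsembleResult], path) -> None:
    """Scaled and unscaled peak times against r0, one marker set per result."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for res in results:
        d = res.draws[res.draws.delta_t > 0]
        label = f"$I_0$={res.spec.i0:g}" if res.spec else None
        axes[0].scatter(d.r0, d.delta_t / d.d_inf, s=3, alpha=0.25, label=label)
        axes[1].scatter(d.r0, d.scaled_delta_t, s=3, alpha=0.25, label=label)
    axes[0].set_ylabel(r"$\gamma\,\Delta t$")
    axes[1].set_ylabel(r"$\alpha\gamma\,\Delta t$")
    for ax in axes:
        ax.set_xlabel(r"basic reproduction number $\mathcal{R}_0$")
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
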