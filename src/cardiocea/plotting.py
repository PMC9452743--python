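"""Small matplotlib helpers: trace area chart, tornado bars, grid heat table."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .markov import CohortTrace, State

__all__ = ["plot_trace", "plot_tornado", "plot_grid"]

_CATEGORY_COLORS = {"green": "#2e8b57", "yellow": "#e6c229", "gray": "#9e9e9e"}


def plot_trace(trace: CohortTrace, title: str = "Cohort state occupancy"):
    """Stacked area chart of state occupancy by attained age."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ages = trace.start_age + np.arange(trace.n_cycles + 1)
    ax.stackplot(
        ages,
        [trace.occupancy[:, s] for s in State],
        labels=[s.name.replace("_", " ").title() for s in State],
    )
    ax.set_xlabel("Attained age (years)")
    ax.set_ylabel("State occupancy")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(loc="center left", fontsize=8)
    return fig


def plot_tornado(entries, base_icer: float | None = None):
    """Horizontal bars of the ICER range per parameter, widest on top."""
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(entries) + 1.5))
    names = [e.parameter for e in entries][::-1]
    for i, e in enumerate(reversed(entries)):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    if base_icer is not None:
        ax.axvline(base_icer, color="k", lw=1, ls="--", label="base ICER")
        ax.legend(fontsize=8)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("ICER ($/QALY)")
    ax.set_title("One-way sensitivity")
    return fig


def plot_grid(grid, proton_cost: float, wtp: float):
    """Colour table of threshold doses (age x risk multiplier) at one cost/WTP."""
    fig, axes = plt.subplots(1, len(grid.ages), figsize=(3 * len(grid.ages), 4), squeeze=False)
    for ax, age in zip(axes[0], grid.ages):
        for j, m in enumerate(grid.multipliers):
            thr, cat = grid.cells[(age, m, proton_cost, wtp)]
            ax.add_patch(plt.Rectangle((0, j), 1, 1, color=_CATEGORY_COLORS[cat]))
            ax.text(0.5, j + 0.5, "-" if thr is None else str(thr), ha="center", va="center")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, len(grid.multipliers))
        ax.set_xticks([])
        ax.set_yticks([j + 0.5 for j in range(len(grid.multipliers))], [f"{m:g}x" for m in grid.multipliers])
        ax.set_title(f"{age}-year-old")
        ax.set_ylabel("Preexisting risk multiplier" if age == grid.ages[0] else "")
    fig.suptitle(f"Minimum cost-effective photon MHD (proton ${proton_cost:,.0f}, WTP ${wtp:,.0f}/QALY)")
    return fig
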