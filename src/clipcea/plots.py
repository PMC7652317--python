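"""Cost-effectiveness plane and CEAC figures (matplotlib)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sensitivity import BootstrapReplicates, confidence_ellipse

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(replicates: BootstrapReplicates, wtp: float = 50_000.0,
                  level: float = 0.95):
    """Replicate scatter on the CE plane with the confidence ellipse.

    The dashed line is the willingness-to-pay threshold; points below it
    have positive net monetary benefit.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(replicates.delta_qaly, replicates.delta_cost, s=8, alpha=0.5,
               label=f"{replicates.n_iter} replicates")
    ell = confidence_ellipse(replicates, level=level)
    if not ell.degenerate:
        theta = np.linspace(0, 2 * np.pi, 200)
        circ = np.column_stack([np.cos(theta), np.sin(theta)]) * ell.radii
        xy = circ @ ell.axes.T + ell.center
        ax.plot(xy[:, 1], xy[:, 0], "r-", lw=1,
                label=f"{level:.0%} ellipse")
    q = np.linspace(*ax.get_xlim(), 50)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP €{wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (€)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def plot_ceac(curve, wtp: float = 50_000.0):
    """Cost-effectiveness acceptability curve with the WTP threshold marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability"], lw=1.5)
    ax.axvline(wtp, color="grey", ls="--", lw=1)
    ax.set_xlabel("willingness-to-pay (€/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    return fig
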