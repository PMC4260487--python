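"""Boundary / RT-distribution panel figures.

One figure per model comparison: the recovered boundaries on the left
(solid for the point-wise phase, broken for the piecewise-refined tail) and
the choice-probability-weighted RT distributions for the two alternatives
on the right (target as a line, achieved as a filled step histogram), with
the choice probabilities annotated.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .types import BoundaryPair, ChoiceRTDistribution

__all__ = ["plot_panels"]


def plot_panels(
    bounds: BoundaryPair,
    achieved: ChoiceRTDistribution,
    target: ChoiceRTDistribution | None,
    path,
    main_until: int | None = None,
    title: str = "",
) -> None:
    """Render the boundary/RT panel figure to ``path`` (best effort)."""
    fig = plt.figure(figsize=(9, 4))
    gs = fig.add_gridspec(2, 2, width_ratios=[2, 1])
    ax_b = fig.add_subplot(gs[:, 0])
    ax_u = fig.add_subplot(gs[0, 1])
    ax_l = fig.add_subplot(gs[1, 1], sharex=ax_u)

    t = np.concatenate(([0.0], bounds.times))
    up = np.concatenate(([bounds.start_upper], bounds.upper))
    lo = np.concatenate(([bounds.start_lower], bounds.lower))
    m = bounds.n_steps if main_until is None else int(main_until)
    ax_b.plot(t[: m + 1], up[: m + 1], "k-", lw=1.5)
    ax_b.plot(t[: m + 1], lo[: m + 1], "k-", lw=1.5)
    if m < bounds.n_steps:
        ax_b.plot(t[m:], up[m:], "k--", lw=1.2)
        ax_b.plot(t[m:], lo[m:], "k--", lw=1.2)
    ax_b.axhline(0.0, color="0.8", lw=0.6)
    ax_b.set_xlabel("time (s)")
    ax_b.set_ylabel("evidence")
    if title:
        ax_b.set_title(title)

    for ax, side, label in ((ax_u, "upper", "A"), (ax_l, "lower", "B")):
        pmf = achieved.pmf_upper if side == "upper" else achieved.pmf_lower
        ax.fill_between(achieved.times, pmf, step="mid", color="0.7")
        p_show = pmf.sum()
        if target is not None:
            tp = target.pmf_upper if side == "upper" else target.pmf_lower
            ax.plot(target.times, tp, "k-", lw=1.0)
        ax.annotate(f"{p_show:.2f}", xy=(0.97, 0.85), xycoords="axes fraction", ha="right", fontsize=9)
        ax.set_ylabel(label, rotation=0, labelpad=10)
    ax_l.set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
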