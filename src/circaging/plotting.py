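"""Forest-plot rendering of association results."""

from __future__ import annotations

from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .associate import AssociationResult


def forest_plot(results: Iterable[AssociationResult], path, title: str | None = None):
    """Render beta coefficients with 95% CIs, one row per circRNA.

    Not-detected rows are skipped.  Writes SVG/PNG depending on the path
    suffix and returns the matplotlib figure.
    """
    rows = [r for r in results if r.detected]
    if not rows:
        raise ValueError("no detected results to plot")
    rows = sorted(rows, key=lambda r: r.circ_id, reverse=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    ys = range(len(rows))
    for y, r in zip(ys, rows):
        color = "firebrick" if r.significant_adjusted else "steelblue"
        ax.errorbar(
            r.beta,
            y,
            xerr=[[r.beta - r.ci_low], [r.ci_high - r.beta]],
            fmt="o",
            color=color,
            capsize=3,
        )
    ax.axvline(0.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_yticks(list(ys))
    ax.set_yticklabels([r.circ_id for r in rows])
    ax.set_xlabel("beta coefficient (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fig
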