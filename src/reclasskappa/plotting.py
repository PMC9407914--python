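"""Graphical decomposition of the chance-corrected reclassification count.

The bar chart contrasts, separately for disease-free subjects reclassified
down and diseased subjects reclassified up, the observed count with the
count expected under purely random reclassification; the hatched excess is
the x statistic (O - E), the number of people genuinely better classified
by the added marker.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import ReclassResult

__all__ = ["plot_reclassification"]


def plot_reclassification(result: ReclassResult, path=None, ax=None):
    """Observed-vs-expected bar decomposition of correct reclassifications.

    Saves to ``path`` (PNG/SVG inferred from the extension) when given;
    returns the matplotlib Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6.5, 4.0))
    obs, exp = result.observed, result.expected
    groups = [
        ("disease-free\nreclassified down", obs.a, exp.a),
        ("diseased\nreclassified up", obs.f, exp.f),
        ("all correct\nreclassifications", obs.a + obs.f, exp.a + exp.f),
    ]
    xs = range(len(groups))
    width = 0.38
    ax.bar(
        [x - width / 2 for x in xs], [g[1] for g in groups], width,
        label="observed", color="#3b6ea5",
    )
    ax.bar(
        [x + width / 2 for x in xs], [g[2] for g in groups], width,
        label="expected by chance", color="#c0c6cf", hatch="//",
    )
    for x, (_, o, e) in zip(xs, groups):
        ax.annotate(f"{o - e:+.1f}", (x, max(o, e)), textcoords="offset points",
                    xytext=(0, 4), ha="center", fontsize=9)
    ax.set_xticks(list(xs))
    ax.set_xticklabels([g[0] for g in groups])
    ax.set_ylabel("subjects")
    ax.set_title(
        f"x = {result.x} of n = {result.n} "
        f"({100 * result.x / result.n:.1f}%), kappa = {result.kappa:.2f}"
    )
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
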