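"""Control-chart rendering (Q vs T^2 scatter with dashed confidence limits)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_control_chart(chart, t2_limit: float, q_limit: float, path=None,
                       hue: str | None = "condition", ax=None):
    """Scatter each sample at (T^2, Q) with dashed limits.

    ``chart`` is a conformance table with ``t2`` and ``q`` columns; points
    are colored by the ``hue`` column when present.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if hue and hue in chart.columns:
        for key, grp in chart.groupby(hue, dropna=False):
            ax.scatter(grp["t2"], grp["q"], s=22, label=str(key), alpha=0.8)
        ax.legend(title=hue, fontsize=8)
    else:
        ax.scatter(chart["t2"], chart["q"], s=22, alpha=0.8)
    ax.axvline(t2_limit, ls="--", c="k", lw=1)
    ax.axhline(q_limit, ls="--", c="k", lw=1)
    ax.set_xlabel("Hotelling's $T^2$")
    ax.set_ylabel("Q (squared prediction error)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
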