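"""Bar-plot rendering of percent-change effect tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_effects"]


def plot_effects(effects: pd.DataFrame, title: str = "", path: str | None = None):
    """Bar plot of percent-change contrasts with their confidence intervals.

    Expects the frame produced by :func:`hapticlearn.lmm.report_effects`.
    """
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(effects)), 4))
    x = range(len(effects))
    ax.bar(x, effects["percent_change"], color="#9ecae1", edgecolor="k")
    yerr_lo = effects["percent_change"] - effects["ci_low"]
    yerr_hi = effects["ci_high"] - effects["percent_change"]
    ax.errorbar(x, effects["percent_change"], yerr=[yerr_lo, yerr_hi],
                fmt="none", ecolor="k", capsize=3)
    ax.set_xticks(list(x))
    ax.set_xticklabels(effects["label"], rotation=60, ha="right", fontsize=7)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("predicted change (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
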