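"""Box-and-whisker and variance-CI plots for population summaries.

Rendering convention: boxes span the 1st–3rd quartile with the median line;
whiskers extend to the most extreme points within 1.5×IQR and remaining
points are drawn as outlier dots (the stored summaries keep true min/max).
Variance plots show the point estimate with vertical 95% CI bars.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .popstats import PopulationSummary, _feature_column


def box_whisker_plot(
    records: pd.DataFrame, group_key: str, feature: str = "length", path=None
):
    col = _feature_column(records, feature)
    groups = sorted(records[group_key].dropna().unique(), key=str)
    data = [records.loc[records[group_key] == g, col].dropna() for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot(data, tick_labels=[str(g) for g in groups], whis=1.5)
    ax.set_xlabel(group_key)
    ax.set_ylabel(col)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def variance_ci_plot(summaries: list[PopulationSummary], path=None):
    fig, ax = plt.subplots(figsize=(1.2 * len(summaries) + 2, 4))
    xs = range(len(summaries))
    for x, s in zip(xs, summaries):
        ax.plot([x, x], list(s.variance_ci), color="gray", lw=2)
        ax.plot(x, s.variance, "o", color="black")
    ax.set_xticks(list(xs), [str(s.group) for s in summaries])
    ax.set_ylabel("variance (µm²), 95% CI")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
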