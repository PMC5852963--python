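"""Minimal figure helpers: per-set box plots with significance stars."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .stats import ComparisonResult


def plot_set_comparison(
    vectors_by_set: Mapping[str, Sequence[float]],
    results: Sequence[ComparisonResult] | None = None,
    ax=None,
    title: str | None = None,
    log: bool = False,
):
    """Box plot of one value vector per gene set.

    A star is drawn above each set that is the significantly higher member
    of at least one pairwise comparison.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(vectors_by_set) + 1, 4))
    labels = list(vectors_by_set)
    data = [np.asarray(vectors_by_set[k], dtype=float) for k in labels]
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    if log:
        ax.set_yscale("log")
    starred = {r.higher for r in results or [] if r.significant and r.higher}
    top = max((np.quantile(d, 0.95) for d in data if d.size), default=1.0)
    for i, lab in enumerate(labels, start=1):
        if lab in starred:
            ax.annotate("*", (i, top), ha="center", fontsize=16)
    if title:
        ax.set_title(title)
    return ax
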