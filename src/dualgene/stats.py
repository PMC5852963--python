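"""Two-sample set comparisons: KS, Wilcoxon rank-sum, chi-square.

All pairwise gene-set comparisons in the pipeline run through
:func:`compare_matrix`, which flags significance at α = 0.05 (raw p-values,
no multiple-testing correction, matching the reporting convention of the
figures this reproduces; Benjamini–Hochberg is available as an option) and
marks which set is "higher" (greater mean) when the difference is
significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
#: sample-size threshold below which exact small-sample p-values are used
EXACT_MAX_N = 10


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    set_a: str
    set_b: str
    statistic: float
    p_value: float
    higher: str | None
    significant: bool


def _validate(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    return x, y


def ks_two_sided(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D is the sup-distance between the empirical CDFs.  The p-value is exact
    (permutation distribution) when min(n, m) ≤ 10, asymptotic otherwise.
    """
    x, y = _validate(x, y)
    method = "exact" if min(x.size, y.size) <= EXACT_MAX_N else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) test; W is the rank sum of ``x``.

    Exact p-value for min(n, m) ≤ 10 without ties; otherwise the normal
    approximation with tie correction and continuity correction.  Fully tied
    data (every value identical) degenerates to p = 1 with a warning.
    """
    x, y = _validate(x, y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[: x.size].sum())
    if np.unique(combined).size == 1:
        warnings.warn("all values tied; rank-sum test is uninformative")
        return w, 1.0
    has_ties = np.unique(combined).size < combined.size
    method = (
        "exact" if (min(x.size, y.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return w, float(res.pvalue)


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r × c count table.

    No continuity correction.  Cells with expected count < 5 trigger a
    warning reporting their fraction.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=1) <= 0).any() or (table.sum(axis=0) <= 0).any():
        raise ValueError("every row and column must have a positive sum")
    res = sps.chi2_contingency(table, correction=False)
    frac_small = float((res.expected_freq < 5).mean())
    if frac_small > 0:
        warnings.warn(
            f"{frac_small:.0%} of cells have expected count < 5; "
            "chi-square approximation may be poor"
        )
    return float(res.statistic), int(res.dof), float(res.pvalue)


_TESTS = {
    "KS": ks_two_sided,
    "WILCOXON": wilcoxon_rank_sum,
}


def compare_matrix(
    vectors_by_set: Mapping[str, Sequence[float]],
    test: str = "KS",
    alpha: float = ALPHA,
    bh_correct: bool = False,
) -> list[ComparisonResult]:
    """Run one two-sample test on every unordered pair of gene sets.

    ``higher`` is the set with the greater mean, reported only when the pair
    is significant at ``alpha``.  ``bh_correct=True`` applies
    Benjamini–Hochberg across the pairs before flagging significance.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    labels = list(vectors_by_set)
    if len(labels) < 2:
        raise ValueError("need at least two sets to compare")
    func = _TESTS[test]
    raw = []
    for a, b in combinations(labels, 2):
        stat, p = func(vectors_by_set[a], vectors_by_set[b])
        raw.append((a, b, stat, p))
    pvals = [p for *_, p in raw]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        flags, adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        adj = pvals
        flags = [p < alpha for p in pvals]
    results = []
    for (a, b, stat, _), p, sig in zip(raw, adj, flags):
        higher = None
        if sig:
            higher = a if np.mean(vectors_by_set[a]) >= np.mean(vectors_by_set[b]) else b
        results.append(
            ComparisonResult(
                test=test,
                set_a=a,
                set_b=b,
                statistic=stat,
                p_value=float(p),
                higher=higher,
                significant=bool(sig),
            )
        )
    return results


def results_frame(results: Sequence[ComparisonResult]):
    """Comparison results as a DataFrame with a star column for plots."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "test": r.test,
                "set_a": r.set_a,
                "set_b": r.set_b,
                "statistic": r.statistic,
                "p": r.p_value,
                "higher": r.higher or "NONE",
                "star": "*" if r.significant else "",
            }
            for r in results
        ]
    )
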