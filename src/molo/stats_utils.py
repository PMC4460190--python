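"""Small shared statistical primitives (BH step-up, exact Spearman test)."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.stats import mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests


def rank_sum_test(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value, exact for small untied samples.

    The exact null distribution is used whenever the pooled sample has at
    most 30 observations with no ties (so small-group comparisons reproduce
    full-enumeration p-values); larger or tied samples fall back to scipy's
    default method selection.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 30 and no_ties) else "auto"
    return float(mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone along the sorted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman_test(x, y, max_exact_n: int = 8) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    For n <= ``max_exact_n`` with no ties in either vector the p-value is
    exact, from full enumeration of rank permutations; otherwise the
    t-approximation is used.  Returns (rho, p); rho is nan for a constant
    input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    rho = float(spearmanr(x, y).statistic)
    ties = np.unique(x).size < n or np.unique(y).size < n
    if n <= max_exact_n and not ties:
        rx = rankdata(x)
        ry = rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, float(spearmanr(x, y).pvalue)
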