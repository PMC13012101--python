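"""Shared statistical primitives: rank-sum tests, effect sizes, multiplicity.

The two-group comparisons throughout the pipeline (case vs. control relative
expression, PAS group contrasts) use the two-sided Wilcoxon rank-sum test.
An exact p-value is computed whenever feasible; large samples fall back to
the normal approximation with tie correction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# exact enumeration with ties is O(C(n+m, min(n,m))); cap the work
_TIE_ENUM_CAP = 100_000
_EXACT_MIN_CAP = 25


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of the first sample, two-sided p-value).

    Method selection:
      * no ties and min(n, m) <= 25 -> exact distribution (scipy);
      * ties present and C(n+m, min) <= 100k -> exact midrank enumeration
        (two-sided by distance of U from its null mean nm/2);
      * otherwise -> normal approximation with tie correction.

    Degenerate case: if every pooled value is identical the test carries no
    information and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("each group needs at least 2 samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n + m
    u_obs = float(sps.rankdata(pooled, method="average")[:n].sum() - n * (n + 1) / 2)

    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    if not has_ties and min(n, m) <= _EXACT_MIN_CAP:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return u_obs, float(res.pvalue)

    if has_ties and math.comb(n + m, min(n, m)) <= _TIE_ENUM_CAP:
        return u_obs, _exact_tied_pvalue(pooled, n, u_obs)

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def _exact_tied_pvalue(pooled: np.ndarray, n: int, u_obs: float) -> float:
    """Enumerate all assignments of pooled midranks to the first group."""
    ranks = _midranks(pooled)
    total = len(pooled)
    m = total - n
    mean_u = n * m / 2.0
    dev_obs = abs(u_obs - mean_u)
    offset = n * (n + 1) / 2.0
    count = 0
    n_comb = 0
    for combo in itertools.combinations(range(total), n):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        n_comb += 1
    return count / n_comb


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment across a family of tests.

    method: "BH" (Benjamini-Hochberg step-up) or "bonferroni".
    """
    p = np.asarray(p, dtype=float)
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method: {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method=key)[1]


def cohens_d(treated, baseline) -> float:
    """Standardized mean difference (treated - baseline) with pooled sd.

    Pooled sd uses n-1 denominators per group. If both groups have zero
    variance the difference of means is either exactly 0 (d = 0) or
    undefined (inf with the sign of the difference).
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(baseline, dtype=float)
    diff = a.mean() - b.mean()
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return float(diff / math.sqrt(pooled_var))
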