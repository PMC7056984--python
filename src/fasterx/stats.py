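"""Statistical primitives shared by the chromosome-level analyses.

Thin, explicitly specified wrappers: a percentile bootstrap for the
median, a Mann-Whitney U test whose exact/approximate switch is fixed by
rule (exact enumeration when the smaller sample has <= 8 observations and
there are no ties; tie-corrected normal approximation otherwise), a
Yates-corrected chi-square for 2x2 tables, and an exact two-sided
binomial sign test.

The bootstrap RNG protocol is part of the contract so results are
reproducible and independently checkable: a ``numpy.random.Generator``
(PCG64) seeded with ``seed``, drawing for each of the ``n_boot``
replicates, in order, one array of ``n`` indices via
``rng.integers(0, n, size=n)``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def bootstrap_median_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the median. Returns (median, lo, hi)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    med = float(np.median(v))
    if v.size == 1:
        logger.warning("bootstrap of a single value: degenerate interval")
        return med, med, med
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    boot = np.median(v[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return med, float(lo), float(hi)


def mwu_test(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when min(n) <= 8 and the pooled sample has no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def chi2_yates(a: int, b: int, c: int, d: int) -> float:
    """Yates continuity-corrected chi-square p-value for the 2x2 table
    [[a, b], [c, d]] (1 df, two-sided)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("table entries must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def sign_test(n_success: int, n_total: int) -> float:
    """Exact two-sided binomial sign test against p = 0.5."""
    if n_total <= 0:
        raise ValueError("sign test needs at least one observation")
    if not 0 <= n_success <= n_total:
        raise ValueError("n_success must lie in [0, n_total]")
    return float(stats.binomtest(n_success, n_total, 0.5).pvalue)
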