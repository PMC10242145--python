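"""Shared statistical kernels.

Every hypergeometric enrichment in the package (motif enrichment, LMR x
feature grids, LMR x peak overlap) goes through :func:`hypergeom_upper_p`
so a single kernel carries all of the exact-tail arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_p", "fold_enrichment", "bh_adjust", "welch_t_log2"]


def hypergeom_upper_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` items without replacement from a universe of ``N`` items
    of which ``K`` are successes; returns the probability of seeing ``k``
    or more successes.  ``P(X >= 0)`` is 1 by convention.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric configuration N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    return float(_sps.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed/expected ratio (k/n) / (K/N); NaN when K == 0, 0 when k == 0."""
    if n == 0 or N == 0:
        return float("nan")
    if K == 0:
        return float("nan")
    return (k / n) / (K / N)


def bh_adjust(p):
    """Benjamini-Hochberg adjusted p-values; NaNs are passed through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def welch_t_log2(a: np.ndarray, b: np.ndarray, axis: int = 1) -> np.ndarray:
    """Two-sided Welch t-test p-values on log2(x + 1) transformed values.

    ``a`` and ``b`` are arrays of non-negative expression values with
    observations along ``axis`` (genes along the other axis).  Genes whose
    groups are both constant get p = NaN.
    """
    la = np.log2(np.asarray(a, dtype=float) + 1.0)
    lb = np.log2(np.asarray(b, dtype=float) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = _sps.ttest_ind(la, lb, axis=axis, equal_var=False)
    return np.asarray(res.pvalue, dtype=float)
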