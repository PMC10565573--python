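"""Shared statistical primitives: exact binomial test, Clopper-Pearson
interval, Benjamini-Hochberg adjustment."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


@lru_cache(maxsize=100_000)
def exact_binom_pvalue(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value by the minimum-likelihood convention:
    the sum of all Binomial(n, p) point masses no larger than the observed
    one.  Stated explicitly because two-sided conventions differ.
    """
    if n == 0:
        return 1.0
    return float(sps.binomtest(k, n, p, alternative="two-sided").pvalue)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="beta")
    return (float(lo), float(hi))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values; NaN inputs stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
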