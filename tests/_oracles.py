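"""Independent brute-force oracles used to validate the statistical
primitives and the pileup/junction counting.  These deliberately avoid the
code paths (and where possible the libraries) they check."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pysam

_EXCLUDE = 0x4 | 0x100 | 0x200 | 0x400 | 0x800


def binom_pvalue_enum(k: int, n: int) -> float:
    """Two-sided exact binomial p vs 0.5 by full enumeration of point
    masses (minlike convention), in exact rational arithmetic."""
    pmf = [Fraction(comb(n, j)) for j in range(n + 1)]  # common 2^-n factor
    obs = pmf[k]
    return float(sum(m for m in pmf if m <= obs) / Fraction(2) ** n)


def fisher_pvalue_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration over all
    tables with the observed margins, exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = Fraction(comb(n, c1))
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {x: Fraction(comb(r1, x) * comb(r2, c1 - x)) / denom for x in range(lo, hi + 1)}
    obs = pmf[a]
    tol = Fraction(1, 10**12)
    return float(sum(p for p in pmf.values() if p <= obs * (1 + tol)))


def clopper_pearson_beta(k: int, n: int, conf: float = 0.95):
    """Clopper-Pearson bounds from the closed-form beta quantiles."""
    from scipy.special import betaincinv  # direct beta quantile, not statsmodels

    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(betaincinv(k, n - k + 1, alpha / 2))
    hi = 1.0 if k == n else float(betaincinv(k + 1, n - k, 1 - alpha / 2))
    return lo, hi


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sv = values[order]
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def mannwhitney_enum(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of all
    C(n_a+n_b, n_a) labelings of the pooled sample (midrank ties;
    two-sided by doubling the smaller tail, capped at 1)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a = len(a)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = ranks[:n_a].sum()
    u_obs = w_obs - n_a * (n_a + 1) / 2.0
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n_a)]
    )
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def naive_pileup(path, contig, pos1, min_bq=20, min_mq=20):
    """Brute-force pileup at one site: iterate every read, walk the CIGAR,
    tally the base covering the site.  Returns (dict base->count, n_other)
    where reference skips are excluded and deletions count as other."""
    tally = {b: 0 for b in "ACGT"}
    other = 0
    pos0 = pos1 - 1
    with pysam.AlignmentFile(str(path)) as af:
        for read in af.fetch(until_eof=True):
            if read.flag & _EXCLUDE or read.mapping_quality < min_mq:
                continue
            if read.reference_name != contig or read.cigartuples is None:
                continue
            qpos, rpos = 0, read.reference_start
            for op, length in read.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    if rpos <= pos0 < rpos + length:
                        off = pos0 - rpos
                        if read.query_qualities[qpos + off] >= min_bq:
                            base = read.query_sequence[qpos + off].upper()
                            if base in tally:
                                tally[base] += 1
                            else:
                                other += 1
                    qpos += length
                    rpos += length
                elif op == 1:  # I
                    qpos += length
                elif op == 2:  # D
                    if rpos <= pos0 < rpos + length:
                        other += 1
                    rpos += length
                elif op == 3:  # N: excluded entirely
                    rpos += length
                elif op == 4:  # S
                    qpos += length
    return tally, other


def junction_counts_walk(path, contig, junctions, min_overhang=6, min_mq=20):
    """Brute-force junction tally: for every read, list its (gap, flank)
    triples by walking the CIGAR and count matches."""
    tallies = {j: 0 for j in junctions}
    with pysam.AlignmentFile(str(path)) as af:
        for read in af.fetch(until_eof=True):
            if read.flag & _EXCLUDE or read.mapping_quality < min_mq:
                continue
            if read.reference_name != contig or read.cigartuples is None:
                continue
            cig = read.cigartuples
            rpos = read.reference_start
            flank = 0
            for i, (op, length) in enumerate(cig):
                if op in (0, 7, 8):
                    flank += length
                    rpos += length
                elif op == 3:
                    gap = (rpos, rpos + length)
                    rpos += length
                    after = 0
                    for op2, l2 in cig[i + 1 :]:
                        if op2 in (0, 7, 8):
                            after += l2
                        else:
                            break
                    if gap in tallies and flank >= min_overhang and after >= min_overhang:
                        tallies[gap] += 1
                    flank = 0
                elif op == 2:
                    flank = 0
                    rpos += length
                else:
                    flank = 0
    return tallies
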