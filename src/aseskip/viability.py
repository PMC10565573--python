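"""Growth-in-low-attachment (GILA) viability statistics.

Raw ATP-luminescence values from the Day-8 low-attachment plate are
normalized to the mean of that line's four Day-0 replicates, and cell
lines are compared with a two-sided Mann-Whitney (Wilcoxon rank-sum)
test.  The exact null distribution of the U statistic is computed by
dynamic programming over (doubled) midranks, which is equivalent to full
enumeration of all group labelings and handles ties exactly; a normal
approximation with tie correction takes over for larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

PLATE_COLUMNS = ["line", "bio_rep", "tech_rep", "day", "value"]


@dataclass
class ViabilityPlate:
    """Long-format viability measurements: one row per well with columns
    line, bio_rep, tech_rep, day (0 or 8), value (arbitrary units)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        if (self.data["value"] < 0).any():
            raise ValueError("raw luminescence values must be >= 0")
        days = set(self.data["day"].unique())
        if not days <= {0, 8}:
            raise ValueError(f"unexpected day labels: {sorted(days - {0, 8})}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ViabilityPlate":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())


def normalize_viability(plate: ViabilityPlate) -> pd.DataFrame:
    """Divide each Day-8 value by the mean of the matching line's Day-0
    replicates (within the same biological replicate).

    Returns the Day-8 rows with an added ``normalized`` column.
    """
    df = plate.data
    day0 = (
        df[df["day"] == 0]
        .groupby(["line", "bio_rep"])["value"]
        .mean()
        .rename("day0_mean")
    )
    if (day0 <= 0).any():
        bad = day0[day0 <= 0].index.tolist()
        raise ValueError(f"Day-0 mean is zero for {bad}; cannot normalize")
    day8 = df[df["day"] == 8].merge(day0, on=["line", "bio_rep"], how="left")
    if day8["day0_mean"].isna().any():
        missing = day8[day8["day0_mean"].isna()][["line", "bio_rep"]]
        raise ValueError(f"no Day-0 replicates for {missing.drop_duplicates().values}")
    day8["normalized"] = day8["value"] / day8["day0_mean"]
    return day8


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U statistics for both labelings and the two-sided p."""

    u_a: float
    u_b: float
    pvalue: float
    method: str  # "exact" | "normal"
    n_a: int
    n_b: int


def _exact_rank_sum_p(ranks2: np.ndarray, n_a: int, w2_obs: int) -> float:
    """Exact two-sided p for the rank-sum statistic by DP over doubled
    midranks: counts subsets of size n_a by doubled rank sum, which is the
    full enumeration of all C(N, n_a) equally-likely labelings."""
    total = int(ranks2.sum())
    n = len(ranks2)
    # f[k, s] = number of size-k subsets with doubled rank sum s
    f = np.zeros((n_a + 1, total + 1), dtype=float)
    f[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(min(n_a, n) - 1, -1, -1):
            f[k + 1, r:] += f[k, : total + 1 - r]
    dist = f[n_a]
    n_subsets = comb(n, n_a)
    p_le = dist[: w2_obs + 1].sum() / n_subsets
    p_ge = dist[w2_obs:].sum() / n_subsets
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
) -> RankSumResult:
    """Two-sided Mann-Whitney test with midrank ties.

    ``method='auto'`` uses the exact null distribution when
    n_a + n_b <= 20 and the tie-corrected normal approximation otherwise;
    the two-sided p doubles the smaller tail, capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w_a = ranks[:n_a].sum()
    u_a = w_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    if method == "auto":
        method = "exact" if n <= 20 else "normal"
    if method == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        w2_obs = int(round(2 * w_a))
        p = _exact_rank_sum_p(ranks2, n_a, w2_obs)
    elif method == "normal":
        mu = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var == 0:
            p = 1.0
        else:
            # continuity-corrected two-sided normal p
            z = (abs(u_a - mu) - 0.5) / sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankSumResult(u_a=float(u_a), u_b=float(u_b), pvalue=float(p),
                         method=method, n_a=n_a, n_b=n_b)


def compare_lines(
    plate: ViabilityPlate,
    aggregate: str = "none",
    method: str = "auto",
) -> pd.DataFrame:
    """Normalize and run pairwise rank-sum tests between all cell lines.

    ``aggregate='none'`` tests the normalized technical-replicate values
    (mirroring plots that show every well); ``'biological'`` first averages
    technical replicates within each biological replicate, the conservative
    option when technical replicates are pseudo-replicates.
    """
    norm8 = normalize_viability(plate)
    if aggregate == "biological":
        values = (
            norm8.groupby(["line", "bio_rep"])["normalized"].mean().reset_index()
        )
    elif aggregate == "none":
        values = norm8
    else:
        raise ValueError("aggregate must be 'none' or 'biological'")
    lines = sorted(values["line"].unique())
    rows = []
    for i, la in enumerate(lines):
        for lb in lines[i + 1 :]:
            va = values.loc[values["line"] == la, "normalized"].to_numpy()
            vb = values.loc[values["line"] == lb, "normalized"].to_numpy()
            res = rank_sum_test(va, vb, method=method)
            rows.append(
                {
                    "line_a": la,
                    "line_b": lb,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "U": res.u_a,
                    "p": res.pvalue,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
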