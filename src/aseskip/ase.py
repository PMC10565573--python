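"""Allelic-imbalance quantification at heterozygous sites in RNA.

At each heterozygous tag SNV the RNA non-reference fraction f_R estimates
the relative expression of the two alleles; under balanced expression
f_R = 0.5.  Per site we attach an exact two-sided binomial p-value against
0.5, a Clopper-Pearson 95% interval, and a Benjamini-Hochberg q-value
across the sample's sites; a site is called imbalanced when q falls below
alpha *and* |f_R - 0.5| reaches an effect-size floor, because a pure
p-value rule over-calls at high depth.

The module is organized around :class:`AllelicImbalanceModel` (data in,
``fit()`` out) whose :class:`AllelicImbalanceResults` carries the per-site
table, the pooled sample summary and a ``summary()`` text table; the
functional operations below are the building blocks and remain usable on
their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts import SiteAlleleCounts
from .genotype import ZygosityCall
from .stats import bh_adjust, clopper_pearson, exact_binom_pvalue

BALANCED = "balanced"
IMBALANCED = "imbalanced"
INSUFFICIENT = "insufficient"
UNTESTED = "untested"  # fraction computed, test not yet run


@dataclass
class ImbalanceResult:
    """Per-site allelic-imbalance record."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    n_ref: int
    n_alt: int
    n_other: int
    fraction: float | None  # f_R = alt / (ref + alt)
    ci_low: float | None
    ci_high: float | None
    pvalue: float | None
    qvalue: float | None = None
    verdict: str = INSUFFICIENT

    @property
    def informative_depth(self) -> int:
        return self.n_ref + self.n_alt


@dataclass(frozen=True)
class SampleImbalanceSummary:
    """Sample-level pooled summary across het sites.

    Pooling sums ref and alt reads over sites; this treats all het sites
    as lying on one consistently-labelled haplotype pair within the gene
    (phase between sites is not inferred).
    """

    sample: str
    n_het_sites: int
    n_imbalanced: int
    n_informative: int
    pooled_alt_fraction: float | None
    pooled_pvalue: float | None
    majority_allele: str  # ref | alt | none
    verdict: str


def allele_fraction(
    counts: SiteAlleleCounts,
    site: ZygosityCall,
    min_depth: int = 10,
    conf: float = 0.95,
) -> ImbalanceResult:
    """RNA non-reference allele fraction at one heterozygous site, with a
    Clopper-Pearson interval.  Bases other than ref/alt are excluded from
    the denominator and reported separately."""
    if not site.is_het:
        raise ValueError(f"site {site.contig}:{site.pos} is not heterozygous")
    if counts.material != "RNA":
        raise ValueError(f"allele fraction requires RNA counts, got {counts.material!r}")
    if (counts.contig, counts.pos) != (site.contig, site.pos):
        raise ValueError("RNA counts and zygosity call are for different sites")
    n_ref = counts.count(site.ref)
    n_alt = counts.count(site.alt)
    n_other = counts.depth - n_ref - n_alt
    informative = n_ref + n_alt
    if informative < min_depth or informative == 0:
        return ImbalanceResult(
            site.contig, site.pos, site.ref, site.alt, n_ref, n_alt, n_other,
            None, None, None, None, verdict=INSUFFICIENT,
        )
    frac = n_alt / informative
    lo, hi = clopper_pearson(n_alt, informative, conf)
    return ImbalanceResult(
        site.contig, site.pos, site.ref, site.alt, n_ref, n_alt, n_other,
        frac, lo, hi, None, verdict=UNTESTED,
    )


def _betabinom_pvalue(k: int, n: int, rho: float) -> float:
    """Two-sided beta-binomial p-value (minlike convention) at mean 0.5 and
    fixed overdispersion rho = 1/(a+b+1)."""
    s = (1.0 - rho) / rho  # a + b
    a = b = s / 2.0
    ks = np.arange(n + 1)
    pmf = sps.betabinom.pmf(ks, n, a, b)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())


def test_imbalance(
    results: Sequence[ImbalanceResult],
    alpha: float = 0.05,
    effect_floor: float = 0.15,
    dispersion: float | None = None,
) -> list[ImbalanceResult]:
    """Attach exact binomial p-values (vs 0.5), BH q-values across the
    sample's sites, and verdicts.

    ``dispersion`` switches to a beta-binomial null with that fixed
    overdispersion (rho); the default exact binomial mirrors a pure
    read-ratio reading of the data.
    """
    out = list(results)
    for r in out:
        if r.verdict == INSUFFICIENT:
            r.pvalue = None
            continue
        if dispersion:
            r.pvalue = _betabinom_pvalue(r.n_alt, r.informative_depth, dispersion)
        else:
            r.pvalue = exact_binom_pvalue(r.n_alt, r.informative_depth, 0.5)
    pvals = [np.nan if r.pvalue is None else r.pvalue for r in out]
    qvals = bh_adjust(pvals)
    for r, q in zip(out, qvals):
        if r.verdict == INSUFFICIENT:
            continue
        r.qvalue = float(q)
        if r.qvalue < alpha and abs(r.fraction - 0.5) >= effect_floor:
            r.verdict = IMBALANCED
        else:
            r.verdict = BALANCED
    return out


def summarize_sample(
    results: Sequence[ImbalanceResult],
    sample: str = "sample",
    alpha: float = 0.05,
) -> SampleImbalanceSummary:
    """Pool counts across the sample's het sites (summation over sites on
    the same haplotype pair) and call the sample-level verdict: imbalanced
    iff the pooled exact binomial test rejects at ``alpha`` and at least
    half of the informative sites are individually imbalanced."""
    informative = [r for r in results if r.verdict != INSUFFICIENT]
    n_imb = sum(1 for r in informative if r.verdict == IMBALANCED)
    if not informative:
        return SampleImbalanceSummary(
            sample, len(results), 0, 0, None, None, "none", INSUFFICIENT
        )
    tot_alt = sum(r.n_alt for r in informative)
    tot = sum(r.informative_depth for r in informative)
    pooled = tot_alt / tot
    pooled_p = exact_binom_pvalue(tot_alt, tot, 0.5)
    if pooled > 0.5:
        majority = "alt"
    elif pooled < 0.5:
        majority = "ref"
    else:
        majority = "none"
    verdict = (
        IMBALANCED
        if pooled_p < alpha and n_imb >= len(informative) / 2
        else BALANCED
    )
    return SampleImbalanceSummary(
        sample, len(results), n_imb, tot, pooled, pooled_p, majority, verdict
    )


@dataclass(frozen=True)
class SiteContrast:
    """Per-site tumor-vs-normal comparison (Fisher exact on the
    ref/alt x tumor/normal table)."""

    contig: str
    pos: int
    tumor_fraction: float | None
    normal_fraction: float | None
    fisher_pvalue: float
    tumor_verdict: str
    normal_verdict: str


@dataclass(frozen=True)
class TumorNormalContrast:
    """Tumor-vs-matched-normal contrast over the shared het sites."""

    sites: tuple[SiteContrast, ...]
    tumor: SampleImbalanceSummary
    normal: SampleImbalanceSummary
    tumor_only_positions: tuple[int, ...]
    normal_only_positions: tuple[int, ...]

    @property
    def tumor_specific_ase(self) -> bool:
        """Tumor imbalanced while the matched normal expresses both alleles
        equally (balanced)."""
        return self.tumor.verdict == IMBALANCED and self.normal.verdict == BALANCED


def compare_tumor_normal(
    tumor_results: Sequence[ImbalanceResult],
    normal_results: Sequence[ImbalanceResult],
    tumor_summary: SampleImbalanceSummary,
    normal_summary: SampleImbalanceSummary,
) -> TumorNormalContrast:
    """Contrast the tumor against its matched normal at shared het sites."""
    t_by = {(r.contig, r.pos): r for r in tumor_results}
    n_by = {(r.contig, r.pos): r for r in normal_results}
    shared = sorted(set(t_by) & set(n_by))
    if not shared:
        raise ValueError("tumor and normal share no sites")
    sites = []
    for key in shared:
        t, n = t_by[key], n_by[key]
        table = [[t.n_alt, t.n_ref], [n.n_alt, n.n_ref]]
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        sites.append(
            SiteContrast(
                contig=key[0], pos=key[1],
                tumor_fraction=t.fraction, normal_fraction=n.fraction,
                fisher_pvalue=p,
                tumor_verdict=t.verdict, normal_verdict=n.verdict,
            )
        )
    return TumorNormalContrast(
        sites=tuple(sites),
        tumor=tumor_summary,
        normal=normal_summary,
        tumor_only_positions=tuple(p for _, p in sorted(set(t_by) - set(n_by))),
        normal_only_positions=tuple(p for _, p in sorted(set(n_by) - set(t_by))),
    )


# ---------------------------------------------------------------- model API
class AllelicImbalanceModel:
    """Allelic-imbalance analysis of one sample, statsmodels-style.

    Parameters
    ----------
    het_sites : heterozygous :class:`ZygosityCall` records (from DNA).
    rna_counts : RNA :class:`SiteAlleleCounts` covering those sites.
    alpha : FDR level for the per-site and pooled verdicts.
    effect_floor : minimum |f_R - 0.5| for an imbalance call.
    min_depth : minimum informative RNA depth per site.
    dispersion : optional fixed beta-binomial overdispersion for the null.
    """

    def __init__(
        self,
        het_sites: Sequence[ZygosityCall],
        rna_counts: Sequence[SiteAlleleCounts],
        alpha: float = 0.05,
        effect_floor: float = 0.15,
        min_depth: int = 10,
        dispersion: float | None = None,
        sample: str = "sample",
    ) -> None:
        self.het_sites = [z for z in het_sites if z.is_het]
        self.rna_counts = {(c.contig, c.pos): c for c in rna_counts}
        self.alpha = alpha
        self.effect_floor = effect_floor
        self.min_depth = min_depth
        self.dispersion = dispersion
        self.sample = sample

    @classmethod
    def from_dataframe(
        cls, het: pd.DataFrame, rna: pd.DataFrame, **kwargs
    ) -> "AllelicImbalanceModel":
        """Build from count-table style DataFrames (columns as in the
        count TSV schema; ``het`` needs contig, pos_1based, ref, alt)."""
        from .genotype import HET

        sites = [
            ZygosityCall(str(r.contig), int(r.pos_1based), str(r.ref), str(r.alt),
                         None, None, HET, 0)
            for r in het.itertuples(index=False)
        ]
        counts = [
            SiteAlleleCounts(
                contig=str(r.contig), pos=int(r.pos_1based), ref=str(r.ref),
                alt=None if str(getattr(r, "alt", ".")) == "." else str(r.alt),
                n_a=int(r.nA), n_c=int(r.nC), n_g=int(r.nG), n_t=int(r.nT),
                n_other=int(getattr(r, "nOther", 0)), material="RNA",
            )
            for r in rna.itertuples(index=False)
        ]
        return cls(sites, counts, **kwargs)

    def fit(self) -> "AllelicImbalanceResults":
        per_site = []
        for z in sorted(self.het_sites, key=lambda z: (z.contig, z.pos)):
            key = (z.contig, z.pos)
            if key not in self.rna_counts:
                raise ValueError(f"no RNA counts at het site {key}")
            per_site.append(
                allele_fraction(self.rna_counts[key], z, min_depth=self.min_depth)
            )
        per_site = test_imbalance(
            per_site,
            alpha=self.alpha,
            effect_floor=self.effect_floor,
            dispersion=self.dispersion,
        )
        summary = summarize_sample(per_site, sample=self.sample, alpha=self.alpha)
        return AllelicImbalanceResults(self, per_site, summary)


class AllelicImbalanceResults:
    """Fitted allelic-imbalance results for one sample."""

    def __init__(
        self,
        model: AllelicImbalanceModel,
        per_site: list[ImbalanceResult],
        sample_summary: SampleImbalanceSummary,
    ) -> None:
        self.model = model
        self.per_site = per_site
        self.sample_summary = sample_summary

    @property
    def sites(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contig": r.contig,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "refCount": r.n_ref,
                    "altCount": r.n_alt,
                    "otherCount": r.n_other,
                    "fraction": r.fraction,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.pvalue,
                    "q": r.qvalue,
                    "verdict": r.verdict,
                }
                for r in self.per_site
            ]
        )

    def summary(self) -> str:
        s = self.sample_summary
        lines = [
            f"Allelic imbalance: sample {s.sample}",
            f"  het sites: {s.n_het_sites}   imbalanced: {s.n_imbalanced}",
            f"  pooled alt fraction: "
            + ("NA" if s.pooled_alt_fraction is None else f"{s.pooled_alt_fraction:.4f}")
            + f"  (n={s.n_informative})",
            f"  pooled p vs 0.5: "
            + ("NA" if s.pooled_pvalue is None else f"{s.pooled_pvalue:.3g}"),
            f"  majority allele: {s.majority_allele}   verdict: {s.verdict}",
            "",
            self.sites.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        s = self.sample_summary
        Path(path).write_text(
            json.dumps(
                {
                    "sample": s.sample,
                    "n_het_sites": s.n_het_sites,
                    "n_imbalanced": s.n_imbalanced,
                    "n_informative": s.n_informative,
                    "pooled_alt_fraction": s.pooled_alt_fraction,
                    "pooled_pvalue": s.pooled_pvalue,
                    "majority_allele": s.majority_allele,
                    "verdict": s.verdict,
                },
                indent=2,
            )
            + "\n"
        )
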