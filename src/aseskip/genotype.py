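"""Germline zygosity calls from DNA allele counts.

A site is heterozygous when its DNA non-reference fraction is "near 1:1":
formalized as the fraction lying inside a configurable window combined
with a two-sided exact binomial test against 0.5 that is *not* rejected.
The window guards low-depth sites; the test guards high-depth sites where
small systematic deviations would otherwise pass the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .counts import SiteAlleleCounts
from .stats import exact_binom_pvalue

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ZygosityCall:
    """Per-site genotype decision with its supporting statistics."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    dna_alt_fraction: float | None
    pvalue: float | None  # exact two-sided binomial vs 0.5
    call: str
    depth_used: int
    alt_was_inferred: bool = False

    @property
    def is_het(self) -> bool:
        return self.call == HET


def call_zygosity(
    counts: SiteAlleleCounts,
    het_window: tuple[float, float] = (0.2, 0.8),
    min_depth: int = 14,
    alpha: float = 0.001,
    hom_cut: float = 0.02,
) -> ZygosityCall:
    """Call hom-ref / het / hom-alt / ambiguous from DNA allele counts.

    The alt base is the most frequent non-reference base when unset (ties
    broken lexicographically, recorded via ``alt_was_inferred``).  Calls:
    het iff the alt fraction lies in ``het_window`` and the exact binomial
    test vs 0.5 is not rejected at ``alpha``; hom-ref iff the fraction is
    below ``hom_cut`` (allowing error bases); hom-alt symmetrically;
    otherwise ambiguous.  Depth below ``min_depth`` is ambiguous.
    """
    if counts.material != "DNA":
        raise ValueError(f"zygosity requires DNA counts, got {counts.material!r}")
    inferred = counts.alt is None
    alt = counts.most_frequent_non_ref() if inferred else counts.alt
    n_ref = counts.n_ref
    n_alt = counts.count(alt)
    informative = n_ref + n_alt
    if informative < min_depth:
        frac = n_alt / informative if informative else None
        return ZygosityCall(
            counts.contig, counts.pos, counts.ref, alt, frac, None, AMBIGUOUS,
            informative, inferred,
        )
    frac = n_alt / informative
    p = exact_binom_pvalue(n_alt, informative, 0.5)
    low, high = het_window
    if low <= frac <= high and p >= alpha:
        call = HET
    elif frac < hom_cut:
        call = HOM_REF
    elif frac > 1.0 - hom_cut:
        call = HOM_ALT
    else:
        call = AMBIGUOUS
    return ZygosityCall(
        counts.contig, counts.pos, counts.ref, alt, frac, p, call, informative, inferred
    )


def genotype_region(
    counts: Sequence[SiteAlleleCounts],
    het_window: tuple[float, float] = (0.2, 0.8),
    min_depth: int = 14,
    alpha: float = 0.001,
    hom_cut: float = 0.02,
    het_vcf: str | Path | None = None,
    sample: str = "sample",
) -> list[ZygosityCall]:
    """Call zygosity at every site of one sample's DNA, in position order,
    optionally serializing the heterozygous sites to a VCF with GT=0/1.

    Duplicate positions are an error: each site must appear once.
    """
    seen: set[tuple[str, int]] = set()
    for c in counts:
        key = (c.contig, c.pos)
        if key in seen:
            raise ValueError(f"duplicate position {key} in input counts")
        seen.add(key)
    ordered = sorted(counts, key=lambda c: (c.contig, c.pos))
    calls = [
        call_zygosity(c, het_window=het_window, min_depth=min_depth, alpha=alpha,
                      hom_cut=hom_cut)
        for c in ordered
    ]
    if het_vcf is not None:
        write_het_vcf([z for z in calls if z.is_het], het_vcf, sample=sample)
    return calls


def write_het_vcf(
    calls: Iterable[ZygosityCall], path: str | Path, sample: str = "sample"
) -> None:
    """Serialize heterozygous calls as a VCF 4.x with GT=0/1."""
    calls = sorted(calls, key=lambda z: (z.contig, z.pos))
    header = pysam.VariantHeader()
    contigs = []
    for z in calls:
        if z.contig not in contigs:
            contigs.append(z.contig)
    max_pos = {c: max(z.pos for z in calls if z.contig == c) for c in contigs}
    for c in contigs:
        header.add_line(f"##contig=<ID={c},length={max_pos[c] + 10000}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for z in calls:
            if not z.is_het:
                raise ValueError("write_het_vcf expects only het calls")
            rec = vf.new_record(
                contig=z.contig, start=z.pos - 1, alleles=(z.ref, z.alt)
            )
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample].phased = False
            vf.write(rec)


def read_het_vcf(path: str | Path) -> list[ZygosityCall]:
    """Read a het-site VCF back into minimal heterozygous calls (used when
    genotyping and imbalance testing run as separate steps)."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            out.append(
                ZygosityCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    dna_alt_fraction=None,
                    pvalue=None,
                    call=HET,
                    depth_used=0,
                )
            )
    return out
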