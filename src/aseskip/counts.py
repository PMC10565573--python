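"""Per-site allele counting from alignments (pileup) and count-table IO.

This is the programmatic equivalent of reading allele ratios off a genome
browser: for each candidate SNV site we tally the A/C/G/T/other bases of
the reads covering it, after the usual quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .gene_model import BASES, Snv

# unmapped | secondary | qcfail | dup | supplementary
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

COUNT_TSV_COLUMNS = [
    "contig",
    "pos_1based",
    "ref",
    "alt",
    "nA",
    "nC",
    "nG",
    "nT",
    "nOther",
    "sample",
    "material",
    "condition",
]


@dataclass
class SiteAlleleCounts:
    """Base counts observed at one genomic site in one alignment set.

    ``pos`` is 1-based.  ``n_other`` collects deletions and any base that is
    not A/C/G/T; reference skips (spliced-over introns) are excluded from
    depth entirely.
    """

    contig: str
    pos: int
    ref: str
    alt: str | None = None
    n_a: int = 0
    n_c: int = 0
    n_g: int = 0
    n_t: int = 0
    n_other: int = 0
    sample: str = ""
    material: str = "DNA"
    condition: str = "tumor"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position is 1-based and must be >= 1")
        for n in (self.n_a, self.n_c, self.n_g, self.n_t, self.n_other):
            if n < 0:
                raise ValueError("counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.n_a + self.n_c + self.n_g + self.n_t + self.n_other

    def count(self, base: str) -> int:
        return {"A": self.n_a, "C": self.n_c, "G": self.n_g, "T": self.n_t}[base]

    @property
    def n_ref(self) -> int:
        return self.count(self.ref)

    @property
    def n_alt(self) -> int:
        if self.alt is None:
            raise ValueError("alt base is unset")
        return self.count(self.alt)

    @property
    def informative_depth(self) -> int:
        """Reads carrying either the ref or the alt base."""
        return self.n_ref + self.n_alt

    def most_frequent_non_ref(self) -> str:
        """Most frequent base other than ref; ties broken lexicographically."""
        others = [(b, self.count(b)) for b in BASES if b != self.ref]
        return max(others, key=lambda t: (t[1], -ord(t[0][0])))[0]


def count_alleles(
    alignments: str | Path,
    sites: Sequence[Snv] | Sequence[tuple],
    contig: str | None = None,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
    sample: str = "",
    material: str = "DNA",
    condition: str = "tumor",
) -> list[SiteAlleleCounts]:
    """Pileup allele counts at the given SNV sites.

    ``sites`` may be :class:`Snv` objects (0-based positions; ``contig``
    must then be given) or ``(contig, pos_1based, ref, alt)`` tuples.
    Duplicate-marked, secondary and supplementary reads and bases below the
    quality thresholds are excluded.  Overlapping mates of a pair are
    counted once.  Deletions at the site count as "other"; reference skips
    do not contribute to depth.
    """
    norm: list[tuple[str, int, str, str | None]] = []
    for s in sites:
        if isinstance(s, Snv):
            if contig is None:
                raise ValueError("contig required when sites are Snv objects")
            norm.append((contig, s.pos + 1, s.ref, s.alt))
        else:
            c, pos1, ref = s[0], int(s[1]), s[2]
            alt = s[3] if len(s) > 3 else None
            norm.append((c, pos1, ref, alt))

    path = str(alignments)
    with pysam.AlignmentFile(path) as af:
        if not af.has_index():
            raise ValueError(
                f"alignment file {path} has no index; sorted+indexed input required"
            )
        known = set(af.references)
        out: list[SiteAlleleCounts] = []
        for c, pos1, ref, alt in norm:
            if c not in known:
                raise ValueError(f"contig {c!r} not present in {path}")
            rec = SiteAlleleCounts(
                contig=c,
                pos=pos1,
                ref=ref,
                alt=alt,
                sample=sample,
                material=material,
                condition=condition,
            )
            tally = {b: 0 for b in BASES}
            other = 0
            for col in af.pileup(
                c,
                pos1 - 1,
                pos1,
                truncate=True,
                stepper="samtools",
                min_base_quality=min_base_quality,
                min_mapping_quality=min_mapping_quality,
                ignore_overlaps=True,
                flag_filter=_EXCLUDE_FLAGS,
                max_depth=1_000_000,
            ):
                for pr in col.pileups:
                    if pr.is_refskip:
                        continue
                    if pr.is_del:
                        other += 1
                        continue
                    base = pr.alignment.query_sequence[pr.query_position].upper()
                    if base in tally:
                        tally[base] += 1
                    else:
                        other += 1
            rec.n_a, rec.n_c, rec.n_g, rec.n_t = (tally[b] for b in BASES)
            rec.n_other = other
            out.append(rec)
    return out


@dataclass(frozen=True)
class CandidateSite:
    """A site flagged by the gene-wide scan as potentially heterozygous."""

    contig: str
    pos: int  # 1-based
    major: str
    minor: str
    n_major: int
    n_minor: int
    depth: int

    @property
    def minor_fraction(self) -> float:
        return self.n_minor / self.depth if self.depth else 0.0


def scan_het_candidates(
    alignments: str | Path,
    contig: str,
    start: int,
    end: int,
    min_depth: int = 14,
    min_minor_fraction: float = 0.2,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> list[CandidateSite]:
    """Scan a region (0-based half-open) for candidate heterozygous sites:
    positions where the second-most-common base reaches
    ``min_minor_fraction`` of an ACGT depth of at least ``min_depth``.

    This is a liberal pre-filter; the genotyping step makes the real call.
    Results are ordered by position.
    """
    if end <= start:
        return []
    out: list[CandidateSite] = []
    with pysam.AlignmentFile(str(alignments)) as af:
        if not af.has_index():
            raise ValueError("alignment file has no index")
        if contig not in af.references:
            raise ValueError(f"contig {contig!r} not present in alignments")
        for col in af.pileup(
            contig,
            start,
            end,
            truncate=True,
            stepper="samtools",
            min_base_quality=min_base_quality,
            min_mapping_quality=min_mapping_quality,
            ignore_overlaps=True,
            flag_filter=_EXCLUDE_FLAGS,
            max_depth=1_000_000,
        ):
            tally = {b: 0 for b in BASES}
            for pr in col.pileups:
                if pr.is_refskip or pr.is_del:
                    continue
                base = pr.alignment.query_sequence[pr.query_position].upper()
                if base in tally:
                    tally[base] += 1
            depth = sum(tally.values())
            if depth < min_depth:
                continue
            ranked = sorted(tally.items(), key=lambda t: (-t[1], t[0]))
            (major, n_major), (minor, n_minor) = ranked[0], ranked[1]
            if n_minor / depth >= min_minor_fraction:
                out.append(
                    CandidateSite(
                        contig, col.reference_pos + 1, major, minor, n_major, n_minor, depth
                    )
                )
    return out


# ---------------------------------------------------------------------- IO
def write_counts_tsv(records: Iterable[SiteAlleleCounts], path: str | Path) -> None:
    rows = [
        {
            "contig": r.contig,
            "pos_1based": r.pos,
            "ref": r.ref,
            "alt": r.alt if r.alt is not None else ".",
            "nA": r.n_a,
            "nC": r.n_c,
            "nG": r.n_g,
            "nT": r.n_t,
            "nOther": r.n_other,
            "sample": r.sample,
            "material": r.material,
            "condition": r.condition,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COUNT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> list[SiteAlleleCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    out = []
    for row in df.itertuples(index=False):
        alt = getattr(row, "alt", ".")
        out.append(
            SiteAlleleCounts(
                contig=str(row.contig),
                pos=int(row.pos_1based),
                ref=str(row.ref),
                alt=None if alt in (".", None) or pd.isna(alt) else str(alt),
                n_a=int(row.nA),
                n_c=int(row.nC),
                n_g=int(row.nG),
                n_t=int(row.nT),
                n_other=int(row.nOther),
                sample=str(getattr(row, "sample", "")),
                material=str(getattr(row, "material", "DNA")),
                condition=str(getattr(row, "condition", "tumor")),
            )
        )
    return out
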