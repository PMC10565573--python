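"""Gene model for a multi-exon gene with one cassette exon.

Coordinates are 0-based half-open internally; 1-based coordinates appear
only at VCF/SAM boundaries and in tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Snv:
    """A biallelic single-nucleotide variant site (0-based position)."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"SNV bases must be one of {BASES}: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at pos {self.pos}")
        if self.pos < 0:
            raise ValueError("SNV position must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene with non-overlapping exons, one interior cassette exon, and
    phased germline SNV sites used as allele tags.

    The two inclusion junctions (upstream-exon -> cassette and
    cassette -> downstream-exon) and the exclusion junction
    (upstream-exon -> downstream-exon) are derived from the exon intervals.
    Junction coordinates are (donor end, acceptor start) pairs, i.e. the
    half-open gap skipped by a spliced alignment.
    """

    contig: str
    exons: tuple[tuple[int, int], ...]
    cassette_index: int
    snvs: tuple[Snv, ...] = ()
    strand: str = "+"
    name: str = "gene"

    def __post_init__(self) -> None:
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "snvs", tuple(self.snvs))
        if len(exons) < 3:
            raise ValueError("need at least 3 exons to define a cassette event")
        for s, e in exons:
            if not 0 <= s < e:
                raise ValueError(f"invalid exon interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError("exons must be sorted and non-overlapping")
        if not 0 < self.cassette_index < len(exons) - 1:
            raise ValueError("cassette exon must be interior (flanked on both sides)")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for snv in self.snvs:
            if not any(s <= snv.pos < e for s, e in exons):
                raise ValueError(f"SNV at {snv.pos} falls outside all exons")

    # ------------------------------------------------------------------ span
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    # ------------------------------------------------------------- junctions
    @property
    def upstream_exon(self) -> tuple[int, int]:
        return self.exons[self.cassette_index - 1]

    @property
    def cassette_exon(self) -> tuple[int, int]:
        return self.exons[self.cassette_index]

    @property
    def downstream_exon(self) -> tuple[int, int]:
        return self.exons[self.cassette_index + 1]

    @property
    def inclusion_junctions(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.upstream_exon[1], self.cassette_exon[0]),
            (self.cassette_exon[1], self.downstream_exon[0]),
        )

    @property
    def exclusion_junction(self) -> tuple[int, int]:
        return (self.upstream_exon[1], self.downstream_exon[0])

    # ------------------------------------------------------------- isoforms
    def isoform_blocks(self, skipped: bool) -> tuple[tuple[int, int], ...]:
        """Exon blocks of the mature transcript, skipping the cassette or not."""
        if skipped:
            return tuple(
                ex for i, ex in enumerate(self.exons) if i != self.cassette_index
            )
        return self.exons

    def snv_in_cassette(self, snv: Snv) -> bool:
        s, e = self.cassette_exon
        return s <= snv.pos < e

    # ------------------------------------------------------------------- IO
    def to_bed(self, path: str | Path) -> None:
        """Write the exon structure as a single BED12 line."""
        sizes = ",".join(str(e - s) for s, e in self.exons)
        starts = ",".join(str(s - self.start) for s, _ in self.exons)
        line = "\t".join(
            [
                self.contig,
                str(self.start),
                str(self.end),
                self.name,
                "0",
                self.strand,
                str(self.start),
                str(self.end),
                "0",
                str(len(self.exons)),
                sizes,
                starts,
            ]
        )
        Path(path).write_text(line + "\n")

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        cassette_index: int,
        snvs: Iterable[Snv] = (),
    ) -> "GeneModel":
        """Read exon structure from BED12 (first record) or from BED6 rows
        (one exon per row, same name)."""
        lines = [
            ln.split("\t")
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith(("#", "track", "browser"))
        ]
        if not lines:
            raise ValueError(f"no BED records in {path}")
        first = lines[0]
        if len(first) >= 12:
            contig = first[0]
            chrom_start = int(first[1])
            name = first[3]
            strand = first[5] if first[5] in "+-" else "+"
            sizes = [int(x) for x in first[10].rstrip(",").split(",")]
            starts = [int(x) for x in first[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
        else:
            contig = first[0]
            name = first[3] if len(first) > 3 else "gene"
            strand = first[5] if len(first) > 5 and first[5] in "+-" else "+"
            exons = tuple(sorted((int(f[1]), int(f[2])) for f in lines))
        return cls(
            contig=contig,
            exons=exons,
            cassette_index=cassette_index,
            snvs=tuple(snvs),
            strand=strand,
            name=name,
        )


def snvs_from_tsv(path: str | Path) -> tuple[Snv, ...]:
    """Read SNV sites from a TSV with columns contig, pos_1based, ref, alt
    (header optional)."""
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if parts[1] in ("pos", "pos_1based", "position"):
            continue
        out.append(Snv(pos=int(parts[1]) - 1, ref=parts[2], alt=parts[3]))
    return tuple(out)


def snvs_from_vcf(path: str | Path) -> tuple[Snv, ...]:
    """Read biallelic SNV sites from a VCF."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1 and ref != alt:
                out.append(Snv(pos=rec.start, ref=ref, alt=alt))
    return tuple(out)


def example_gene(contig: str = "chrT") -> GeneModel:
    """A toy five-exon gene with an interior cassette exon and eight
    heterozygous SNV tag sites in the constitutive exons.

    Exons are 200 bp separated by 400 bp introns; the middle exon (index 2)
    is the cassette.  SNVs sit two per flanking constitutive exon so that
    their RNA coverage does not depend on the splicing outcome, mirroring
    tag SNVs spread along a gene body; they are placed at least 100 bp (one
    default read length) from both transcript ends of either isoform so
    that short-read coverage at the tag sites has no transcript-edge
    deficit.
    """
    exons = ((1000, 1200), (1600, 1800), (2200, 2400), (2800, 3000), (3400, 3600))
    snv_positions = (1110, 1170, 1650, 1750, 2850, 2950, 3430, 3490)
    refs = ("A", "C", "G", "T", "A", "C", "G", "T")
    alts = ("G", "T", "A", "C", "T", "A", "C", "G")
    snvs = tuple(Snv(p, r, a) for p, r, a in zip(snv_positions, refs, alts))
    return GeneModel(
        contig=contig, exons=exons, cassette_index=2, snvs=snvs, name="toygene"
    )
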