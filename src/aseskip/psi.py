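"""Percent exon-skipping (PSI) of a cassette exon from junction-spanning
reads.

Only junction reads are used: an exon-body read is compatible with both
isoforms, so skipping is unambiguous only at the splice junctions.  The
skipping fraction is

    psi_skip = E / (E + I),    I = mean(inclusion_upstream, inclusion_downstream)

where E is the exclusion-junction count and the two inclusion junctions
are averaged so that inclusion support is on the same per-event scale as
exclusion support (an included transcript crosses both inclusion
junctions, an excluded one crosses the single exclusion junction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .gene_model import GeneModel
    from .sim import SimTruth

PSI_METHOD = "junction-flank-mean"

# unmapped | secondary | qcfail | dup | supplementary
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800


@dataclass(frozen=True)
class JunctionCounts:
    """Read counts over the three junctions of one cassette-exon event."""

    inclusion_upstream: int
    inclusion_downstream: int
    exclusion: int
    sample: str = ""

    def __post_init__(self) -> None:
        for n in (self.inclusion_upstream, self.inclusion_downstream, self.exclusion):
            if n < 0 or int(n) != n:
                raise ValueError("junction counts must be non-negative integers")


@dataclass(frozen=True)
class PsiResult:
    """Estimated skipping fraction for one sample's cassette event.

    ``psi_skip`` is None when total junction support is below the minimum;
    ``percent`` reports it on the 0-100 scale used in sample tables.
    """

    psi_skip: float | None
    inclusion_support: float
    exclusion_support: int
    method: str = PSI_METHOD
    sample: str = ""

    @property
    def percent(self) -> float | None:
        return None if self.psi_skip is None else 100.0 * self.psi_skip


def compute_psi(junctions: JunctionCounts, min_total: int = 10) -> PsiResult:
    """Skipping fraction from junction counts; undefined (None) when the
    combined junction support is below ``min_total`` reads."""
    incl = (junctions.inclusion_upstream + junctions.inclusion_downstream) / 2.0
    excl = junctions.exclusion
    total = incl + excl
    psi = None if total < min_total or total == 0 else excl / total
    return PsiResult(
        psi_skip=psi,
        inclusion_support=incl,
        exclusion_support=excl,
        sample=junctions.sample,
    )


def extract_junction_counts(
    alignments: str | Path,
    model: "GeneModel",
    min_overhang: int = 6,
    min_mapping_quality: int = 20,
    sample: str = "",
) -> JunctionCounts:
    """Tally reads supporting each junction of the model's cassette event.

    A read supports a junction iff one of its alignment gaps (N CIGAR
    operations) matches the junction's (donor end, acceptor start) exactly
    and the aligned blocks flanking that gap each span at least
    ``min_overhang`` bases.  Each read counts at most once per junction.
    """
    inc_up, inc_down = model.inclusion_junctions
    excl = model.exclusion_junction
    tallies = {inc_up: 0, inc_down: 0, excl: 0}
    with pysam.AlignmentFile(str(alignments)) as af:
        if model.contig not in af.references:
            raise ValueError(f"contig {model.contig!r} not present in alignments")
        if af.has_index():
            it = af.fetch(model.contig, max(0, model.start - 1000), model.end + 1000)
        else:
            it = af.fetch(until_eof=True)
        for read in it:
            if read.flag & _EXCLUDE_FLAGS:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            if read.reference_name != model.contig or read.cigartuples is None:
                continue
            seen: set[tuple[int, int]] = set()
            ref_pos = read.reference_start
            aligned_before = 0
            cig = read.cigartuples
            for i, (op, length) in enumerate(cig):
                if op in (0, 7, 8):  # M, =, X
                    aligned_before += length
                    ref_pos += length
                elif op == 2:  # D consumes reference, breaks the flank
                    aligned_before = 0
                    ref_pos += length
                elif op == 3:  # N: a candidate junction
                    junction = (ref_pos, ref_pos + length)
                    ref_pos += length
                    if junction in tallies and junction not in seen:
                        after = 0
                        for op2, len2 in cig[i + 1 :]:
                            if op2 in (0, 7, 8):
                                after += len2
                            else:
                                break
                        if aligned_before >= min_overhang and after >= min_overhang:
                            tallies[junction] += 1
                            seen.add(junction)
                    aligned_before = 0
                # I, S, H, P consume no reference and do not extend the flank
                elif op in (1, 4):
                    aligned_before = 0
    return JunctionCounts(
        inclusion_upstream=tallies[inc_up],
        inclusion_downstream=tallies[inc_down],
        exclusion=tallies[excl],
        sample=sample,
    )


@dataclass(frozen=True)
class PsiRecovery:
    """Comparison of an estimated skipping fraction against the generative
    haplotype-mixture expectation."""

    estimate: float | None
    expected: float
    abs_error: float | None


def recover_psi_truth(result: PsiResult, truth: "SimTruth") -> PsiRecovery:
    """Compare an estimate with the configured mixture
    theta_R*psi_alt + (1-theta_R)*psi_ref."""
    expected = truth.expected_exclusion_fraction
    err = None if result.psi_skip is None else abs(result.psi_skip - expected)
    return PsiRecovery(estimate=result.psi_skip, expected=expected, abs_error=err)
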