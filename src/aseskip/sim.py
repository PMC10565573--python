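"""Synthetic paired DNA/RNA data for a two-haplotype gene with a cassette
exon, with full ground truth.

The generative model: a diploid locus carries a reference and an alternate
haplotype distinguished by phased SNV tag sites.  DNA reads sample the two
haplotypes at fraction ``dna_alt_fraction`` (0.5 for a germline
heterozygote); RNA reads sample them at ``rna_alt_fraction``, which may
deviate strongly from 0.5 under allele-specific expression.  Each
transcript skips the cassette exon with a haplotype-specific probability
(``psi_ref``, ``psi_alt``), so the expected exclusion fraction at the
splicing event is the mixture

    phi = theta_R * psi_alt + (1 - theta_R) * psi_ref.

Sequencing substitutes each base uniformly to one of the three other bases
at rate ``error_rate``.  Per-site depths are Poisson around the configured
means.  A fixed seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .counts import SiteAlleleCounts, write_counts_tsv
from .gene_model import BASES, GeneModel
from .psi import JunctionCounts


@dataclass(frozen=True)
class SimTruth:
    """Generative parameters of one synthetic sample.

    dna_alt_fraction : fraction of DNA fragments from the alt haplotype
        (theta_D; 0.5 for a germline heterozygote).
    rna_alt_fraction : fraction of transcripts from the alt haplotype
        (theta_R; deviates from 0.5 under allele-specific expression).
    psi_ref, psi_alt : per-haplotype probability that a transcript skips
        the cassette exon.
    dna_depth, rna_depth : mean per-site read depth (Poisson).
    error_rate : per-base uniform substitution rate (epsilon).
    seed : RNG seed; fixed seed means byte-identical output.
    """

    dna_alt_fraction: float = 0.5
    rna_alt_fraction: float = 0.5
    psi_ref: float = 0.0
    psi_alt: float = 0.0
    dna_depth: float = 80.0
    rna_depth: float = 150.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dna_alt_fraction",
            "rna_alt_fraction",
            "psi_ref",
            "psi_alt",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.dna_depth < 0 or self.rna_depth < 0:
            raise ValueError("depths must be non-negative")

    @property
    def expected_exclusion_fraction(self) -> float:
        """The haplotype mixture phi = theta_R*psi_alt + (1-theta_R)*psi_ref."""
        return (
            self.rna_alt_fraction * self.psi_alt
            + (1.0 - self.rna_alt_fraction) * self.psi_ref
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _observed_base_probs(theta: float, eps: float, ref: str, alt: str) -> dict[str, float]:
    """P(observed base) for a site: true base is alt w.p. theta, ref
    otherwise; sequencing keeps the true base w.p. 1-eps and substitutes
    uniformly among the other three w.p. eps."""
    probs = {b: 0.0 for b in BASES}
    for true_base, w in ((alt, theta), (ref, 1.0 - theta)):
        for b in BASES:
            if b == true_base:
                probs[b] += w * (1.0 - eps)
            else:
                probs[b] += w * (eps / 3.0)
    return probs


def simulate_counts(
    model: GeneModel, truth: SimTruth
) -> tuple[list[SiteAlleleCounts], list[SiteAlleleCounts], JunctionCounts, SimTruth]:
    """Draw per-site DNA and RNA allele-count tables and junction counts
    directly from the generative model (no reads).

    Per site, depth ~ Poisson(mean depth) and the base tally is multinomial
    with the error-adjusted allele probabilities.  Junction counts are
    independent Poissons with means rna_depth*phi for the exclusion
    junction and rna_depth*(1-phi) for each inclusion junction, phi being
    the haplotype mixture above.  Sites in the cassette exon see RNA
    coverage reduced by the inclusion fraction of their haplotype mix.
    """
    rng = np.random.default_rng(truth.seed)
    dna: list[SiteAlleleCounts] = []
    rna: list[SiteAlleleCounts] = []

    def draw_site(pos0, ref, alt, theta, depth_mean, material) -> SiteAlleleCounts:
        depth = int(rng.poisson(depth_mean))
        rec = SiteAlleleCounts(
            contig=model.contig,
            pos=pos0 + 1,
            ref=ref,
            alt=alt,
            material=material,
        )
        if depth > 0:
            probs = _observed_base_probs(theta, truth.error_rate, ref, alt)
            ns = rng.multinomial(depth, [probs[b] for b in BASES])
            rec.n_a, rec.n_c, rec.n_g, rec.n_t = (int(x) for x in ns)
        return rec

    phi = truth.expected_exclusion_fraction
    for snv in model.snvs:
        dna.append(
            draw_site(
                snv.pos, snv.ref, snv.alt, truth.dna_alt_fraction, truth.dna_depth, "DNA"
            )
        )
        rna_mean = truth.rna_depth
        rna_theta = truth.rna_alt_fraction
        if model.snv_in_cassette(snv):
            # cassette-exon sites are covered only by inclusion transcripts,
            # so both coverage and the haplotype mix condition on inclusion
            rna_mean *= 1.0 - phi
            if phi < 1.0:
                rna_theta = (
                    truth.rna_alt_fraction * (1.0 - truth.psi_alt) / (1.0 - phi)
                )
        rna.append(draw_site(snv.pos, snv.ref, snv.alt, rna_theta, rna_mean, "RNA"))

    junctions = JunctionCounts(
        inclusion_upstream=int(rng.poisson(truth.rna_depth * (1.0 - phi))),
        inclusion_downstream=int(rng.poisson(truth.rna_depth * (1.0 - phi))),
        exclusion=int(rng.poisson(truth.rna_depth * phi)),
    )
    return dna, rna, junctions, truth


# ----------------------------------------------------------------- reads
def _make_reference(rng: np.random.Generator, model: GeneModel, length: int) -> np.ndarray:
    """Random reference sequence (as byte codes 0..3) with the model's ref
    base planted at every SNV position."""
    seq = rng.integers(0, 4, size=length)
    for snv in model.snvs:
        seq[snv.pos] = BASES.index(snv.ref)
    return seq


def _apply_errors(rng: np.random.Generator, codes: np.ndarray, eps: float) -> np.ndarray:
    if eps <= 0:
        return codes
    err = rng.random(codes.size) < eps
    if err.any():
        codes = codes.copy()
        # uniform over the 3 other bases
        shift = rng.integers(1, 4, size=int(err.sum()))
        codes[err] = (codes[err] + shift) % 4
    return codes


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclass(frozen=True)
class SimulatedAlignments:
    """Paths written by :func:`simulate_alignments`."""

    dna_bam: Path
    rna_bam: Path
    dna_sam: Path
    rna_sam: Path
    truth_vcf: Path
    truth_json: Path


def simulate_alignments(
    model: GeneModel,
    truth: SimTruth,
    out_dir: str | Path,
    read_length: int = 100,
    prefix: str = "sample",
) -> SimulatedAlignments:
    """Write coordinate-sorted DNA and RNA alignments (SAM text plus
    indexed BAM), a truth VCF of the SNV sites, and a JSON sidecar of the
    generative parameters.

    DNA reads are contiguous fragments from one of the two haplotypes; RNA
    reads are drawn uniformly from spliced transcripts and mapped back to
    the genome with N CIGAR operations across introns.  Read counts are
    chosen so that the expected per-site depth matches
    :func:`simulate_counts` at the same parameters.
    """
    if read_length < 2:
        raise ValueError("read_length must be >= 2")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)

    ref_len = model.end + read_length + 100
    ref = _make_reference(rng, model, ref_len)
    hap = {False: ref, True: ref.copy()}
    for snv in model.snvs:
        hap[True][snv.pos] = BASES.index(snv.alt)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.contig, "LN": ref_len}],
        }
    )

    reads: list[tuple[int, str, int, list[tuple[int, int]], str]] = []
    # each entry: (pos, name, flag, cigartuples, seq)

    # ---- DNA: unspliced fragments uniform over the padded gene span
    span_lo = max(0, model.start - read_length)
    span_hi = model.end
    n_dna = int(rng.poisson(truth.dna_depth * (span_hi - span_lo) / read_length))
    starts = np.sort(rng.integers(span_lo, span_hi, size=n_dna))
    is_alt = rng.random(n_dna) < truth.dna_alt_fraction
    for i, (st, a) in enumerate(zip(starts, is_alt)):
        codes = _apply_errors(rng, hap[bool(a)][st : st + read_length], truth.error_rate)
        reads.append(
            (int(st), f"dna{i:07d}", 0, [(0, read_length)], _codes_to_seq(codes))
        )
    dna_reads = reads

    # ---- RNA: spliced reads per haplotype x isoform category
    rna_reads: list[tuple[int, str, int, list[tuple[int, int]], str]] = []
    idx = 0
    for alt_hap in (False, True):
        w_h = truth.rna_alt_fraction if alt_hap else 1.0 - truth.rna_alt_fraction
        psi = truth.psi_alt if alt_hap else truth.psi_ref
        for skipped in (False, True):
            w = w_h * (psi if skipped else 1.0 - psi)
            if w <= 0:
                continue
            blocks = model.isoform_blocks(skipped)
            tx_len = sum(e - s for s, e in blocks)
            if tx_len < read_length:
                raise ValueError("read_length exceeds transcript length")
            n_starts = tx_len - read_length + 1
            lam = truth.rna_depth * w * n_starts / read_length
            n = int(rng.poisson(lam))
            tx_starts = rng.integers(0, n_starts, size=n)
            tx_seq = np.concatenate([hap[alt_hap][s:e] for s, e in blocks])
            for ts in tx_starts:
                codes = _apply_errors(
                    rng, tx_seq[ts : ts + read_length], truth.error_rate
                )
                pos, cigar = _map_to_genome(blocks, int(ts), read_length)
                rna_reads.append(
                    (pos, f"rna{idx:07d}", 0, cigar, _codes_to_seq(codes))
                )
                idx += 1

    dna_bam = out_dir / f"{prefix}.dna.bam"
    rna_bam = out_dir / f"{prefix}.rna.bam"
    dna_sam = out_dir / f"{prefix}.dna.sam"
    rna_sam = out_dir / f"{prefix}.rna.sam"
    _write_alignments(dna_reads, header, dna_sam, dna_bam)
    _write_alignments(rna_reads, header, rna_sam, rna_bam)

    truth_vcf = out_dir / f"{prefix}.truth.vcf"
    _write_truth_vcf(model, truth, ref_len, truth_vcf)
    truth_json = out_dir / f"{prefix}.truth.json"
    truth.to_json(truth_json)
    return SimulatedAlignments(dna_bam, rna_bam, dna_sam, rna_sam, truth_vcf, truth_json)


def _map_to_genome(
    blocks: tuple[tuple[int, int], ...], tx_start: int, read_length: int
) -> tuple[int, list[tuple[int, int]]]:
    """Map a transcript-coordinate read onto the genome: returns the genomic
    start and CIGAR tuples with M ops inside exons and N ops across the
    introns the read spans."""
    cigar: list[tuple[int, int]] = []
    pos = None
    remaining = read_length
    offset = tx_start
    for i, (s, e) in enumerate(blocks):
        blen = e - s
        if offset >= blen:
            offset -= blen
            continue
        take = min(blen - offset, remaining)
        if pos is None:
            pos = s + offset
        cigar.append((0, take))  # M
        remaining -= take
        offset = 0
        if remaining == 0:
            break
        nxt = blocks[i + 1]
        cigar.append((3, nxt[0] - e))  # N across the intron
    assert remaining == 0 and pos is not None
    return pos, cigar


def _write_alignments(reads, header, sam_path: Path, bam_path: Path) -> None:
    reads = sorted(reads, key=lambda r: (r[0], r[1]))
    segs = []
    for pos, name, flag, cigar, seq in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigartuples = cigar
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        segs.append(a)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for a in segs:
            out.write(a)
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for a in segs:
            out.write(a)
    pysam.index(str(bam_path))


def _write_truth_vcf(model: GeneModel, truth: SimTruth, ref_len: int, path: Path) -> None:
    """Truth VCF of the simulated SNV sites with the DNA genotype implied by
    the configured DNA alt fraction."""
    if truth.dna_alt_fraction == 0.0:
        gt = (0, 0)
    elif truth.dna_alt_fraction == 1.0:
        gt = (1, 1)
    else:
        gt = (0, 1)
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={model.contig},length={ref_len}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("sim")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for snv in model.snvs:
            rec = vf.new_record(
                contig=model.contig,
                start=snv.pos,
                alleles=(snv.ref, snv.alt),
            )
            rec.samples["sim"]["GT"] = gt
            rec.samples["sim"].phased = False
            vf.write(rec)


def write_count_tables(
    model: GeneModel, truth: SimTruth, out_dir: str | Path, prefix: str = "sample"
) -> dict[str, Path]:
    """Convenience wrapper: simulate count tables and write them as TSV plus
    the junction counts and truth sidecar as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dna, rna, junc, _ = simulate_counts(model, truth)
    paths = {
        "dna_counts": out_dir / f"{prefix}.dna_counts.tsv",
        "rna_counts": out_dir / f"{prefix}.rna_counts.tsv",
        "junctions": out_dir / f"{prefix}.junctions.json",
        "truth": out_dir / f"{prefix}.truth.json",
    }
    write_counts_tsv(dna, paths["dna_counts"])
    write_counts_tsv(rna, paths["rna_counts"])
    paths["junctions"].write_text(
        json.dumps(
            {
                "inclusion_upstream": junc.inclusion_upstream,
                "inclusion_downstream": junc.inclusion_downstream,
                "exclusion": junc.exclusion,
            },
            indent=2,
        )
        + "\n"
    )
    truth.to_json(paths["truth"])
    return paths
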