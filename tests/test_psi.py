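"""Tests of junction extraction and percent-skipping computation."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aseskip import (
    JunctionCounts,
    SimTruth,
    compute_psi,
    example_gene,
    extract_junction_counts,
    recover_psi_truth,
)
from aseskip.sim import simulate_alignments, simulate_counts

from _oracles import junction_counts_walk


class TestComputePsi:
    def test_worked_example(self):
        # E=80, I = mean(10, 10) = 10 -> psi = 80/90
        r = compute_psi(JunctionCounts(10, 10, 80))
        assert r.psi_skip == pytest.approx(80 / 90)
        assert r.percent == pytest.approx(100 * 80 / 90)

    def test_no_exclusion_reads(self):
        assert compute_psi(JunctionCounts(50, 60, 0)).psi_skip == 0.0

    def test_no_inclusion_reads(self):
        assert compute_psi(JunctionCounts(0, 0, 40)).psi_skip == 1.0

    def test_undefined_below_min_total(self):
        r = compute_psi(JunctionCounts(2, 2, 3), min_total=10)
        assert r.psi_skip is None and r.percent is None

    @given(
        up=st.integers(0, 500),
        down=st.integers(0, 500),
        excl=st.integers(0, 500),
        k=st.integers(1, 7),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, up, down, excl, k):
        a = compute_psi(JunctionCounts(up, down, excl), min_total=0)
        b = compute_psi(JunctionCounts(k * up, k * down, k * excl), min_total=0)
        if a.psi_skip is None:
            assert b.psi_skip is None
        else:
            assert b.psi_skip == pytest.approx(a.psi_skip)

    def test_monotone_in_counts(self):
        base = compute_psi(JunctionCounts(20, 20, 30), min_total=0).psi_skip
        more_excl = compute_psi(JunctionCounts(20, 20, 31), min_total=0).psi_skip
        more_incl = compute_psi(JunctionCounts(21, 20, 30), min_total=0).psi_skip
        assert more_excl > base > more_incl


class TestExtractJunctions:
    def test_no_skipping_no_exclusion_reads(self, model, tmp_path):
        truth = SimTruth(psi_ref=0.0, psi_alt=0.0, seed=31)
        paths = simulate_alignments(model, truth, tmp_path)
        j = extract_junction_counts(paths.rna_bam, model)
        assert j.exclusion == 0
        assert j.inclusion_upstream > 0 and j.inclusion_downstream > 0

    def test_matches_cigar_walk_oracle(self, model, tmp_path):
        truth = SimTruth(
            rna_alt_fraction=0.9, psi_alt=0.95, psi_ref=0.05, seed=32
        )
        paths = simulate_alignments(model, truth, tmp_path)
        j = extract_junction_counts(paths.rna_bam, model, min_overhang=6)
        inc_up, inc_down = model.inclusion_junctions
        oracle = junction_counts_walk(
            paths.rna_bam,
            model.contig,
            [inc_up, inc_down, model.exclusion_junction],
            min_overhang=6,
        )
        assert j.inclusion_upstream == oracle[inc_up]
        assert j.inclusion_downstream == oracle[inc_down]
        assert j.exclusion == oracle[model.exclusion_junction]
        assert j.exclusion > 0

    def test_min_overhang_threshold(self, model, tmp_path):
        """A read with a 4-base overhang supports no junction at
        min_overhang=6 but does at 4."""
        up_end, cass_start = model.inclusion_junctions[0]
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": model.contig, "LN": 10_000}],
            }
        )
        a = pysam.AlignedSegment(header)
        a.query_name = "short_overhang"
        a.reference_id = 0
        a.reference_start = up_end - 4
        a.mapping_quality = 60
        a.cigartuples = [(0, 4), (3, cass_start - up_end), (0, 50)]
        a.query_sequence = "A" * 54
        a.query_qualities = pysam.qualitystring_to_array("I" * 54)
        bam = tmp_path / "one.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
            out.write(a)
        pysam.index(str(bam))
        assert extract_junction_counts(bam, model, min_overhang=6).inclusion_upstream == 0
        assert extract_junction_counts(bam, model, min_overhang=4).inclusion_upstream == 1


class TestRecovery:
    def test_mixture_recovered_at_high_junction_depth(self, model):
        """theta_R=0.9, psi_alt=0.95, psi_ref=0 -> expected exclusion
        fraction 0.855; estimate within 0.05 at junction depth 300."""
        for seed in range(5):
            truth = SimTruth(
                rna_alt_fraction=0.9, psi_alt=0.95, psi_ref=0.0,
                rna_depth=300.0, seed=seed,
            )
            _, _, junc, _ = simulate_counts(model, truth)
            rec = recover_psi_truth(compute_psi(junc), truth)
            assert rec.expected == pytest.approx(0.855)
            assert rec.abs_error < 0.05

    def test_equal_psi_is_theta_independent(self, model):
        for theta in (0.1, 0.5, 0.9):
            truth = SimTruth(
                rna_alt_fraction=theta, psi_ref=0.3, psi_alt=0.3, seed=8
            )
            assert truth.expected_exclusion_fraction == pytest.approx(0.3)

    def test_pure_alt_expression_gives_psi_alt(self, model):
        truth = SimTruth(
            rna_alt_fraction=1.0, psi_alt=0.6, psi_ref=0.0, error_rate=0.0,
            rna_depth=400.0, seed=9,
        )
        _, _, junc, _ = simulate_counts(model, truth)
        rec = recover_psi_truth(compute_psi(junc), truth)
        assert rec.expected == pytest.approx(0.6)
        assert rec.abs_error < 0.08


def test_joint_structure_of_headline_finding(model, tmp_path):
    """When psi_alt >> psi_ref and theta_R >> 0.5, both the imbalance flag
    and high skipping fire on the same synthetic sample."""
    from aseskip import AllelicImbalanceModel
    from aseskip.ase import IMBALANCED
    from aseskip.genotype import HET, ZygosityCall

    truth = SimTruth(rna_alt_fraction=0.95, psi_alt=0.95, psi_ref=0.0, seed=33)
    _, rna, junc, _ = simulate_counts(model, truth)
    het = [
        ZygosityCall(model.contig, s.pos + 1, s.ref, s.alt, 0.5, 1.0, HET, 100)
        for s in model.snvs
    ]
    fit = AllelicImbalanceModel(het, rna).fit()
    psi = compute_psi(junc)
    assert fit.sample_summary.verdict == IMBALANCED
    assert psi.psi_skip > 0.8
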