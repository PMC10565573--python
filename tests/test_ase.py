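"""Tests of allelic-imbalance quantification: per-site fractions and CIs,
exact binomial testing with BH adjustment, pooling, and the tumor-normal
contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aseskip import SimTruth, example_gene
from aseskip.ase import (
    BALANCED,
    IMBALANCED,
    INSUFFICIENT,
    AllelicImbalanceModel,
    allele_fraction,
    compare_tumor_normal,
    summarize_sample,
    test_imbalance as run_imbalance_test,
)
from aseskip.counts import SiteAlleleCounts
from aseskip.genotype import HET, ZygosityCall
from aseskip.sim import simulate_counts

from _oracles import binom_pvalue_enum, clopper_pearson_beta, fisher_pvalue_enum


def het_call(pos=100, ref="A", alt="G"):
    return ZygosityCall("c", pos, ref, alt, 0.5, 1.0, HET, 100)


def rna_site(n_ref, n_alt, n_other=0, pos=100, ref="A", alt="G"):
    kwargs = {"n_a": 0, "n_c": 0, "n_g": 0, "n_t": 0}
    kwargs[f"n_{ref.lower()}"] += n_ref
    kwargs[f"n_{alt.lower()}"] += n_alt
    return SiteAlleleCounts(
        contig="c", pos=pos, ref=ref, alt=alt, material="RNA",
        n_other=n_other, **kwargs,
    )


def fit_sites(count_pairs, **kwargs):
    """Run allele_fraction + test_imbalance over (n_ref, n_alt) pairs."""
    results = [
        allele_fraction(rna_site(r, a, pos=100 + i), het_call(pos=100 + i))
        for i, (r, a) in enumerate(count_pairs)
    ]
    return run_imbalance_test(results, **kwargs)


class TestAlleleFraction:
    def test_simple_fraction(self):
        r = allele_fraction(rna_site(10, 90), het_call())
        assert r.fraction == pytest.approx(0.90)

    def test_no_informative_reads_is_insufficient(self):
        r = allele_fraction(rna_site(0, 0, n_other=5), het_call())
        assert r.verdict == INSUFFICIENT
        assert r.fraction is None and r.n_other == 5

    def test_clopper_pearson_matches_beta_quantiles(self):
        r = allele_fraction(rna_site(25, 25), het_call())
        lo, hi = clopper_pearson_beta(25, 50)
        assert r.fraction == pytest.approx(0.5)
        assert r.ci_low == pytest.approx(lo, abs=1e-10)
        assert r.ci_high == pytest.approx(hi, abs=1e-10)

    def test_ci_contains_fraction(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(10, 300))
            k = int(rng.integers(0, n + 1))
            r = allele_fraction(rna_site(n - k, k), het_call())
            assert r.ci_low <= r.fraction <= r.ci_high
            lo, hi = clopper_pearson_beta(k, n)
            assert (r.ci_low, r.ci_high) == pytest.approx((lo, hi), abs=1e-10)

    def test_third_allele_excluded_from_denominator(self):
        r = allele_fraction(rna_site(40, 40, n_other=20), het_call())
        assert r.fraction == pytest.approx(0.5)
        assert r.n_other == 20

    def test_non_het_site_rejected(self):
        z = ZygosityCall("c", 100, "A", "G", 0.0, None, "hom_ref", 100)
        with pytest.raises(ValueError, match="heterozygous"):
            allele_fraction(rna_site(50, 50), z)


class TestImbalanceTest:
    def test_null_site_balanced(self):
        (r,) = fit_sites([(50, 50)])
        assert r.pvalue == pytest.approx(1.0)
        assert r.verdict == BALANCED

    def test_complete_imbalance_flagged(self):
        # "close to 100%": all reads from one allele
        (r,) = fit_sites([(0, 100)])
        assert r.verdict == IMBALANCED
        assert r.qvalue < 1e-20

    def test_p_matches_enumeration_and_verdict(self):
        (r,) = fit_sites([(30, 70)], alpha=0.05, effect_floor=0.15)
        assert r.pvalue == pytest.approx(binom_pvalue_enum(70, 100), rel=1e-9)
        assert r.verdict == IMBALANCED

    def test_effect_floor_blocks_small_shifts_at_high_depth(self):
        # 54% at depth 5000 is highly significant but below the floor
        (r,) = fit_sites([(2300, 2700)], alpha=0.05, effect_floor=0.15)
        assert r.qvalue < 0.05
        assert r.verdict == BALANCED

    def test_bh_adjustment_invariants(self):
        rng = np.random.default_rng(11)
        pairs = [
            (int(rng.integers(10, 80)), int(rng.integers(10, 80))) for _ in range(20)
        ]
        results = fit_sites(pairs)
        assert all(r.qvalue >= r.pvalue - 1e-12 for r in results)
        assert all(r.qvalue <= 1.0 for r in results)
        by_p = sorted(results, key=lambda r: r.pvalue)
        qs = [r.qvalue for r in by_p]
        assert qs == sorted(qs)

    def test_allele_relabeling_symmetry(self):
        pairs = [(30, 70), (55, 45), (10, 90), (60, 60)]
        fwd = fit_sites(pairs)
        rev = fit_sites([(a, r) for r, a in pairs])
        for f, r in zip(fwd, rev):
            assert r.fraction == pytest.approx(1 - f.fraction)
            assert r.pvalue == pytest.approx(f.pvalue, rel=1e-12)
            assert r.qvalue == pytest.approx(f.qvalue, rel=1e-12)
            assert r.verdict == f.verdict

    def test_beta_binomial_option_is_more_conservative(self):
        (binom_r,) = fit_sites([(30, 70)])
        (bb_r,) = fit_sites([(30, 70)], dispersion=0.05)
        assert bb_r.pvalue > binom_r.pvalue


class TestSampleSummary:
    def test_pooled_fraction_is_depth_weighted_mean(self):
        pairs = [(80, 20), (10, 90), (50, 50)]
        results = fit_sites(pairs)
        s = summarize_sample(results)
        fracs = np.array([r.fraction for r in results])
        weights = np.array([r.informative_depth for r in results], dtype=float)
        assert s.pooled_alt_fraction == pytest.approx(
            float(np.average(fracs, weights=weights))
        )

    def test_empty_input_insufficient(self):
        s = summarize_sample([])
        assert s.verdict == INSUFFICIENT

    def test_single_insufficient_site(self):
        r = allele_fraction(rna_site(1, 2), het_call(), min_depth=10)
        s = summarize_sample(run_imbalance_test([r]))
        assert s.verdict == INSUFFICIENT

    def test_null_sample_verdict_calibrated(self, model=example_gene()):
        """Under theta_R = 0.5 the sample-level imbalance rule fires at no
        more than alpha plus Monte-Carlo slack."""
        hits = 0
        reps = 300
        for seed in range(reps):
            _, rna, _, _ = simulate_counts(model, SimTruth(seed=seed))
            fit = AllelicImbalanceModel(
                [het_call_for(s) for s in model.snvs], rna, sample="null"
            ).fit()
            hits += fit.sample_summary.verdict == IMBALANCED
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= bound

    def test_skewed_sample_power(self, model=example_gene()):
        """theta_R = 0.95 at 8 sites x depth 150 is called imbalanced in at
        least 99% of replicates."""
        truth_args = dict(rna_alt_fraction=0.95)
        hits = 0
        reps = 500
        for seed in range(reps):
            _, rna, _, _ = simulate_counts(model, SimTruth(seed=seed, **truth_args))
            fit = AllelicImbalanceModel(
                [het_call_for(s) for s in model.snvs], rna, sample="t"
            ).fit()
            hits += fit.sample_summary.verdict == IMBALANCED
        assert hits / reps >= 0.99


def het_call_for(snv):
    return ZygosityCall("chrT", snv.pos + 1, snv.ref, snv.alt, 0.5, 1.0, HET, 100)


class TestTumorNormalContrast:
    def fit_sample(self, pairs):
        results = fit_sites(pairs)
        return results, summarize_sample(results)

    def test_identical_tables_not_flagged(self):
        pairs = [(50, 50), (40, 60)]
        t_res, t_sum = self.fit_sample(pairs)
        n_res, n_sum = self.fit_sample(pairs)
        c = compare_tumor_normal(t_res, n_res, t_sum, n_sum)
        assert not c.tumor_specific_ase
        assert all(s.fisher_pvalue == pytest.approx(1.0) for s in c.sites)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        t_res, t_sum = self.fit_sample([(10, 90)])
        n_res, n_sum = self.fit_sample([(50, 50)])
        c = compare_tumor_normal(t_res, n_res, t_sum, n_sum)
        # table rows are (alt, ref) for tumor and normal
        assert c.sites[0].fisher_pvalue == pytest.approx(
            fisher_pvalue_enum(90, 10, 50, 50), rel=1e-8
        )

    def test_simulated_tumor_specific_ase_flagged(self, model=example_gene()):
        het = [het_call_for(s) for s in model.snvs]
        _, rna_t, _, _ = simulate_counts(
            model, SimTruth(rna_alt_fraction=0.95, seed=101)
        )
        _, rna_n, _, _ = simulate_counts(
            model, SimTruth(rna_alt_fraction=0.5, seed=102)
        )
        tfit = AllelicImbalanceModel(het, rna_t, sample="tumor").fit()
        nfit = AllelicImbalanceModel(het, rna_n, sample="normal").fit()
        c = compare_tumor_normal(
            tfit.per_site, nfit.per_site, tfit.sample_summary, nfit.sample_summary
        )
        assert c.tumor_specific_ase
        assert c.tumor.verdict == IMBALANCED and c.normal.verdict == BALANCED

    def test_disjoint_site_sets_rejected(self):
        t_res, t_sum = self.fit_sample([(50, 50)])
        n_results = run_imbalance_test(
            [allele_fraction(rna_site(50, 50, pos=999), het_call(pos=999))]
        )
        n_sum = summarize_sample(n_results)
        with pytest.raises(ValueError, match="no sites"):
            compare_tumor_normal(t_res, n_results, t_sum, n_sum)


def test_model_summary_and_tables(model=example_gene()):
    _, rna, _, _ = simulate_counts(model, SimTruth(rna_alt_fraction=0.95, seed=7))
    fit = AllelicImbalanceModel(
        [het_call_for(s) for s in model.snvs], rna, sample="demo"
    ).fit()
    text = fit.summary()
    assert "demo" in text and "pooled alt fraction" in text
    df = fit.sites
    assert len(df) == 8
    assert set(df["verdict"]) <= {BALANCED, IMBALANCED, INSUFFICIENT}
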