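# Methods

## Model and assumptions

The package analyzes one diploid gene with one internal cassette exon.
Heterozygous germline SNVs act as allele tags; reads covering a tag site
are classified by base identity. The core quantities:

- **DNA alt fraction** f_D = alt/(ref+alt) at a site. A germline
  heterozygote has E[f_D] = 0.5 (we assume no copy-number alteration or
  mapping bias; neither is modeled).
- **RNA alt fraction** f_R at a heterozygous site. Under equal expression
  of both alleles E[f_R] = 0.5; allele-specific expression shifts it
  toward 0 or 1.
- **Skipping fraction.** With per-haplotype skipping probabilities
  (ψ_ref, ψ_alt) and alt-haplotype expression share θ_R, the expected
  fraction of transcripts lacking the cassette exon is the mixture
  φ = θ_R·ψ_alt + (1 − θ_R)·ψ_ref. Junction-spanning reads estimate it
  as psi_skip = E/(E + I), where E counts exclusion-junction reads and I
  is the mean of the two inclusion-junction counts. The flanking mean
  puts inclusion support on the per-event scale: an included transcript
  crosses two inclusion junctions, an excluded one crosses the single
  exclusion junction. Exon-body reads are ignored — they are compatible
  with both isoforms, so skipping is only unambiguous at junctions.

Pooling across het sites sums ref and alt reads. This assumes all sites in
the gene lie on one consistently labelled haplotype pair; inter-site phase
is *not* inferred, so the pooled "majority allele" is reported per allele
label, not per physical haplotype. Sites whose labels are phase-swapped
would partially cancel; for a single gene with few tag SNVs we accept this
rather than estimate phase from the same data being tested.

## Statistical procedures

- **Exact binomial test** (zygosity and imbalance): two-sided vs 0.5 by
  the minimum-likelihood convention — the sum of all Binomial(n, ½) point
  masses no larger than the observed one. Stated explicitly because
  two-sided conventions differ; the doubled-tail convention would be more
  conservative. Implemented via `scipy.stats.binomtest` and cross-checked
  in the test suite against full enumeration in exact rational arithmetic.
- **Zygosity call**: het iff f_D ∈ [0.2, 0.8] *and* the exact test does
  not reject at α = 0.001; hom-ref iff f_D < 0.02 (tolerating error
  bases), hom-alt symmetrically; ambiguous otherwise or when fewer than 14
  informative reads. The window guards low-depth sites, the test guards
  high-depth sites. These numeric choices are conventions of this package:
  "near 1:1" has no canonical quantification.
- **Imbalance call**: per-site exact binomial p, Benjamini–Hochberg
  adjusted within the sample (multiple testing is within-sample only,
  mirroring per-sample reporting), imbalanced iff q < 0.05 and
  |f_R − 0.5| ≥ 0.15. The effect floor exists because at high depth the
  test rejects for biologically trivial shifts. Clopper–Pearson 95%
  intervals accompany every fraction. Sites with fewer than 10 informative
  RNA reads are "insufficient" and excluded from testing. An optional
  beta-binomial null with *fixed* overdispersion ρ is provided for
  sensitivity analysis; it is not the default because a handful of sites
  in one gene cannot estimate ρ.
- **Sample verdict**: imbalanced iff the pooled exact test rejects at
  α = 0.05 *and* at least half the informative sites are individually
  imbalanced.
- **Tumor vs normal**: per shared site, Fisher's exact test on the
  (alt, ref) × (tumor, normal) table; the tumor-specific ASE flag requires
  tumor imbalanced *and* normal balanced.
- **Viability (GILA)**: each Day-8 luminescence value is divided by the
  mean of the matching line's four Day-0 replicates (within the same
  biological replicate — each replicate has its own Day-0 plate). Lines
  are compared with a two-sided Mann–Whitney test using midranks for
  ties; for n_A + n_B ≤ 20 the null distribution of U is computed exactly
  by dynamic programming over doubled midranks (equivalent to enumerating
  all C(N, n_A) labelings), otherwise a tie-corrected,
  continuity-corrected normal approximation is used; the two-sided p
  doubles the smaller tail, capped at 1. By default the test runs on the
  normalized technical-replicate values (matching plots that show every
  well); `aggregate="biological"` first averages technical replicates, the
  conservative option when wells are pseudo-replicates.

## Allele counting

Pileup counting at requested sites excludes unmapped, secondary,
supplementary, QC-fail and duplicate-marked reads, bases below quality 20
and reads below mapping quality 20 (all configurable). Overlapping mates
of a pair are counted once. Deletions spanning a site count as "other";
reference skips (spliced-over introns) are excluded from depth entirely,
since an RNA read splicing over a site carries no allele information. A
junction read supports a junction only if its alignment gap matches the
junction coordinates exactly with ≥ 6 aligned bases on each side.
Whether browser-displayed counts that motivated this formalization applied
such filters is unknowable; these defaults follow common ASE practice.

## The synthetic-data generator

The generator is the package's study condition, not a tuning knob. It
emulates: two haplotypes distinguished by phased tag SNVs (DNA fraction
θ_D, default 0.5), RNA allele share θ_R, per-haplotype skipping
(ψ_ref, ψ_alt), Poisson per-site depths (defaults: DNA 80×, RNA 150× —
conventions chosen as typical exome/transcriptome coverage, since no
per-site depths are published for controlled-access cohorts), and a
uniform substitution error ε (default 0.001) to each of the three other
bases. Junction counts are independent Poissons with means depth·φ
(exclusion) and depth·(1 − φ) (each inclusion junction). At SNV sites
inside the cassette exon both coverage and the haplotype mix condition on
inclusion (coverage × (1 − φ), θ conditioned on the including haplotypes);
the default toy gene places all tag sites in constitutive exons.

The read-level simulator draws spliced reads uniformly from each
haplotype-isoform transcript with Poisson read counts calibrated so the
expected site depth equals the count-level generator's; reads are written
as coordinate-sorted SAM text plus an indexed BAM, with a truth VCF and a
JSON parameter sidecar. A fixed seed gives byte-identical output. The toy
gene's tag sites sit ≥ one read length from both isoforms' transcript
ends so short-read coverage at the sites has no transcript-edge deficit.

Not emulated (and therefore not demonstrated by passing tests): mapping
bias and alignability artifacts, reference bias, indels, paired-end
fragment-length structure, copy-number change, overdispersed (non-Poisson)
coverage, and position-dependent error profiles. Conclusions about real
data must keep those in mind; in particular, reference bias in real
RNA-seq shifts f_R slightly below its true value.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; 1-based only at VCF/SAM
  boundaries and in tabular output.
- Alt-base inference at a site takes the most frequent non-reference base,
  ties broken lexicographically and recorded.
- Zero-depth sites are emitted as all-zero records (not errors); zero
  informative RNA depth yields an undefined fraction and an
  "insufficient" verdict; junction support below 10 reads yields an
  undefined PSI rather than a noisy one.
- All-identical rank-sum inputs give U = n_A·n_B/2 and p = 1.
- Simulation and pipeline are strand-agnostic (counts strand-collapsed).

## Problem sizes in the validation suite

The test suite and acceptance script size their simulations to be
informative yet quick on one CPU: oracle equivalence on ~120 randomized
fixtures per primitive; null calibration on 10,000 simulated sites;
recovery on 500 replicates (8 sites × 150× for the pooled fraction,
junction depth 300 for PSI); end-to-end checks on single simulated
tumor/normal/null samples at the defaults above.

## Known limitations

- The exact binomial test is conservative on discrete counts: its attained
  size at α = 0.05 and depth ≈ 150 is ≈ 0.041, not 0.05. The acceptance
  script reports the analytic attained size next to the measured null
  rejection rate so the two can be compared like for like.
- The genotype het rule rejects a true heterozygote whenever its exact
  binomial p falls below α = 0.001 (≈ 0.05–0.1% of sites at depth ~100),
  so across many sites and samples an occasional planted het is missed by
  design, not by defect.
- Pooling ignores inter-site phase (above); per-site verdicts are
  unaffected.
- PSI from junction reads ignores isoform-specific library or length
  biases; with only three junctions there is no internal way to detect
  them.
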