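import numpy as np
import pytest
from scipy import stats

from lncorf.errors import UndefinedValueError
from lncorf.genome_io import GenomicInterval, RegionAnnotation, VariantRecord
from lncorf.popgen import (
    VariantSet,
    classify_site,
    daf_spectrum,
    diversity_by_region,
    excess_rare_test,
    exon_intron_mc_test,
    neutral_sfs_expectation,
    normalize_by_intron,
    nucleotide_diversity,
    pn_ps_ratio,
    watterson_theta,
)
from lncorf.sequence_features import CodingSequence
from lncorf.synthetic_data import (
    SelectionConfig,
    SequenceSimConfig,
    generate_coding_sequence,
    simulate_polymorphism,
)
from tests.oracles import pairwise_diversity, watterson_direct


def variant(pos, ref="A", alt="C", genotypes=((0, 1), (0, 1)), ancestral=None,
            contig="c"):
    return VariantRecord(contig, pos, ref, alt,
                         ancestral if ancestral is not None else ref,
                         tuple(genotypes))


def plus_strand_region(cds_len=9, intron_len=0, contig="c"):
    intervals = {"CDS": [GenomicInterval(contig, 100, 100 + cds_len)]}
    if intron_len:
        intervals["intron"] = [
            GenomicInterval(contig, 200, 200 + intron_len)
        ]
    return RegionAnnotation("g", intervals, frame_anchor=100)


class TestDiversity:
    def test_no_variants_zero(self):
        assert nucleotide_diversity([], 100) == 0.0

    def test_single_site_worked_example(self):
        # n=4 chromosomes, derived count 2, L=100:
        # site term 2*0.5*0.5*(4/3) = 0.6667 -> pi = 0.006667
        assert nucleotide_diversity([(2, 4)], 100) == pytest.approx(
            0.0066667, rel=1e-4
        )

    def test_two_haplotypes_one_of_ten_sites(self):
        assert nucleotide_diversity([(1, 2)], 10) == pytest.approx(0.1)

    def test_matches_pairwise_oracle_exactly(self):
        """Unbiased per-site heterozygosity equals the all-pairs mean
        difference count on an 8-haplotype fixture."""
        rng = np.random.default_rng(5)
        n, L = 8, 40
        haplotypes = rng.integers(0, 2, size=(n, L))
        # keep only truly segregating columns
        counts = haplotypes.sum(axis=0)
        pairs = [(int(c), n) for c in counts if 0 < c < n]
        pi = nucleotide_diversity(pairs, L)
        hap_strings = ["".join("AC"[int(v)] for v in row) for row in haplotypes]
        assert pi == pytest.approx(pairwise_diversity(hap_strings), abs=1e-12)

    def test_watterson_worked_examples(self):
        assert watterson_theta(0, 5, 100) == 0.0
        assert watterson_theta(3, 5, 100) == pytest.approx(0.0144, abs=1e-6)
        assert watterson_theta(1, 2, 1) == pytest.approx(1.0)
        assert watterson_theta(3, 5, 100) == pytest.approx(
            watterson_direct(3, 5, 100)
        )

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            nucleotide_diversity([], 0)
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 100)


class TestClassifySite:
    CDS = CodingSequence("g", "human", "ATGGATGGG")  # ATG GAT GGG

    def test_synonymous_third_position(self):
        # GAT -> GAC, both Asp; CDS offset 5 is genomic 105
        region = plus_strand_region()
        v = variant(105, ref="T", alt="C")
        assert classify_site(v, region, self.CDS).label == "synonymous"

    def test_nonsynonymous_first_position(self):
        # GAT -> AAT (Asp -> Asn) at codon start, genomic 103
        region = plus_strand_region()
        v = variant(103, ref="G", alt="A")
        assert classify_site(v, region, self.CDS).label == "nonsynonymous"

    def test_intronic_site_noncoding(self):
        region = plus_strand_region(intron_len=50)
        v = variant(210)
        assert classify_site(v, region, self.CDS).label == "noncoding"

    def test_nonsense_substitution_flagged(self):
        # GGG -> TGG is missense; GAT -> TAT... use GGA? Build codon TGG:
        cds = CodingSequence("g", "human", "ATGTGGGGG")
        region = plus_strand_region()
        v = variant(104, ref="G", alt="A")  # TGG -> TAG stop
        cls = classify_site(v, region, cds)
        assert cls.label == "nonsynonymous"
        assert cls.nonsense

    def test_mismatching_reference_unclassifiable(self):
        region = plus_strand_region()
        v = variant(105, ref="G", alt="C")  # CDS has T at that offset
        assert classify_site(v, region, self.CDS).unclassifiable

    def test_strand_consistency(self):
        """The reverse-complement locus yields the same label."""
        # minus-strand gene: genomic interval holds the reverse complement
        region_plus = plus_strand_region()
        region_minus = RegionAnnotation(
            "g", {"CDS": [GenomicInterval("c", 100, 109, "-")]},
            frame_anchor=108,
        )
        rng = np.random.default_rng(9)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(40):
            offset = int(rng.integers(0, 9))
            base = self.CDS.seq[offset]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == base:
                continue
            v_plus = variant(100 + offset, ref=base, alt=alt)
            # same coding offset on the minus strand maps to genomic
            # position 108-offset with complemented alleles
            v_minus = variant(
                108 - offset, ref=base.translate(comp), alt=alt.translate(comp)
            )
            a = classify_site(v_plus, region_plus, self.CDS)
            b = classify_site(v_minus, region_minus, self.CDS)
            assert a.label == b.label
            assert a.nonsense == b.nonsense

    def test_pseudo_sites_through_alignment(self):
        from lncorf.ortholog_assessment import AlignmentRow, CodonAlignment

        rows = [
            AlignmentRow(0, "ATG", "ATG", "match"),
            AlignmentRow(1, "GAT", "GAC", "substitution"),
            AlignmentRow(2, "GGG", "GGG", "match"),
        ]
        aln = CodonAlignment("g", "human", "macaque", rows)
        region = plus_strand_region()
        # subject offset 5 is the C of GAC; C->T returns to GAT (still Asp)
        v = variant(105, ref="C", alt="T")
        cls = classify_site(v, region, self.CDS, alignment=aln)
        assert cls.label == "pseudo_synonymous"
        # subject offset 3 G->A gives AAC (Asp -> Asn equivalent)
        v = variant(103, ref="G", alt="A")
        cls = classify_site(v, region, self.CDS, alignment=aln)
        assert cls.label == "pseudo_nonsynonymous"


class TestPnPs:
    def _neutral_panel(self, seed, n_codons=300, density=0.5, gamma=0.0, n=20):
        cds = generate_coding_sequence(
            SequenceSimConfig(length=3 * n_codons, gc_target=0.5,
                              ensure_orf=True, seed=seed)
        )
        region = RegionAnnotation(
            "g", {"CDS": [GenomicInterval("c", 0, 3 * n_codons)]},
            frame_anchor=0,
        )
        from lncorf.ortholog_assessment import _ng86_site_counts
        from lncorf.sequence_features import STANDARD_TABLE

        s_sites = n_sites = 0.0
        for codon in cds.sense_codons():
            s, nn = _ng86_site_counts(codon, STANDARD_TABLE)
            s_sites += s
            n_sites += nn
        cfg = SelectionConfig(
            n=n,
            sites={
                "nonsynonymous": int(density * n_sites),
                "synonymous": int(density * s_sites),
            },
            gamma={"nonsynonymous": gamma},
            cds=cds,
            seed=seed,
        )
        return simulate_polymorphism(region, cfg).classify(cds), cds

    def test_only_synonymous_variants_gives_zero(self):
        vs, cds = self._neutral_panel(seed=1)
        syn_only = vs.subset_by_site_class("synonymous")
        syn_only.region_annotation = vs.region_annotation
        result = pn_ps_ratio(syn_only, cds)
        assert result.pi_n == 0.0
        assert result.ratio == 0.0

    def test_neutral_ratio_near_one(self):
        """Class-blind placement yields piN/piS ~ 1 (>=2,000 sites)."""
        vs, cds = self._neutral_panel(seed=2, n_codons=1000, density=0.8)
        assert len(vs.variants) >= 2000
        result = pn_ps_ratio(vs, cds)
        assert result.ratio == pytest.approx(1.0, rel=0.20)

    def test_purifying_selection_depresses_ratio(self):
        """gamma=-10 on nonsynonymous sites drives piN/piS below 1 in at
        least 95 of 100 seeded replicates."""
        below = 0
        for seed in range(100):
            vs, cds = self._neutral_panel(seed=seed, n_codons=150,
                                          density=0.4, gamma=-10.0)
            result = pn_ps_ratio(vs, cds)
            if result.defined and result.ratio < 1.0:
                below += 1
        assert below >= 95

    def test_undefined_when_no_synonymous_diversity(self):
        cds = CodingSequence("g", "human", "ATGGATGGG")
        region = plus_strand_region()
        vs = VariantSet([variant(103, ref="G", alt="A")], region).classify(cds)
        result = pn_ps_ratio(vs, cds)
        assert not result.defined
        assert result.ratio is None


class TestDafSpectrum:
    def test_counting_example(self):
        spec = daf_spectrum([(1, 4), (1, 4), (2, 4), (3, 4)], B=100, seed=0)
        assert spec.proportions == pytest.approx([0.5, 0.25, 0.25])

    def test_single_site_degenerate_ci(self):
        spec = daf_spectrum([(2, 4)], B=200, seed=0)
        assert spec.ci_low[1] == spec.ci_high[1] == 1.0

    def test_neutral_law_within_bootstrap_ci(self):
        """10,000 neutral sites at n=4: proportions match 6/11, 3/11,
        2/11 inside the bootstrap interval."""
        rng = np.random.default_rng(11)
        expected = neutral_sfs_expectation(4)
        counts = rng.choice([1, 2, 3], size=10_000, p=expected)
        spec = daf_spectrum([(int(i), 4) for i in counts], B=1000, seed=12)
        assert expected == pytest.approx([6 / 11, 3 / 11, 2 / 11])
        for k in range(3):
            assert spec.ci_low[k] <= expected[k] <= spec.ci_high[k]

    def test_projection_matches_hypergeometric_expectation(self):
        """Sites with more chromosomes contribute their exact
        hypergeometric downsampling distribution (monomorphic mass
        discarded)."""
        spec = daf_spectrum([(2, 8)] * 10, n=4, B=10, seed=0)
        j = np.arange(1, 4)
        expected = stats.hypergeom.pmf(j, 8, 2, 4)
        expected = expected / expected.sum()
        assert spec.proportions == pytest.approx(expected, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(UndefinedValueError):
            daf_spectrum([], B=10, seed=0)

    def test_unpolarizable_sites_counted_not_dropped_silently(self):
        region = plus_strand_region()
        recs = [
            variant(101, ref="T", alt="C"),
            VariantRecord("c", 102, "G", "C", "A", ((0, 1), (1, 1)),
                          unpolarizable=True),
        ]
        vs = VariantSet(recs, region)
        spec = daf_spectrum(vs, B=10, seed=0)
        assert spec.n_unpolarizable == 1
        assert spec.n_sites == 1


class TestExcessRareTest:
    def _spec(self, rare, total, n=10):
        counts = np.zeros(n - 1)
        counts[0] = rare
        counts[1:] = (total - rare) / (n - 2)
        from lncorf.popgen import SfsSpectrum

        return SfsSpectrum(
            n=n, counts=counts, proportions=counts / counts.sum(),
            sd=np.zeros(n - 1), ci_low=counts, ci_high=counts,
            n_sites=total, B=0,
        )

    def test_identical_spectra_p_half(self):
        a = self._spec(30, 100)
        assert excess_rare_test(a, a).p_value == pytest.approx(0.5)

    def test_clear_excess_significant(self):
        r = excess_rare_test(self._spec(80, 100), self._spec(50, 100))
        assert r.p_value < 0.01
        # cross-check against the exact normal two-proportion computation
        pool = 130 / 200
        z = (0.8 - 0.5) / np.sqrt(pool * (1 - pool) * (2 / 100))
        assert r.p_value == pytest.approx(stats.norm.sf(z), rel=1e-9)

    def test_power_under_purifying_selection(self):
        """gamma=-10 nonsyn spectra vs neutral syn spectra: significant
        at alpha=0.05 in >=90% of seeded runs (1,000 sites each)."""
        from lncorf.synthetic_data import sfs_weights

        n = 20
        w_sel = np.array(sfs_weights(n, -10.0))
        w_neu = np.array(sfs_weights(n, 0.0))
        hits = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            sel = rng.choice(np.arange(1, n), size=1000, p=w_sel / w_sel.sum())
            neu = rng.choice(np.arange(1, n), size=1000, p=w_neu / w_neu.sum())
            a = daf_spectrum([(int(i), n) for i in sel], B=50, seed=seed)
            b = daf_spectrum([(int(i), n) for i in neu], B=50, seed=seed)
            if excess_rare_test(a, b).p_value < 0.05:
                hits += 1
        assert hits >= 0.9 * runs


class TestMcTest:
    def test_matches_exact_binomial_tail(self):
        """100 bp exon / 900 bp intron, 10 variants all intronic:
        p ~= 0.9^10 within 3 Monte Carlo standard errors."""
        region = RegionAnnotation(
            "g",
            {
                "CDS": [GenomicInterval("c", 0, 99)],
                "intron": [GenomicInterval("c", 100, 1000)],
            },
            complete_orf=False,
        )
        # pad CDS to 100 with a 1bp UTR so exon length is exactly 100
        region.intervals["UTR"] = [GenomicInterval("c", 99, 100)]
        variants = [variant(100 + 50 * i, contig="c") for i in range(10)]
        vs = VariantSet(variants, region)
        result = exon_intron_mc_test(vs, n_sims=10_000, seed=0)
        exact = stats.binom.cdf(0, 10, 0.1)
        mc_se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(result.p_value - exact) < 3 * mc_se
        assert result.observed_exonic == 0

    def test_all_variants_exonic_upper_tail(self):
        region = RegionAnnotation(
            "g",
            {
                "CDS": [GenomicInterval("c", 0, 90)],
                "intron": [GenomicInterval("c", 100, 1000)],
            },
        )
        variants = [variant(3 * i, contig="c") for i in range(30)]
        vs = VariantSet(variants, region)
        result = exon_intron_mc_test(vs, n_sims=2000, seed=1)
        assert result.p_value > 0.95

    def test_p_in_open_unit_interval(self):
        region = RegionAnnotation(
            "g",
            {
                "CDS": [GenomicInterval("c", 0, 90)],
                "intron": [GenomicInterval("c", 100, 1000)],
            },
        )
        vs = VariantSet([variant(500, contig="c")], region)
        p = exon_intron_mc_test(vs, n_sims=500, seed=2).p_value
        assert 0.0 < p <= 1.0

    def test_zero_length_region_rejected(self):
        region = plus_strand_region()  # no intron
        vs = VariantSet([variant(101)], region)
        with pytest.raises(ValueError):
            exon_intron_mc_test(vs, n_sims=100, seed=0)


class TestNormalizeByIntron:
    def _estimates(self, intron_pi=0.001, cds_pi=0.0005):
        from lncorf.popgen import DiversityEstimate

        return [
            DiversityEstimate("intron", intron_pi, intron_pi, 10, 1000, 4),
            DiversityEstimate("CDS", cds_pi, cds_pi, 5, 1000, 4),
        ]

    def test_simple_normalization(self):
        values = normalize_by_intron(self._estimates())
        assert values["CDS"] == pytest.approx(0.5)
        assert values["intron"] == 1.0

    def test_missing_intron_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_intron(self._estimates()[1:])

    def test_zero_intron_flagged(self):
        with pytest.raises(UndefinedValueError):
            normalize_by_intron(self._estimates(intron_pi=0.0))


def test_neutral_pi_theta_agree():
    """Under neutral placement E[pi] ~ E[theta_w] (within 15%)."""
    cds = generate_coding_sequence(
        SequenceSimConfig(length=3000, gc_target=0.5, ensure_orf=True, seed=7)
    )
    region = RegionAnnotation(
        "g",
        {
            "CDS": [GenomicInterval("c", 0, 3000)],
            "intron": [GenomicInterval("c", 4000, 14000)],
        },
        frame_anchor=0,
    )
    cfg = SelectionConfig(
        n=40,
        sites={"synonymous": 700, "nonsynonymous": 2200, "intron": 10000 // 1},
        cds=cds,
        seed=8,
    )
    vs = simulate_polymorphism(region, cfg)
    estimates = diversity_by_region(vs, classes=("intron",), n=40)
    (intron,) = estimates
    assert intron.pi / intron.theta_w == pytest.approx(1.0, rel=0.15)
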