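import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from lncorf.ortholog_assessment import assess_orf, detect_common_disablers
from lncorf.sequence_features import STOP_CODONS, gc_content
from lncorf.synthetic_data import (
    DEFAULT_SPECIES,
    DEFAULT_TREE,
    DisablerSpec,
    MutationModel,
    SelectionConfig,
    SequenceSimConfig,
    TreeSimConfig,
    evolve_orthologs,
    generate_coding_sequence,
    generate_expression_matrix,
    generate_sequence,
    make_fixture_bundle,
    selection_intensity_factor,
    sfs_weights,
    simulate_polymorphism,
)

OUTGROUPS = tuple(sp for sp in DEFAULT_SPECIES if sp != "human")


class TestGenerateSequence:
    def test_gc_concentrates_around_target(self):
        seq = generate_sequence(
            SequenceSimConfig(length=30_000, gc_target=0.5, seed=1)
        )
        assert 0.48 <= gc_content(seq) <= 0.52

    @pytest.mark.parametrize("gc", [0.3, 0.6])
    def test_gc_target_honoured_with_orf(self, gc):
        seq = generate_sequence(
            SequenceSimConfig(length=30_000, gc_target=gc, ensure_orf=True,
                              seed=2)
        )
        assert abs(gc_content(seq) - gc) < 0.02

    def test_orf_structure(self):
        seq = generate_sequence(
            SequenceSimConfig(length=300, gc_target=0.5, ensure_orf=True,
                              seed=3)
        )
        assert seq.startswith("ATG")
        assert seq[-3:] in STOP_CODONS
        internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
        assert not any(c in STOP_CODONS for c in internal)

    def test_seed_reproducibility(self):
        cfg = SequenceSimConfig(length=600, gc_target=0.4, seed=9)
        assert generate_sequence(cfg) == generate_sequence(cfg)

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            SequenceSimConfig(length=300, gc_target=1.2)


class TestEvolveOrthologs:
    def _ancestor(self, seed=0, codons=100):
        return generate_coding_sequence(
            SequenceSimConfig(length=3 * codons, gc_target=0.5,
                              ensure_orf=True, seed=seed)
        ).seq

    def test_zero_branch_lengths_identical_tips(self):
        tree = "(((((human:0,chimp:0):0,gorilla:0):0,orangutan:0):0,macaque:0):0,mouse:0);"
        anc = self._ancestor()
        sim = evolve_orthologs(anc, TreeSimConfig(newick=tree, seed=1))
        assert all(seq == anc for seq in sim.sequences.values())

    def test_ancestral_disabler_shared_by_all_outgroups(self):
        anc = self._ancestor(seed=4)
        spec = DisablerSpec(clade=OUTGROUPS, codon_position=50,
                            kind="premature_stop")
        sim = evolve_orthologs(anc, TreeSimConfig(disablers=(spec,), seed=5))
        for sp in OUTGROUPS:
            aln = sim.alignments[sp]
            assert aln.rows[50].subject in STOP_CODONS
        # human tip is intact: a valid ORF without internal stops
        human = sim.sequences["human"]
        internal = [human[i : i + 3] for i in range(0, len(human) - 3, 3)]
        assert not any(c in STOP_CODONS for c in internal)

    def test_noiseless_disabler_recovered_downstream(self):
        """With zero mutation the pipeline rules recover every injected
        disabler as a common ancestral disabler."""
        anc = self._ancestor(seed=6)
        spec = DisablerSpec(clade=OUTGROUPS, codon_position=40,
                            kind="premature_stop")
        cfg = TreeSimConfig(
            disablers=(spec,),
            model=MutationModel(point_rate=0.0, indel_rate=0.0),
            seed=7,
        )
        sim = evolve_orthologs(anc, cfg)
        statuses = {
            sp: assess_orf(sim.alignments[sp], query_len_codons=99)
            for sp in OUTGROUPS
        }
        shared, newly = detect_common_disablers(statuses, list(OUTGROUPS))
        assert newly
        assert shared[0].aligned_codon_position == 40

    def test_true_clade_disabler(self):
        anc = self._ancestor(seed=8)
        spec = DisablerSpec(clade=("human", "chimp"), codon_position=30,
                            kind="premature_stop")
        cfg = TreeSimConfig(
            disablers=(spec,),
            model=MutationModel(point_rate=0.0, indel_rate=0.0),
            reject_stops_on_query=False,
            seed=9,
        )
        sim = evolve_orthologs(anc, cfg)
        assert sim.sequences["chimp"][90:93] in STOP_CODONS
        assert sim.sequences["gorilla"][90:93] == anc[90:93]

    def test_non_clade_rejected(self):
        anc = self._ancestor()
        spec = DisablerSpec(clade=("human", "gorilla"), codon_position=10,
                            kind="premature_stop")
        with pytest.raises(ValueError, match="not a clade"):
            evolve_orthologs(anc, TreeSimConfig(disablers=(spec,)))

    def test_substitution_count_matches_poisson_expectation(self):
        """Tip-ancestor differences track mu * years * L within 3 SD."""
        anc = self._ancestor(seed=10, codons=500)
        tree = "(human:0,macaque:40000000);"
        model = MutationModel()
        diffs = []
        for seed in range(8):
            sim = evolve_orthologs(
                anc,
                TreeSimConfig(newick=tree, model=model,
                              reject_stops_on_query=False, seed=seed),
            )
            seq = sim.sequences["macaque"]
            diffs.append(sum(a != b for a, b in zip(anc, seq)))
        lam = model.point_rate * 40e6 * len(anc)
        total = sum(diffs)
        expect = lam * len(diffs)
        # back-substitutions make observed differences slightly fewer
        assert abs(total - expect) < 3 * np.sqrt(expect) + 0.05 * expect

    def test_seed_reproducibility(self):
        anc = self._ancestor(seed=11)
        cfg = TreeSimConfig(seed=12)
        a = evolve_orthologs(anc, cfg)
        b = evolve_orthologs(anc, cfg)
        assert a.sequences == b.sequences


class TestSfsSampler:
    def test_neutral_limit_is_one_over_i(self):
        w = np.array(sfs_weights(6, 0.0))
        assert w == pytest.approx([1, 1 / 2, 1 / 3, 1 / 4, 1 / 5])

    def test_neutral_singleton_fraction_n4(self):
        w = np.array(sfs_weights(4, 0.0))
        p = w / w.sum()
        assert p[0] == pytest.approx(6 / 11)

    def test_selection_skews_towards_singletons(self):
        for n in (4, 20, 134):
            p_neu = np.array(sfs_weights(n, 0.0))
            p_sel = np.array(sfs_weights(n, -10.0))
            assert (
                p_sel[0] / p_sel.sum() > p_neu[0] / p_neu.sum()
            )

    @pytest.mark.parametrize("gamma", [-25.0, -10.0, -1.0, 0.0])
    def test_sampler_converges_to_integrated_target(self, gamma):
        """Empirical spectrum of 100,000 draws is within total variation
        0.03 of the numerically integrated density."""
        n = 12
        w = np.array(sfs_weights(n, gamma))
        p = w / w.sum()
        rng = np.random.default_rng(13)
        draws = rng.choice(n - 1, size=100_000, p=p)
        emp = np.bincount(draws, minlength=n - 1) / 100_000
        assert 0.5 * np.abs(emp - p).sum() < 0.03

    def test_weights_match_independent_quadrature(self):
        """Cross-check the cached integrals against a direct dblquad-free
        re-computation with a different integration variable."""
        n, gamma = 8, -5.0
        mine = np.array(sfs_weights(n, gamma))
        denom = 1.0 - np.exp(-2.0 * gamma)
        ref = []
        for i in range(1, n):
            logC = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)

            def f(q):
                return (
                    np.exp(logC + i * np.log(q) + (n - i) * np.log1p(-q))
                    * (1 - np.exp(-2 * gamma * (1 - q)))
                    / (denom * q * (1 - q))
                )

            val, _ = integrate.quad(f, 1e-12, 1 - 1e-12, limit=400)
            ref.append(val)
        assert mine == pytest.approx(np.array(ref), rel=1e-6)

    def test_selection_reduces_segregating_sites(self):
        assert selection_intensity_factor(134, -10.0) < 0.6
        assert selection_intensity_factor(134, 0.0) == pytest.approx(1.0)


class TestSimulatePolymorphism:
    def _region_and_cds(self, seed=0):
        from lncorf.genome_io import GenomicInterval, RegionAnnotation

        cds = generate_coding_sequence(
            SequenceSimConfig(length=900, gc_target=0.5, ensure_orf=True,
                              seed=seed)
        )
        region = RegionAnnotation(
            "g",
            {
                "CDS": [GenomicInterval("c", 0, 900)],
                "intron": [GenomicInterval("c", 1000, 3000)],
            },
            frame_anchor=0,
        )
        return region, cds

    def test_site_classes_self_consistent(self):
        """Placed variants classify back to the class that sampled them."""
        region, cds = self._region_and_cds()
        cfg = SelectionConfig(
            n=10, sites={"synonymous": 50, "nonsynonymous": 150, "intron": 200},
            cds=cds, seed=1,
        )
        vs = simulate_polymorphism(region, cfg).classify(cds)
        labels = [c.label for c in vs.classifications]
        from collections import Counter

        counts = Counter(labels)
        assert counts["synonymous"] == pytest.approx(50, abs=25)
        assert counts["nonsynonymous"] == pytest.approx(150, abs=40)
        assert counts["noncoding"] == pytest.approx(200, abs=45)
        assert not any(c.unclassifiable for c in vs.classifications)

    def test_neutral_singletons_near_six_elevenths(self):
        from lncorf.popgen import daf_spectrum

        region, cds = self._region_and_cds(seed=2)
        cfg = SelectionConfig(n=4, sites={"intron": 1800}, cds=cds, seed=3)
        vs = simulate_polymorphism(region, cfg)
        spec = daf_spectrum(vs, B=1000, seed=4)
        assert spec.ci_low[0] <= 6 / 11 <= spec.ci_high[0]

    def test_same_seed_identical_vcf_bytes(self, tmp_path):
        from lncorf.genome_io import write_variants

        region, cds = self._region_and_cds(seed=5)
        cfg = SelectionConfig(n=8, sites={"intron": 100}, cds=cds, seed=6)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_variants(simulate_polymorphism(region, cfg).variants, p1)
        write_variants(simulate_polymorphism(region, cfg).variants, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_odd_chromosome_count_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(n=7)


class TestExpressionMatrix:
    def test_zero_noise_profiles_identical_across_species(self):
        sim = generate_expression_matrix(
            ["g1", "g2", "g3", "g4"], species=("human", "macaque"),
            noise=0.0, seed=1,
        )
        from lncorf.expression import tissue_profile_correlation
        import pandas as pd

        a, b = sim.matrices["human"], sim.matrices["macaque"]
        assert np.allclose(a.values, b.values)
        merged = pd.DataFrame(
            {"h": a.iloc[:, 0], "m": b.iloc[:, 0]}
        )
        assert tissue_profile_correlation(merged).loc["h", "m"] == 1.0

    def test_background_exceedance_matches_construction(self):
        from lncorf.expression import BackgroundModel, background_p

        sim = generate_expression_matrix(["g"], seed=2)
        values = sim.background["brain"]
        model = BackgroundModel("brain", values)
        assert background_p(model, 0.2) == pytest.approx(0.02, abs=0.008)

    def test_seeded_reproducibility(self):
        a = generate_expression_matrix(["g1", "g2"], seed=3)
        b = generate_expression_matrix(["g1", "g2"], seed=3)
        assert np.array_equal(
            a.matrices["human"].values, b.matrices["human"].values
        )


class TestFixtureBundle:
    def test_bundle_contents_and_manifest(self, tmp_path):
        bundle = make_fixture_bundle(seed=11, out_dir=tmp_path / "b")
        assert len(bundle.roles) == 9
        assert sorted(set(bundle.roles.values())) == ["control", "de_novo", "dying"]
        # manifest lists every written file with a checksum
        assert "human_orfs.fasta" in bundle.manifest
        assert all(len(h) == 64 for h in bundle.manifest.values())
        listed = set(bundle.manifest)
        on_disk = {
            str(p.relative_to(tmp_path / "b"))
            for p in (tmp_path / "b").rglob("*")
            if p.is_file() and p.name != "manifest.json"
        }
        assert listed == on_disk

    def test_two_seeds_differ_same_schema(self, tmp_path):
        a = make_fixture_bundle(seed=1, out_dir=tmp_path / "a")
        b = make_fixture_bundle(seed=2, out_dir=tmp_path / "b")
        assert set(a.manifest) == set(b.manifest)
        assert a.human_cds.keys() == b.human_cds.keys()
        assert any(
            a.human_cds[g].seq != b.human_cds[g].seq for g in a.human_cds
        )
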