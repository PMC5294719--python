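import numpy as np
import pytest
import scipy.stats

from wgdomega import simulate as sim
from wgdomega.alignment import CodonFrequencies
from wgdomega.codonmodel import CLASS_ORDER
from wgdomega.orthogroups import back_translate_alignment, filter_orthogroups


class TestScenarioSpecs:
    def test_presets_cover_taxonomy(self):
        for name in sim.SCENARIO_NAMES:
            spec = sim.scenario(name)
            assert set(spec.omega_by_class) == set(CLASS_ORDER)

    def test_constant_scenario_requires_equal_omegas(self):
        with pytest.raises(ValueError):
            sim.ScenarioSpec("constant", {"0": 0.1, "a1": 0.2, "b1": 0.1, "a2": 0.1, "b2": 0.1})

    def test_asymmetric_decel_shape(self):
        spec = sim.scenario("asymmetric_decel")
        om = spec.omega_by_class
        assert om["a1"] == om["b1"] and om["a2"] != om["b2"]
        with pytest.raises(ValueError):
            spec.replace(omega_by_class={"0": 0.1, "a1": 0.2, "b1": 0.3, "a2": 0.1, "b2": 0.5})


class TestTopologyGeneration:
    def test_leaf_count_and_labels(self):
        spec = sim.scenario("constant").replace(n_postwgd_species=4, n_nonwgd_species=3)
        _topo, tree = sim.generate_topology(spec, np.random.default_rng(0))
        assert len(tree.leaf_names()) == 2 * 4 + 3
        counts = {}
        for n in tree.postorder():
            if n is not tree:
                counts[n.branch_class] = counts.get(n.branch_class, 0) + 1
        assert counts["a1"] == counts["b1"] == 1
        assert counts["a2"] == counts["b2"] == 6

    def test_determinism_and_seed_sensitivity(self):
        spec = sim.scenario("constant")
        from wgdomega.trees import write_newick

        t1 = sim.generate_topology(spec, np.random.default_rng(9))[1]
        t2 = sim.generate_topology(spec, np.random.default_rng(9))[1]
        t3 = sim.generate_topology(spec, np.random.default_rng(10))[1]
        assert write_newick(t1) == write_newick(t2)
        assert write_newick(t1) != write_newick(t3)

    def test_mean_tree_length_tracks_law(self):
        spec = sim.scenario("constant").replace(
            n_postwgd_species=2, n_nonwgd_species=2, branch_length_law=("exponential", 0.15)
        )
        rng = np.random.default_rng(3)
        totals, n_branches = [], None
        for _ in range(200):
            _t, tree = sim.generate_topology(spec, rng)
            branches = [n for n in tree.postorder() if n is not tree]
            n_branches = len(branches)
            totals.append(sum(n.length for n in branches))
        expected = n_branches * 0.15
        assert np.mean(totals) == pytest.approx(expected, rel=0.1)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            sim.generate_topology(sim.scenario("constant").replace(n_postwgd_species=0))


class TestAlignmentSimulation:
    def test_zero_lengths_copy_root_states(self):
        spec = sim.scenario("constant").replace(
            branch_length_law=("fixed", 0.0), n_codons=50
        )
        _topo, tree = sim.generate_topology(spec, np.random.default_rng(1))
        aln = sim.simulate_alignment(tree, spec, np.random.default_rng(2))
        assert np.all(aln.codons == aln.codons[0])

    def test_deterministic_given_seed(self):
        spec = sim.scenario("symmetric_shift").replace(n_codons=40)
        _topo, tree = sim.generate_topology(spec, np.random.default_rng(5))
        a1 = sim.simulate_alignment(tree, spec, np.random.default_rng(6))
        a2 = sim.simulate_alignment(tree, spec, np.random.default_rng(6))
        assert np.array_equal(a1.codons, a2.codons)

    def test_no_stop_codons_by_construction(self):
        spec = sim.scenario("constant").replace(n_codons=200)
        _topo, tree = sim.generate_topology(spec, np.random.default_rng(7))
        aln = sim.simulate_alignment(tree, spec, np.random.default_rng(8))
        assert aln.codons.min() >= 0  # every state a sense codon

    def test_stationary_frequencies_preserved(self):
        # a long branch pair: observed codon usage should match pi
        spec = sim.scenario("constant").replace(
            n_codons=4000, n_postwgd_species=1, n_nonwgd_species=1,
            branch_length_law=("fixed", 0.3),
        )
        _topo, tree = sim.generate_topology(spec, np.random.default_rng(11))
        aln = sim.simulate_alignment(tree, spec, np.random.default_rng(12))
        # one leaf: its marginal is exactly pi (leaves are correlated through
        # the shared root, so pooling rows would inflate the statistic)
        counts = np.bincount(aln.codons[0], minlength=61)
        expected = np.full(61, counts.sum() / 61)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = scipy.stats.chi2.sf(chi2, 60)
        assert p > 0.01


class TestCohorts:
    def test_scenario_mix_split(self):
        cohort = sim.generate_cohort(
            100,
            {"constant": 0.2, "symmetric_shift": 0.8},
            template=sim.scenario("constant").replace(
                n_codons=3, n_postwgd_species=1, n_nonwgd_species=1
            ),
            seed=0,
        )
        n_const = sum(1 for s in cohort if s.truth.name == "constant")
        assert 10 <= n_const <= 32  # multinomial draw around 20

    def test_byte_identical_reproduction(self):
        kw = dict(
            n_orthogroups=4,
            scenario_mix={"constant": 0.5, "asymmetric_decel": 0.5},
            template=sim.scenario("constant").replace(
                n_codons=20, n_postwgd_species=2, n_nonwgd_species=3
            ),
            seed=7,
        )
        c1, c2 = sim.generate_cohort(**kw), sim.generate_cohort(**kw)
        for s1, s2 in zip(c1, c2):
            assert s1.orthogroup.cds == s2.orthogroup.cds
            assert s1.truth.name == s2.truth.name

    def test_orthogroups_pass_default_filters_and_back_translate(self):
        cohort = sim.generate_cohort(
            3,
            {"constant": 1.0},
            template=sim.scenario("constant").replace(n_codons=30),
            seed=1,
        )
        for s in cohort:
            s.orthogroup.focal_species = "post1"
        kept, discarded = filter_orthogroups([s.orthogroup for s in cohort])
        assert not discarded  # 5 post-WGD pairs + 3 outgroups = 13 sequences
        s = cohort[0]
        aln = back_translate_alignment(
            s.orthogroup.protein_alignment, s.orthogroup.cds
        )
        assert np.array_equal(np.sort(aln.codons, 0), np.sort(s.alignment.codons, 0))

    def test_truth_manifest_is_sufficient(self):
        cohort = sim.generate_cohort(
            5,
            {"asymmetric_decel": 1.0},
            template=sim.scenario("constant").replace(
                n_codons=10, n_postwgd_species=2, n_nonwgd_species=3
            ),
            seed=3,
        )
        manifest = sim.truth_manifest(cohort)
        assert len(manifest) == 5
        assert (manifest.scenario == "asymmetric_decel").all()
        assert (manifest.omega_a2 != manifest.omega_b2).all()

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_cohort(5, {"constant": 0.4}, seed=0)


class TestPropertyTables:
    @staticmethod
    def cohort(n=60, seed=2):
        return sim.generate_cohort(
            n,
            {"constant": 0.5, "symmetric_shift": 0.5},
            template=sim.scenario("constant").replace(
                n_codons=3, n_postwgd_species=2, n_nonwgd_species=3
            ),
            seed=seed,
        )

    def test_two_focal_genes_per_orthogroup(self):
        cohort = self.cohort(10)
        props = sim.generate_property_tables(cohort, seed=0)
        assert len(props) == 20
        assert set(props["copy"]) == {"A", "B"}
        assert (props.abundance > 0).all()
        assert (props.disorder_aa >= 0).all()
        assert (props.fitness <= 1.0 + 1e-9).all()
        assert props.cai.between(0, 1).all()

    def test_category_mean_ratio_detectable(self):
        cohort = self.cohort(120, seed=4)
        effects = sim.PropertyEffects()
        props = sim.generate_property_tables(cohort, effects, seed=5)
        reg = props[props.category == "regulatory"].abundance
        rib = props[props.category == "ribosomal"].abundance
        if len(reg) >= 25 and len(rib) >= 25:
            from wgdomega.assoc import wilcoxon_rank_sum

            _u, p = wilcoxon_rank_sum(reg, rib)
            assert p < 0.05

    def test_zero_coupling_keeps_property_independent_within_category(self):
        # with coupling 0, within-category rank-sum p-values over re-seeded
        # property draws are uniform
        cohort = self.cohort(80, seed=6)
        truth = {s.orthogroup.id: s.truth.name != "constant" for s in cohort}
        pvals = []
        from wgdomega.assoc import wilcoxon_rank_sum

        for rep in range(60):
            props = sim.generate_property_tables(cohort, seed=100 + rep)
            sub = props[props.category == "other"]
            changed = sub[sub.orthogroup.map(truth)].abundance.to_numpy()
            constant = sub[~sub.orthogroup.map(truth)].abundance.to_numpy()
            if len(changed) >= 5 and len(constant) >= 5:
                pvals.append(wilcoxon_rank_sum(changed, constant)[1])
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
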