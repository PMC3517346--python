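import numpy as np
import pytest
from scipy import stats

from paofam.phylogeny import bipartitions, read_newick
from paofam.synthetic_data import (DuplicationScenario, EvolverParams,
                                   SpeciesTree, blosum_exchangeabilities,
                                   default_params,
                                   exchangeability_from_file,
                                   random_species_tree,
                                   realized_rate_distribution,
                                   simulate_family, true_gene_tree)


class TestSpeciesTree:
    def test_random_tree_valid(self):
        sp = random_species_tree(12, seed=1)
        assert len(sp.taxa()) == 12
        assert sp.outgroup_taxon in sp.taxa()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTree.from_newick("((a:1,a:1):1,b:1);", "b")

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTree.from_newick("((a:1,b:-0.5):1,c:1);", "c")

    def test_outgroup_must_be_leaf(self):
        with pytest.raises(ValueError):
            SpeciesTree.from_newick("((a:1,b:1):1,c:1);", "zz")


class TestEvolverParams:
    def test_rate_matrix_valid(self):
        params = default_params()
        q = params.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        assert np.all(q - np.diag(np.diag(q)) >= 0)
        # normalised to one expected substitution per site per unit time
        assert -(params.freqs * np.diag(q)).sum() == pytest.approx(1.0)

    def test_frequency_validation(self):
        ex, fr = blosum_exchangeabilities()
        with pytest.raises(ValueError):
            EvolverParams(ex, fr * 2.0)
        with pytest.raises(ValueError):
            EvolverParams(ex, fr, p_invariant=1.5)

    def test_paml_dat_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        tri = rng.uniform(0.1, 5.0, 190)
        freqs = rng.dirichlet(np.ones(20))
        lines = []
        k = 0
        for i in range(1, 20):
            lines.append(" ".join(f"{tri[k + j]:.6f}" for j in range(i)))
            k += i
        lines.append("")
        lines.append(" ".join(f"{f:.6f}" for f in freqs))
        path = tmp_path / "model.dat"
        path.write_text("\n".join(lines))
        ex, fr = exchangeability_from_file(path)
        assert ex.shape == (20, 20)
        assert np.allclose(ex, ex.T)
        assert fr.sum() == pytest.approx(1.0)
        EvolverParams(ex, fr)  # accepted as a valid model


class TestSimulateFamily:
    def test_zero_branch_lengths_identical_sequences(self):
        sp = random_species_tree(6, seed=3, min_branch=0.0, max_branch=0.0)
        seqs, _ = simulate_family(sp, None, default_params(seed=1),
                                  root_length=80)
        assert len(set(seqs.values())) == 1

    def test_all_invariant_sites_identical_sequences(self):
        sp = random_species_tree(6, seed=4, min_branch=0.5, max_branch=1.0)
        params = default_params(p_invariant=1.0, seed=2)
        seqs, _ = simulate_family(sp, None, params, root_length=80)
        assert len(set(seqs.values())) == 1

    def test_duplication_copy_counts_and_truth_tree(self, dup_family):
        truth = dup_family["truth"]
        clade = dup_family["clade"]
        n_out = 10 - len(clade)
        assert len(dup_family["sequences"]) == n_out + 2 * len(clade)
        # the true tree contains both locus copies of the clade as clades
        gt = read_newick(truth.true_tree)
        leafsets = {frozenset(lf.taxon.label for lf in nd.leaf_iter())
                    for nd in gt.preorder_node_iter()}
        for locus in ("A", "B"):
            assert frozenset(f"{t}_{locus}" for t in clade) in leafsets

    def test_lost_copies_not_emitted(self):
        sp = random_species_tree(6, seed=9)
        taxa = sp.taxa()
        clade = sp.clade_leafset(sp.tree.seed_node)  # duplicate at root
        victim = taxa[2]
        scen = DuplicationScenario(duplication_clade=clade,
                                   lost_copies=frozenset({(victim, "B")}))
        seqs, truth = simulate_family(sp, scen, default_params(seed=5),
                                      root_length=60)
        assert f"{victim}_B" not in seqs
        assert len(seqs) == 2 * len(taxa) - 1
        assert set(truth.records.sequence_id) == set(seqs)

    def test_determinism_byte_identical(self, dup_family):
        seqs2, truth2 = simulate_family(
            dup_family["species"], dup_family["scenario"],
            dup_family["params"], root_length=240)
        assert seqs2 == dup_family["sequences"]
        assert truth2.true_tree == dup_family["truth"].true_tree
        assert truth2.alignment == dup_family["truth"].alignment

    def test_constrained_columns_never_substituted(self, dup_family):
        truth = dup_family["truth"]
        for col in truth.constrained_alignment_columns:
            chars = {row[col] for row in truth.alignment.values()}
            assert "-" not in chars and len(chars) == 1

    def test_extra_exon_only_in_isoform_clade(self, dup_family):
        truth = dup_family["truth"]
        iso = dup_family["iso"]
        carriers = set(truth.records[truth.records.has_extra_exon].taxon)
        assert carriers == set(iso)
        # carriers are longer than their non-exon paralogs
        lens = {r.sequence_id: len(dup_family["sequences"][r.sequence_id])
                for r in truth.records.itertuples()}
        for taxon in iso:
            assert lens[f"{taxon}_A"] > lens[f"{taxon}_B"] - 20

    def test_truth_partitions_sequences(self, dup_family):
        truth = dup_family["truth"]
        assert sorted(truth.records.sequence_id) == \
            sorted(dup_family["sequences"])
        assert set(truth.partition().values()) == {"fam1"}

    def test_empty_scenario_errors(self):
        sp = random_species_tree(3, seed=2)
        scen = DuplicationScenario(
            lost_copies=frozenset((t, "P") for t in sp.taxa()))
        with pytest.raises(ValueError, match="empty scenario"):
            simulate_family(sp, scen, default_params(seed=1), root_length=50)

    def test_root_length_validated(self):
        sp = random_species_tree(3, seed=2)
        with pytest.raises(ValueError):
            simulate_family(sp, None, default_params(), root_length=0)


class TestTrueGeneTree:
    def test_no_duplication_mirrors_species_tree(self):
        sp = random_species_tree(8, seed=11)
        gt = true_gene_tree(sp, DuplicationScenario())
        stripped = {frozenset(l.split("_")[0] for l in bp)
                    for bp in bipartitions(gt)}
        assert stripped == {frozenset(bp) for bp in
                            bipartitions(sp.tree)}


class TestRealizedRates:
    def test_invariant_fraction_matches_p_invariant(self):
        """With p_invariant=0.5 and a long branch, about half the sites
        show zero substitutions (binomial test at alpha=0.01)."""
        params = default_params(p_invariant=0.5, gamma_shape=None, seed=21)
        t = 8.0
        counts = realized_rate_distribution(params, 3000, branch_length=t)
        p0 = 0.5 + 0.5 * np.exp(-t)
        res = stats.binomtest(int((counts == 0).sum()), 3000, p0)
        assert res.pvalue > 0.01

    def test_single_rate_limit_is_poisson(self):
        """With no invariant sites and no gamma spread the counts are
        Poisson: the dispersion index passes a chi-square test."""
        params = default_params(p_invariant=0.0, gamma_shape=None, seed=22)
        counts = realized_rate_distribution(params, 10000, branch_length=2.0)
        n = len(counts)
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1)
        assert lo < disp < hi

    def test_gamma_overdispersion_detected(self):
        params = default_params(p_invariant=0.0, gamma_shape=0.4, seed=23)
        counts = realized_rate_distribution(params, 4000, branch_length=2.0)
        assert counts.var(ddof=1) / counts.mean() > 1.5

    def test_constrained_sites_never_change(self):
        params = default_params(p_invariant=0.0,
                                constrained_columns=frozenset(range(50)),
                                seed=24)
        counts = realized_rate_distribution(params, 500, branch_length=5.0)
        assert np.all(counts[:50] == 0)

    def test_minimum_sites_enforced(self):
        with pytest.raises(ValueError):
            realized_rate_distribution(default_params(), 50)
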