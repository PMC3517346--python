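import math

import numpy as np
import pytest

from paofam.phylogeny import (DistanceMatrix, as_newick, bipartitions,
                              bootstrap_support, build_tree,
                              correct_distance, leaf_labels,
                              neighbor_joining, p_distance,
                              protein_distance, read_newick,
                              root_with_outgroup)
from paofam.synthetic_data import (DuplicationScenario, default_params,
                                   random_species_tree, simulate_family)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        rows = {"a": "MKWME", "b": "MKWME", "c": "MKWME"}
        for corr in ("none", "poisson", "kimura"):
            dm = protein_distance(rows, corr)
            assert np.all(dm.d == 0)

    def test_poisson_closed_form(self):
        assert correct_distance(0.1, "poisson") == \
            pytest.approx(-math.log(0.9))

    def test_correction_ordering(self):
        """kimura >= poisson >= p over the shared domain."""
        for p in np.linspace(0.01, 0.74, 50):
            poisson = correct_distance(p, "poisson")
            kimura = correct_distance(p, "kimura")
            assert kimura >= poisson >= p

    def test_gapped_columns_excluded_pairwise(self):
        assert p_distance("AC-DE", "ACWD-") == pytest.approx(0.0)
        assert p_distance("ACFDE", "ACWDE") == pytest.approx(0.2)

    def test_out_of_domain_errors(self):
        with pytest.raises(ValueError):
            correct_distance(1.0, "poisson")
        with pytest.raises(ValueError):
            correct_distance(0.9, "kimura")


def patristic(tree):
    labs = sorted(l.taxon.label for l in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tx[labs[i]],
                                                       tx[labs[j]])
    return tuple(labs), d


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # unrooted tree (A:1,B:2):3 with (C:4,D:5)
        d = np.array([[0, 3, 8, 9], [3, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], float)
        t = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        assert bipartitions(t) == {frozenset({"C", "D"})}
        _, d2 = patristic(t)
        assert np.allclose(d, d2)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_recovery_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(8, 17))
            sp = random_species_tree(n, seed=int(rng.integers(2**31 - 1)),
                                     min_branch=0.01, max_branch=1.0)
            labels, d = patristic(sp.tree)
            est = neighbor_joining(DistanceMatrix(labels, d))
            assert bipartitions(est) == bipartitions(sp.tree)
            _, d2 = patristic(est)
            assert np.allclose(d, d2, atol=1e-8)

    def test_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        ids = tuple("abcde")
        t1 = neighbor_joining(DistanceMatrix(ids, d))
        t2 = neighbor_joining(DistanceMatrix(ids, d))
        assert as_newick(t1) == as_newick(t2)
        for lf in t1.leaf_node_iter():
            assert lf.edge.length == pytest.approx(0.5)

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(
                ("a", "b"), np.array([[0, 1], [1, 0]], float)))


@pytest.fixture(scope="module")
def deep_split_rows():
    """Alignment with two deeply separated clades, shallow within each."""
    species = random_species_tree(8, seed=31, min_branch=0.02,
                                  max_branch=0.06)
    seqs = {}
    for fam, s in (("x", 100), ("y", 200)):
        fam_seqs, _ = simulate_family(
            species, DuplicationScenario(),
            default_params(p_invariant=0.0, gamma_shape=1.0, seed=s),
            root_length=250)
        for sid, sq in fam_seqs.items():
            seqs[f"{fam}{sid}"] = sq
    from paofam.msa_conservation import progressive_align
    return progressive_align(seqs).rows


class TestBootstrap:
    def test_deep_split_strongly_supported(self, deep_split_rows):
        st = bootstrap_support(deep_split_rows, n_replicates=100, seed=4)
        members = frozenset(k for k in deep_split_rows if k.startswith("x"))
        support = st.support_of(members)
        assert support is not None and support >= 0.99

    def test_single_replicate_supports_binary(self, deep_split_rows):
        st = bootstrap_support(deep_split_rows, n_replicates=1, seed=9)
        assert set(st.supports.values()) <= {0.0, 1.0}

    def test_column_permutation_leaves_tree_unchanged(self, deep_split_rows):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(next(iter(deep_split_rows.values()))))
        shuffled = {k: "".join(v[c] for c in perm)
                    for k, v in deep_split_rows.items()}
        assert bipartitions(build_tree(deep_split_rows)) == \
            bipartitions(build_tree(shuffled))

    def test_supports_within_unit_interval(self, deep_split_rows):
        st = bootstrap_support(deep_split_rows, n_replicates=20, seed=2)
        assert all(0.0 <= v <= 1.0 for v in st.supports.values())


class TestRooting:
    def test_five_taxon_hand_case(self):
        t = read_newick("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        rooted = root_with_outgroup(t, "e")
        root_kids = rooted.seed_node.child_nodes()
        sides = sorted([frozenset(lf.taxon.label for lf in k.leaf_iter())
                        for k in root_kids], key=len)
        assert sides[0] == frozenset({"e"})
        assert sides[1] == frozenset({"a", "b", "c", "d"})

    def test_outgroup_edge_bisected(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:2):1);")
        rooted = root_with_outgroup(t, "d")
        (leaf,) = [lf for lf in rooted.leaf_node_iter()
                   if lf.taxon.label == "d"]
        assert leaf.edge.length == pytest.approx(1.0)

    def test_rerooting_topology_invariant(self):
        t = read_newick("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        r1 = root_with_outgroup(t, "a")
        r2 = root_with_outgroup(r1, "a")
        assert bipartitions(r1) == bipartitions(r2)

    def test_unknown_leaf_errors(self):
        t = read_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="unknown leaf"):
            root_with_outgroup(t, "zzz")


class TestNewickIO:
    def test_round_trip_topology_lengths_supports(self, deep_split_rows,
                                                  tmp_path):
        st = bootstrap_support(deep_split_rows, n_replicates=10, seed=1)
        path = tmp_path / "tree.nwk"
        from paofam.phylogeny import write_newick
        write_newick(st, path)
        back = read_newick(path)
        assert leaf_labels(back) == leaf_labels(st.tree)
        assert bipartitions(back) == bipartitions(st.tree)
        orig = {lf.taxon.label: lf.edge.length
                for lf in st.tree.leaf_node_iter()}
        re = {lf.taxon.label: lf.edge.length
              for lf in back.leaf_node_iter()}
        for k in orig:
            assert re[k] == pytest.approx(orig[k], abs=1e-9)
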