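"""Ground-truth benchmark experiments for every pipeline stage.

Each function builds its own inputs (random instances or simulated
families), runs one pipeline component, and measures agreement with an
*independent* reference: brute-force enumeration for hit chaining,
breadth-first search for clustering, a plain quadratic-space
dynamic-programming rescoring for local alignment, additive matrices with
known generating trees for neighbor joining, and the simulator's event log
for reconciliation, family recovery and conservation.  The reference
implementations here are deliberately naive and share no code with the
components they check.

All functions are deterministic given their seed and return plain dicts
(JSON-ready), so they serve both the test suite and the reproduction
script.
"""

from __future__ import annotations

from itertools import combinations

import dendropy
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .family_builder import (FilterThresholds, HomologyEdge, apply_filters,
                             family_partition, reciprocal_edges,
                             single_linkage_families)
from .hit_chaining import chain_all, chain_hits, hits_conflict
from .msa_conservation import conserved_columns, progressive_align
from .pairwise_search import LocalHit, all_vs_all
from .phylogeny import (DistanceMatrix, bipartitions, bootstrap_support,
                        neighbor_joining, p_distance)
from .reconciliation import reconcile
from .scoring import AA_ORDER, ScoringScheme, encode
from .synthetic_data import (DuplicationScenario, default_params,
                             random_species_tree, simulate_family,
                             true_gene_tree)

AA20 = AA_ORDER[:20]


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2**31 - 1)


# -- hit chaining vs exhaustive enumeration -------------------------------

def _random_hit(rng: np.random.Generator, qid="q", sid="s") -> LocalHit:
    qlen = int(rng.integers(5, 60))
    slen = int(rng.integers(5, 60))
    qs = int(rng.integers(0, 200))
    ss = int(rng.integers(0, 200))
    cols = max(qlen, slen)
    ident = int(rng.integers(1, min(qlen, slen) + 1))
    raw = float(rng.integers(20, 300))
    return LocalHit(qid, sid, (qs, qs + qlen), (ss, ss + slen), raw, ident,
                    cols, raw / 2.0, 1e-12)


def _exhaustive_chain_objective(hits: list[LocalHit]) -> int:
    """Best total aligned length over all non-overlapping subsets, by
    explicit enumeration of every subset."""
    n = len(hits)
    conflict = [[hits_conflict(hits[a], hits[b]) for b in range(n)]
                for a in range(n)]
    weights = [h.query_len + h.subject_len for h in hits]
    best = 0
    for mask in range(1, 1 << n):
        members = [k for k in range(n) if mask >> k & 1]
        if any(conflict[a][b] for a, b in combinations(members, 2)):
            continue
        best = max(best, sum(weights[k] for k in members))
    return best


def chaining_oracle_agreement(n_instances: int = 1000, max_hits: int = 10,
                              seed: int = 0) -> dict:
    rng = np.random.default_rng(_child_seed(seed, 1))
    agree = 0
    for _ in range(n_instances):
        hits = [_random_hit(rng) for _ in range(int(rng.integers(1,
                                                                 max_hits + 1)))]
        chained = chain_hits(hits)
        got = chained.total_aligned_query + chained.total_aligned_subject
        if got == _exhaustive_chain_objective(hits):
            agree += 1
    return {"value": agree / n_instances, "n": n_instances}


# -- single-linkage clustering vs BFS components --------------------------

def _bfs_components(nodes: list[str],
                    edges: list[tuple[str, str]]) -> set[frozenset[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = set()
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], {start}
        seen.add(start)
        while queue:
            x = queue.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    comp.add(y)
                    queue.append(y)
        comps.add(frozenset(comp))
    return comps


def clustering_oracle_agreement(n_graphs: int = 500, n_nodes: int = 30,
                                seed: int = 0) -> dict:
    rng = np.random.default_rng(_child_seed(seed, 2))
    agree = 0
    for _ in range(n_graphs):
        nodes = [f"g{k}" for k in range(n_nodes)]
        edges = []
        homology = []
        for a, b in combinations(range(n_nodes), 2):
            if rng.random() < 0.05:
                edges.append((nodes[a], nodes[b]))
                homology.append(HomologyEdge(nodes[a], nodes[b], True, True))
            elif rng.random() < 0.03:  # one-way only: must NOT merge
                homology.append(HomologyEdge(nodes[a], nodes[b], True,
                                             False))
        fams = single_linkage_families(nodes, homology)
        got = {frozenset(f.members) for f in fams}
        if got == _bfs_components(nodes, edges):
            agree += 1
    return {"value": agree / n_graphs, "n": n_graphs}


# -- local alignment vs naive full-matrix DP ------------------------------

def _gotoh_local_score(a: str, b: str, scoring: ScoringScheme) -> float:
    """Plain-python quadratic-space Gotoh local alignment score."""
    ea, eb = encode(a), encode(b)
    S, go, ge = scoring.matrix, scoring.gap_open, scoring.gap_extend
    n, m = len(ea), len(eb)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1],
                       0.0)
            M[i][j] = S[ea[i - 1]][eb[j - 1]] + prev
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
            if M[i][j] > best:
                best = M[i][j]
    return best


def alignment_oracle_agreement(n_pairs: int = 500, max_len: int = 60,
                               seed: int = 0) -> dict:
    from .pairwise_search import local_align
    scoring = ScoringScheme.blosum62()
    rng = np.random.default_rng(_child_seed(seed, 3))
    agree = 0
    for _ in range(n_pairs):
        a = "".join(AA20[k] for k in rng.integers(0, 20,
                                                  int(rng.integers(5, max_len + 1))))
        b = "".join(AA20[k] for k in rng.integers(0, 20,
                                                  int(rng.integers(5, max_len + 1))))
        hits = local_align(a, b, scoring, max_hits=1)
        got = hits[0].raw_score if hits else 0.0
        if abs(got - _gotoh_local_score(a, b, scoring)) < 1e-9:
            agree += 1
    return {"value": agree / n_pairs, "n": n_pairs}


# -- neighbor joining on additive matrices --------------------------------

def _patristic(tree: dendropy.Tree) -> tuple[tuple[str, ...], np.ndarray]:
    """Leaf-to-leaf path lengths by explicit root-path traversal."""
    paths: dict[str, list[tuple[dendropy.Node, float]]] = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node is not None:
            chain.append((node, node.edge.length or 0.0))
            node = node.parent_node
        paths[leaf.taxon.label] = chain
    labels = tuple(sorted(paths))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            up_i = {id(nd): (k, ln) for k, (nd, ln)
                    in enumerate(paths[labels[i]])}
            total_j = 0.0
            for nd, ln in paths[labels[j]]:
                if id(nd) in up_i:
                    k, _ = up_i[id(nd)]
                    total_i = sum(l for _, l in paths[labels[i]][:k])
                    d[i, j] = d[j, i] = total_i + total_j
                    break
                total_j += ln
    return labels, d


def nj_additive_recovery(n_trees: int = 200, seed: int = 0,
                         min_taxa: int = 8, max_taxa: int = 16) -> dict:
    rng = np.random.default_rng(_child_seed(seed, 4))
    recovered = 0
    for rep in range(n_trees):
        n = int(rng.integers(min_taxa, max_taxa + 1))
        sp = random_species_tree(n, seed=int(rng.integers(2**31 - 1)),
                                 min_branch=0.01, max_branch=1.0)
        labels, d = _patristic(sp.tree)
        est = neighbor_joining(DistanceMatrix(labels, d))
        if bipartitions(est) != bipartitions(sp.tree):
            continue
        _, d2 = _patristic(est)
        if np.allclose(d, d2, atol=1e-8):
            recovered += 1
    return {"value": recovered / n_trees, "n": n_trees}


# -- reconciliation on true gene trees ------------------------------------

def reconciliation_recovery(n_scenarios: int = 200, seed: int = 0) -> dict:
    rng = np.random.default_rng(_child_seed(seed, 5))
    correct = 0
    for _ in range(n_scenarios):
        n = int(rng.integers(8, 13))
        sp = random_species_tree(n, seed=int(rng.integers(2**31 - 1)))
        clades = [sp.clade_leafset(nd)
                  for nd in sp.tree.preorder_internal_node_iter()]
        clades = [c for c in clades if 2 <= len(c) <= n - 1]
        if not clades:
            continue
        clade = clades[int(rng.integers(len(clades)))]
        scen = DuplicationScenario(duplication_clade=clade)
        gt = true_gene_tree(sp, scen)
        rt = reconcile(gt, sp)
        dups = rt.duplication_nodes()
        if len(dups) == 1 and rt.mapped_clade(dups[0]) == clade:
            correct += 1
    return {"value": correct / n_scenarios, "n": n_scenarios}


# -- end-to-end family recovery -------------------------------------------

def _min_within_identity(truth_alignment: dict[str, str]) -> float:
    vals = []
    for a, b in combinations(truth_alignment, 2):
        vals.append(1.0 - p_distance(truth_alignment[a],
                                     truth_alignment[b]))
    return min(vals)


def simulate_two_subfamilies(seed: int, n_taxa: int = 8,
                             root_length: int = 300):
    """Two independently rooted families on one species tree: the
    within-family divergence is moderate (identity well above the 30%
    filter) while between-family pairs are unrelated random proteins."""
    species = random_species_tree(n_taxa, seed=_child_seed(seed, 6),
                                  min_branch=0.02, max_branch=0.08)
    seqs: dict[str, str] = {}
    partition: dict[str, str] = {}
    min_ident = 1.0
    for k, fam in enumerate(("famA", "famB")):
        params = default_params(p_invariant=0.1, gamma_shape=1.0,
                                indel_rate=0.001,
                                seed=_child_seed(seed, 7 + k))
        fam_seqs, truth = simulate_family(species, DuplicationScenario(),
                                          params, root_length=root_length,
                                          family_id=fam)
        min_ident = min(min_ident, _min_within_identity(truth.alignment))
        for sid, s in fam_seqs.items():
            seqs[f"{fam}_{sid}"] = s
            partition[f"{fam}_{sid}"] = fam
    return species, seqs, partition, min_ident


def family_recovery(seed: int = 0, n_taxa: int = 8, root_length: int = 300,
                    n_bootstrap: int = 100) -> dict:
    """Simulate two subfamilies, run search -> chain -> filter -> cluster,
    and compare the recovered partition with truth (adjusted Rand index);
    then check each subfamily is a monophyletic, well-supported clade in
    the bootstrap NJ tree."""
    species, seqs, truth_part, min_ident = simulate_two_subfamilies(
        seed, n_taxa, root_length)
    scoring = ScoringScheme.blosum62()
    hits = all_vs_all(seqs, scoring, evalue_cutoff=1e-10)
    chains = chain_all(hits)
    lengths = {k: len(v) for k, v in seqs.items()}
    passes = apply_filters(chains, lengths, FilterThresholds())
    edges = reciprocal_edges(passes)
    fams = single_linkage_families(lengths, edges)
    got = family_partition(fams)
    ids = sorted(seqs)
    ari = adjusted_rand_score([truth_part[i] for i in ids],
                              [got[i] for i in ids])

    profile = progressive_align(seqs, scoring)
    st = bootstrap_support(profile.rows, n_replicates=n_bootstrap,
                           seed=_child_seed(seed, 9))
    supports = []
    for fam in ("famA", "famB"):
        members = frozenset(i for i in ids if truth_part[i] == fam)
        bps = bipartitions(st.tree)
        all_leaves = frozenset(ids)
        side = members if min(all_leaves) not in members \
            else all_leaves - members
        mono = side in bps
        supports.append(st.supports.get(side, 0.0) if mono else 0.0)
    return {"ari": ari, "min_within_identity": min_ident,
            "min_subfamily_support": min(supports),
            "n_sequences": len(seqs), "n_families": len(fams),
            "n_bootstrap": n_bootstrap,
            "chains": chains, "lengths": lengths}


def threshold_monotonicity(chains, lengths, seed: int = 0) -> dict:
    """Family count as each filter threshold rises on a fixed dataset."""
    ids = sorted(lengths)

    def count(th: FilterThresholds) -> int:
        passes = apply_filters(chains, lengths, th)
        return len(single_linkage_families(ids, reciprocal_edges(passes)))

    grids = {
        "min_identity": [FilterThresholds(min_identity=v)
                         for v in (0.1, 0.3, 0.5, 0.7, 0.9)],
        "min_bitscore": [FilterThresholds(min_bitscore=v)
                         for v in (10, 50, 200, 500, 1000)],
        "min_coverage_both": [FilterThresholds(min_coverage_both=v)
                              for v in (0.2, 0.5, 0.7, 0.9, 0.99)],
    }
    counts = {name: [count(t) for t in ths] for name, ths in grids.items()}
    monotone = all(all(a <= b for a, b in zip(cs, cs[1:]))
                   for cs in counts.values())
    return {"monotone": monotone, "counts": counts}


# -- conservation closed loop ---------------------------------------------

def conservation_closed_loop(seed: int = 0, n_taxa: int = 24,
                             root_length: int = 300,
                             n_constrained: int = 12) -> dict:
    """Plant absolutely constrained columns in a diverged family and check
    the conservation scorer flags exactly those columns at the 90%
    threshold (on the true alignment, isolating the scorer from aligner
    error).  Divergence is deep (tens of expected substitutions per
    unconstrained site over the whole tree) and rates homogeneous, so the
    probability that any unconstrained column stays >= 90% conserved by
    chance is negligible (< 1e-5 per family)."""
    planted = frozenset(range(0, n_constrained * 20, 20))
    params = default_params(p_invariant=0.0, gamma_shape=None,
                            indel_rate=0.001, constrained_columns=planted,
                            seed=_child_seed(seed, 10))
    species = random_species_tree(n_taxa, seed=_child_seed(seed, 11),
                                  min_branch=0.4, max_branch=0.6)
    _, truth = simulate_family(species, DuplicationScenario(), params,
                               root_length=root_length)
    flagged = frozenset(conserved_columns(truth.alignment, threshold=0.90))
    expected = truth.constrained_alignment_columns
    inter = len(flagged & expected)
    union = len(flagged | expected)
    return {"exact_match": flagged == expected,
            "jaccard": inter / union if union else 1.0,
            "n_planted": len(expected), "n_flagged": len(flagged),
            "n_rows": n_taxa, "n_columns": len(
                next(iter(truth.alignment.values())))}
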