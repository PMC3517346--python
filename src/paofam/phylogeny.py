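"""Distance-based phylogeny: corrected protein distances, neighbor-joining,
nonparametric bootstrap support and outgroup rooting.

This is the package's built-in tree builder; externally computed trees
(e.g. maximum-likelihood or Bayesian ones) can be imported as Newick and
used anywhere a tree is expected.  Trees are ``dendropy.Tree`` objects
throughout; bipartitions are handled as frozensets of leaf labels so trees
from different sources compare cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)


def p_distance(row_a: str, row_b: str) -> float:
    """Mismatch fraction over columns where neither row is gapped."""
    used = mism = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        used += 1
        if x != y:
            mism += 1
    if used == 0:
        raise ValueError("no comparable (mutually ungapped) columns")
    return mism / used


def correct_distance(p: float, correction: str) -> float:
    if correction == "none":
        return p
    if correction == "poisson":
        if p >= 1.0:
            raise ValueError(f"p-distance {p} outside Poisson domain")
        return -math.log(1.0 - p)
    if correction == "kimura":
        arg = 1.0 - p - p * p / 5.0
        if arg <= 0.0:
            raise ValueError(f"p-distance {p} outside Kimura domain")
        return -math.log(arg)
    raise ValueError(f"unknown correction: {correction}")


def protein_distance(rows: Mapping[str, str],
                     correction: str = "poisson") -> DistanceMatrix:
    """Pairwise corrected distances from aligned rows (gaps excluded
    pairwise)."""
    ids = tuple(rows)
    if len(ids) < 3:
        raise ValueError("need at least 3 aligned sequences")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = correct_distance(
                p_distance(rows[ids[i]], rows[ids[j]]), correction)
    return DistanceMatrix(ids, d)


# -- neighbor joining -----------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Returns an unrooted tree (trifurcating seed node).  On an additive
    matrix the unique additive tree is recovered exactly, topology and
    branch lengths.  Ties in the Q criterion go to the smallest (i, j)
    index pair; negative branch-length estimates are clamped to zero with
    the deficit moved to the sibling edge.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=lab))
             for lab in dm.ids]
    d = dm.d.copy()
    active = list(range(n))  # indices into `nodes`; d indexed in parallel

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among minima, in current index order
        flat = np.flatnonzero(q == q.min())
        ai, aj = divmod(int(flat[0]), k)
        if ai > aj:
            ai, aj = aj, ai
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        if lj < 0.0:
            li, lj = dij, 0.0
        ni, nj = nodes[active[ai]], nodes[active[aj]]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        # distances from the new node to the others
        new_idx = len(nodes)
        nodes.append(parent)
        drow = np.zeros(len(nodes))
        for am, mi in enumerate(active):
            if am in (ai, aj):
                continue
            drow[mi] = 0.5 * (sub[ai, am] + sub[aj, am] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, :len(drow)] = drow
        d[:len(drow), new_idx] = drow
        active = [m for t, m in enumerate(active) if t not in (ai, aj)]
        active.append(new_idx)

    a, b, c = active
    center = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# -- bipartitions and bootstrap ------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf label is the canonical form, so
    rooted and unrooted versions of the same topology agree.
    """
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


@dataclass
class SupportTree:
    """A tree with per-internal-edge bootstrap support in [0, 1]."""

    tree: dendropy.Tree
    supports: dict[frozenset[str], float]
    n_replicates: int

    def support_of(self, labels: frozenset[str]) -> float | None:
        all_leaves = leaf_labels(self.tree)
        ref = min(all_leaves)
        side = frozenset(labels)
        if ref in side:
            side = all_leaves - side
        return self.supports.get(side)


def build_tree(rows: Mapping[str, str],
               correction: str = "poisson") -> dendropy.Tree:
    return neighbor_joining(protein_distance(rows, correction))


def bootstrap_support(rows: Mapping[str, str], n_replicates: int = 500,
                      seed: int = 0, correction: str = "poisson"
                      ) -> SupportTree:
    """NJ tree on the full alignment plus column-bootstrap edge supports.

    Columns are resampled with replacement per replicate, the tree rebuilt,
    and each internal edge of the full-data tree annotated with the fraction
    of replicate trees containing the same bipartition (also stored as the
    internal node label, the common Newick dialect).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids = list(rows)
    length = len(rows[ids[0]])
    full = build_tree(rows, correction)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(full)}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {sid: "".join(rows[sid][c] for c in cols) for sid in ids}
        try:
            rep = build_tree(resampled, correction)
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    supports = {bp: c / n_replicates for bp, c in counts.items()}
    all_leaves = leaf_labels(full)
    ref = min(all_leaves)
    for node in full.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.label = f"{supports[side]:.3f}"
    return SupportTree(full, supports, n_replicates)


# -- rooting and Newick I/O ----------------------------------------------

def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root on the edge subtending the outgroup leaf, at its midpoint."""
    rooted = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_id:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"unknown leaf: {outgroup_id}")
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def write_newick(tree: dendropy.Tree | SupportTree, path: str | Path) -> None:
    if isinstance(tree, SupportTree):
        tree = tree.tree
    Path(path).write_text(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read Newick from a path or a literal string."""
    text = source if str(source).lstrip().startswith("(") \
        else Path(source).read_text()
    return dendropy.Tree.get(data=str(text), schema="newick",
                             preserve_underscores=True)
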