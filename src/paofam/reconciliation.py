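"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the lowest common ancestor (in the species
tree) of the taxa below it.  An internal node whose mapping coincides with
the mapping of at least one of its children is a duplication; otherwise it
is a speciation.  Two genes are paralogs when their gene-tree LCA is a
duplication node and orthologs when it is a speciation node.  No losses or
transfers are modelled; this is the minimal reading sufficient to call the
SMO/APAO split a duplication on the vertebrate stem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

from .phylogeny import SupportTree
from .synthetic_data import SpeciesTree

SPECIATION = "speciation"
DUPLICATION = "duplication"


def default_leaf_taxon_map(gene_tree: dendropy.Tree) -> dict[str, str]:
    """Map ``{taxon}_{locus}`` leaf names to taxa (text before the last
    underscore)."""
    out = {}
    for lf in gene_tree.leaf_node_iter():
        label = lf.taxon.label
        if "_" not in label:
            raise ValueError(f"cannot infer taxon from leaf {label!r}")
        out[label] = label.rsplit("_", 1)[0]
    return out


@dataclass
class ReconciledTree:
    """Rooted gene tree with duplication/speciation labels per internal
    node and, per node, the species-tree clade it maps to."""

    gene_tree: dendropy.Tree
    species_tree: SpeciesTree
    leaf_taxon_map: dict[str, str]
    node_labels: dict[dendropy.Node, str]
    node_mappings: dict[dendropy.Node, dendropy.Node]

    def duplication_nodes(self) -> list[dendropy.Node]:
        return [n for n, lab in self.node_labels.items()
                if lab == DUPLICATION]

    def mapped_clade(self, node: dendropy.Node) -> frozenset[str]:
        sp = self.node_mappings[node]
        return self.species_tree.clade_leafset(sp)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tlabel\tmapped_species\n")
            for node in self.gene_tree.preorder_internal_node_iter():
                leaves = ",".join(sorted(
                    lf.taxon.label for lf in node.leaf_iter()))
                fh.write(f"{leaves}\t{self.node_labels[node]}\t"
                         f"{','.join(sorted(self.mapped_clade(node)))}\n")


def reconcile(gene_tree: dendropy.Tree, species_tree: SpeciesTree,
              leaf_taxon_map: Mapping[str, str] | None = None
              ) -> ReconciledTree:
    """Label gene-tree internal nodes as duplication or speciation."""
    if not gene_tree.is_rooted:
        raise ValueError("root required: reconcile takes a rooted gene tree")
    if leaf_taxon_map is None:
        leaf_taxon_map = default_leaf_taxon_map(gene_tree)

    sp_leaf = {lf.taxon.label: lf
               for lf in species_tree.tree.leaf_node_iter()}
    # species-node depths for LCA walking
    depth: dict[dendropy.Node, int] = {}
    for node in species_tree.tree.preorder_node_iter():
        depth[node] = 0 if node.parent_node is None \
            else depth[node.parent_node] + 1

    def sp_lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if depth[a] < depth[b]:
                b = b.parent_node
            else:
                a = a.parent_node
        return a

    mapping: dict[dendropy.Node, dendropy.Node] = {}
    labels: dict[dendropy.Node, str] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_taxon_map:
                raise ValueError(f"unmapped leaf: {label}")
            taxon = leaf_taxon_map[label]
            if taxon not in sp_leaf:
                raise ValueError(f"unmapped leaf: {label} -> {taxon} not in "
                                 f"species tree")
            mapping[node] = sp_leaf[taxon]
        else:
            kids = node.child_nodes()
            m = mapping[kids[0]]
            for k in kids[1:]:
                m = sp_lca(m, mapping[k])
            mapping[node] = m
            labels[node] = DUPLICATION if any(
                mapping[k] is m for k in kids) else SPECIATION
    return ReconciledTree(gene_tree, species_tree, dict(leaf_taxon_map),
                          labels, mapping)


# -- pairwise homology calls ----------------------------------------------

ORTHOLOG = "ortholog"
PARALOG = "paralog"


@dataclass(frozen=True)
class HomologyCall:
    gene_a: str
    gene_b: str
    relation: str  # ortholog | paralog


def classify_pairs(rt: ReconciledTree) -> list[HomologyCall]:
    """One ortholog/paralog call per unordered gene-leaf pair, from the
    label of the pair's gene-tree LCA."""
    leaves = sorted(rt.gene_tree.leaf_node_iter(),
                    key=lambda n: n.taxon.label)
    # ancestor chains for LCA-by-walking
    parent = {n: n.parent_node for n in rt.gene_tree.preorder_node_iter()}
    gdepth: dict[dendropy.Node, int] = {}
    for node in rt.gene_tree.preorder_node_iter():
        gdepth[node] = 0 if parent[node] is None else gdepth[parent[node]] + 1

    def lca(a, b):
        while a is not b:
            if gdepth[a] < gdepth[b]:
                b = parent[b]
            else:
                a = parent[a]
        return a

    calls = []
    for a, b in combinations(leaves, 2):
        anc = lca(a, b)
        rel = PARALOG if rt.node_labels.get(anc) == DUPLICATION else ORTHOLOG
        calls.append(HomologyCall(a.taxon.label, b.taxon.label, rel))
    return calls


def write_pairs(calls: Iterable[HomologyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\trelation\n")
        for c in calls:
            fh.write(f"{c.gene_a}\t{c.gene_b}\t{c.relation}\n")


# -- monophyly ------------------------------------------------------------

def subfamily_monophyly(tree: dendropy.Tree | SupportTree,
                        subsets: Mapping[str, Iterable[str]]
                        ) -> dict[str, tuple[bool, float | None]]:
    """Is each named leaf subset monophyletic, and with what edge support?

    A subset is monophyletic when it equals the leaf set of some node of
    the (rooted) tree; singletons are trivially monophyletic.  Support is
    taken from the subtending edge when the input carries bootstrap
    supports, else None.
    """
    support_tree = tree if isinstance(tree, SupportTree) else None
    t = tree.tree if isinstance(tree, SupportTree) else tree
    clades = {frozenset(lf.taxon.label for lf in node.leaf_iter())
              for node in t.preorder_node_iter()}
    out = {}
    for name, members in subsets.items():
        mset = frozenset(members)
        mono = mset in clades or len(mset) == 1
        sup = None
        if mono and support_tree is not None and len(mset) > 1:
            sup = support_tree.support_of(mset)
        out[name] = (mono, sup)
    return out


def reconciliation_summary(rt: ReconciledTree) -> dict:
    dups = rt.duplication_nodes()
    return {
        "n_internal_nodes": len(rt.node_labels),
        "n_duplications": len(dups),
        "n_speciations": sum(1 for v in rt.node_labels.values()
                             if v == SPECIATION),
        "duplication_mapped_clades": [sorted(rt.mapped_clade(d))
                                      for d in dups],
    }


def write_summary(rt: ReconciledTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(reconciliation_summary(rt), indent=2))
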