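"""Ground-truth protein-family simulator.

Families are evolved along a known rooted species tree under a reversible
amino-acid substitution process with across-site rate heterogeneity: a
proportion ``p_invariant`` of sites never substitutes and the remainder draw
a multiplicative rate from a mean-1 gamma distribution with shape
``gamma_shape`` (the classical I+G model).  The generator supports

* one ancient duplication on a chosen species-tree edge (the proto locus
  ``P`` splits into paralogous loci ``A`` and ``B`` at the top of that
  edge — the SMO/APAO analog),
* per-taxon copy losses,
* absolutely constrained "active-site" columns (rate multiplier 0),
  globally or per paralog locus,
* single-residue insertions/deletions at ``indel_rate`` events per site per
  unit branch length (never touching constrained columns), and
* a clade-restricted extra domain: a fixed-length block appended to one
  locus within a chosen clade, evolving under the same process (the
  alternatively spliced long-isoform exon analog).

Every stochastic draw comes from one seeded generator consumed in a fixed
traversal order, so identical inputs give byte-identical outputs.  The
returned :class:`TruthTable` carries the true gene tree, the true alignment
(from the simulator's own column registry) and per-sequence metadata, so
every downstream stage can be checked against ground truth.

Substitutions are realized site-by-site with exponential waiting times, so
the per-site substitution counts are available exactly (used by
:func:`realized_rate_distribution` to validate the I+G emulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .scoring import AA_ORDER
from .phylogeny import as_newick, read_newick

AA20 = AA_ORDER[:20]


# -- species tree ---------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted binary species tree with branch lengths in expected
    substitutions per site, plus a designated outgroup leaf."""

    tree: dendropy.Tree
    outgroup_taxon: str

    def __post_init__(self) -> None:
        labels = self.taxa()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        if self.outgroup_taxon not in labels:
            raise ValueError("outgroup_taxon must be a leaf")
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("branch lengths must be >= 0")

    def taxa(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        taxa = set(taxa)
        node = self.tree.mrca(taxon_labels=taxa)
        if node is None:
            raise ValueError(f"no MRCA for {sorted(taxa)}")
        return node

    def clade_leafset(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    @classmethod
    def from_newick(cls, source: str | Path,
                    outgroup_taxon: str) -> "SpeciesTree":
        try:
            t = read_newick(source)
        except Exception as exc:  # dendropy raises its own hierarchy
            raise ValueError(f"invalid species tree: {exc}") from exc
        t.is_rooted = True
        return cls(t, outgroup_taxon)


def random_species_tree(n_taxa: int, seed: int, min_branch: float = 0.05,
                        max_branch: float = 0.25,
                        prefix: str = "t") -> SpeciesTree:
    """Random rooted binary tree by sequential pair joining, with uniform
    branch lengths.  The first taxon is the designated outgroup and is
    attached as the basal lineage (sister to all remaining taxa), so
    outgroup rooting of estimated gene trees is consistent with the
    species-tree root."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    labels = [f"{prefix}{k + 1}" for k in range(n_taxa)]
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=lab))
             for lab in labels]
    for nd in nodes:
        nd.edge.length = float(rng.uniform(min_branch, max_branch))
    outgroup = nodes.pop(0)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        p = dendropy.Node()
        p.add_child(a)
        p.add_child(b)
        p.edge.length = float(rng.uniform(min_branch, max_branch))
        nodes.append(p)
    root = dendropy.Node()
    root.add_child(outgroup)
    root.add_child(nodes[0])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    tree.seed_node.edge.length = None
    return SpeciesTree(tree, labels[0])


# -- substitution model ---------------------------------------------------

def blosum_exchangeabilities() -> tuple[np.ndarray, np.ndarray]:
    """Default empirical-style exchangeability matrix.

    Derived from BLOSUM62 log-odds (s_ij = 2**(S_ij / 2), the implied
    target/background odds under uniform backgrounds) with uniform
    stationary frequencies.  Any empirical matrix in PAML ``.dat`` layout
    can be swapped in via :func:`exchangeability_from_file`.
    """
    from .scoring import ScoringScheme
    S = ScoringScheme.blosum62().matrix[:20, :20]
    ex = 2.0 ** (S / 2.0)
    np.fill_diagonal(ex, 0.0)
    freqs = np.full(20, 1.0 / 20.0)
    return ex, freqs


def exchangeability_from_file(path: str | Path
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Load a PAML-style ``.dat`` empirical model file.

    Layout: 19 lower-triangle rows of exchangeabilities (row i has i
    entries, amino acids in ARNDCQEGHILKMFPSTWYV order), then a line of 20
    stationary frequencies.  The matrix is returned reordered to this
    package's alphabetical amino-acid order.
    """
    values: list[float] = []
    for line in Path(path).read_text().split("\n"):
        values.extend(float(v) for v in line.split())
    if len(values) < 190 + 20:
        raise ValueError("not enough values for a 20-state PAML .dat file")
    tri, freqs_in = values[:190], values[190:210]
    paml_order = "ARNDCQEGHILKMFPSTWYV"
    ex_p = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            ex_p[i, j] = ex_p[j, i] = tri[k]
            k += 1
    perm = [paml_order.index(a) for a in AA20]
    ex = ex_p[np.ix_(perm, perm)]
    freqs = np.array([freqs_in[paml_order.index(a)] for a in AA20])
    freqs = freqs / freqs.sum()
    return ex, freqs


@dataclass(frozen=True)
class EvolverParams:
    """Substitution-process parameters (I+G with optional constraints)."""

    exchangeabilities: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    gamma_shape: float | None = 1.0   # None: single rate for variable sites
    p_invariant: float = 0.1
    indel_rate: float = 0.0           # events / site / unit branch length
    constrained_columns: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.freqs, dtype=float)
        if ex.shape != (20, 20) or not np.allclose(ex, ex.T):
            raise ValueError("exchangeabilities must be 20x20 symmetric")
        if np.any(ex < 0):
            raise ValueError("exchangeabilities must be >= 0 off-diagonal")
        if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0):
            raise ValueError("stationary frequencies must sum to 1")
        if not (0.0 <= self.p_invariant <= 1.0):
            raise ValueError("p_invariant must be in [0, 1]")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "freqs", fr)

    def rate_matrix(self) -> np.ndarray:
        """Normalised reversible rate matrix Q (1 expected sub/site/unit
        time at relative rate 1)."""
        q = self.exchangeabilities * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(self.freqs * np.diag(q)).sum()
        return q / scale


def default_params(**overrides) -> EvolverParams:
    ex, fr = blosum_exchangeabilities()
    return EvolverParams(exchangeabilities=ex, freqs=fr, **overrides)


# -- duplication scenario -------------------------------------------------

PROTO_LOCUS = "P"
LOCUS_A = "A"
LOCUS_B = "B"


@dataclass(frozen=True)
class DuplicationScenario:
    """Where the family duplicates, which copies survive, and where the
    extra domain lives.

    ``duplication_clade`` names the taxa whose MRCA's stem edge carries the
    duplication (None: no duplication; the single locus is ``P``).  Losses
    are per (taxon, locus) pairs.  ``locus_constrained`` adds root-column
    indices whose rate drops to 0 inside one paralog's subtree only (the
    subfamily-specific active-site analog).
    """

    duplication_clade: frozenset[str] | None = None
    lost_copies: frozenset[tuple[str, str]] = frozenset()
    isoform_clade: frozenset[str] = frozenset()
    isoform_locus: str = LOCUS_A
    exon_length: int = 40
    exon_anchor: int | None = None    # root-column after which to insert
    locus_constrained: Mapping[str, frozenset[int]] = \
        field(default_factory=dict)

    def loci_for(self, taxon: str, duplicated: bool) -> list[str]:
        loci = [LOCUS_A, LOCUS_B] if duplicated else [PROTO_LOCUS]
        return [lc for lc in loci if (taxon, lc) not in self.lost_copies]


# -- truth ---------------------------------------------------------------

@dataclass
class TruthTable:
    """Per-sequence ground truth plus the simulator's event bookkeeping."""

    records: pd.DataFrame       # sequence_id taxon locus family_id has_extra_exon
    true_tree: str              # Newick, leaves = sequence ids
    alignment: dict[str, str]   # true MSA from the column registry
    constrained_alignment_columns: frozenset[int]
    duplication_taxa: frozenset[str] | None  # leafset under the true dup node
    site_substitutions: dict[int, int]       # column id -> substitution count
    root_column_positions: dict[int, int]    # root site -> alignment column

    def partition(self) -> dict[str, str]:
        return dict(zip(self.records.sequence_id, self.records.family_id))

    def write_tsv(self, path: str | Path) -> None:
        cols = ["sequence_id", "taxon", "locus", "family_id",
                "has_extra_exon"]
        self.records[cols].to_csv(path, sep="\t", index=False)


class _Site:
    __slots__ = ("col", "state", "rate", "constrained")

    def __init__(self, col: int, state: int, rate: float,
                 constrained: bool) -> None:
        self.col = col
        self.state = state
        self.rate = rate
        self.constrained = constrained

    def copy(self) -> "_Site":
        return _Site(self.col, self.state, self.rate, self.constrained)


class _Evolver:
    def __init__(self, params: EvolverParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.Q = params.rate_matrix()
        self.exit_rate = -np.diag(self.Q)
        jump = self.Q / self.exit_rate[:, None]
        np.fill_diagonal(jump, 0.0)
        self.jump = jump
        self.counts: dict[int, int] = {}
        self.next_col = 0
        self.column_order: list[int] = []

    def new_rate(self) -> float:
        p = self.params
        if p.p_invariant > 0 and self.rng.random() < p.p_invariant:
            return 0.0
        if p.gamma_shape is None:
            return 1.0
        a = p.gamma_shape
        return float(self.rng.gamma(a, 1.0 / a))

    def new_site(self, constrained: bool, after_col: int | None) -> _Site:
        col = self.next_col
        self.next_col += 1
        if after_col is None:
            self.column_order.append(col)
        else:
            self.column_order.insert(self.column_order.index(after_col) + 1,
                                     col)
        state = int(self.rng.choice(20, p=self.params.freqs))
        rate = 0.0 if constrained else self.new_rate()
        return _Site(col, state, rate, constrained)

    def root_sequence(self, length: int) -> list[_Site]:
        cset = self.params.constrained_columns
        return [self.new_site(i in cset, None) for i in range(length)]

    def evolve_substitutions(self, site: _Site, t: float) -> None:
        if site.rate <= 0.0 or t <= 0.0:
            return
        state, left = site.state, t
        while True:
            lam = self.exit_rate[state] * site.rate
            dt = float(self.rng.exponential(1.0 / lam))
            if dt > left:
                break
            left -= dt
            state = int(self.rng.choice(20, p=self.jump[state]))
            self.counts[site.col] = self.counts.get(site.col, 0) + 1
        site.state = state

    def evolve_branch(self, sites: list[_Site], t: float) -> None:
        for s in sites:
            self.evolve_substitutions(s, t)
        ir = self.params.indel_rate
        if ir <= 0.0 or t <= 0.0 or not sites:
            return
        n_events = int(self.rng.poisson(ir * t * len(sites)))
        for _ in range(n_events):
            if self.rng.random() < 0.5:  # insertion between positions
                pos = int(self.rng.integers(0, len(sites) + 1))
                after = sites[pos - 1].col if pos > 0 else None
                if after is None:
                    # prepend: register column before the first current one
                    site = self.new_site(False, None)
                    self.column_order.remove(site.col)
                    self.column_order.insert(
                        self.column_order.index(sites[0].col), site.col)
                else:
                    site = self.new_site(False, after)
                self.evolve_substitutions(site,
                                          float(self.rng.uniform(0.0, t)))
                sites.insert(pos, site)
            else:  # deletion of one unconstrained site
                cands = [k for k, s in enumerate(sites) if not s.constrained]
                if not cands:
                    continue
                del sites[cands[int(self.rng.integers(len(cands)))]]


def simulate_family(species_tree: SpeciesTree,
                    scenario: DuplicationScenario | None = None,
                    params: EvolverParams | None = None,
                    root_length: int = 500,
                    family_id: str = "fam1",
                    seed: int | None = None
                    ) -> tuple[dict[str, str], TruthTable]:
    """Evolve one gene family on the species tree.

    Returns ``(sequences, truth)``: one sequence per retained copy per
    taxon, named ``{taxon}_{locus}``, plus the full ground truth.  The
    effective seed is ``seed`` if given, else ``params.seed``.
    """
    if scenario is None:
        scenario = DuplicationScenario()
    if params is None:
        params = default_params()
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    taxa = species_tree.taxa()
    if not taxa:
        raise ValueError("empty scenario")

    dup_node = None
    if scenario.duplication_clade is not None:
        dup_node = species_tree.mrca(scenario.duplication_clade)
    iso_mrca = None
    if scenario.isoform_clade:
        iso_mrca = species_tree.mrca(scenario.isoform_clade)

    rng = np.random.default_rng(params.seed if seed is None else seed)
    ev = _Evolver(params, rng)
    root_sites = ev.root_sequence(root_length)

    # lineage state: locus -> (sites, carries_extra_exon)
    leaves: dict[str, dict[str, tuple[list[_Site], bool]]] = {}

    def apply_locus_constraints(sites: list[_Site], locus: str) -> None:
        extra = scenario.locus_constrained.get(locus)
        if extra:
            for s in sites:
                if s.col in extra:  # root columns share their index as id
                    s.rate = 0.0
                    s.constrained = True

    def duplicate(loci: dict[str, tuple[list[_Site], bool]]) -> None:
        if PROTO_LOCUS not in loci:
            return
        proto, exon = loci.pop(PROTO_LOCUS)
        loci[LOCUS_A] = (proto, exon)
        loci[LOCUS_B] = ([s.copy() for s in proto], exon)
        apply_locus_constraints(loci[LOCUS_A][0], LOCUS_A)
        apply_locus_constraints(loci[LOCUS_B][0], LOCUS_B)

    def insert_exon(loci: dict[str, tuple[list[_Site], bool]]) -> None:
        if scenario.exon_length <= 0:
            return
        target = scenario.isoform_locus if scenario.isoform_locus in loci \
            else (PROTO_LOCUS if PROTO_LOCUS in loci else None)
        if target is None:
            return
        sites, _ = loci[target]
        anchor_pos = len(sites) if scenario.exon_anchor is None \
            else min(scenario.exon_anchor, len(sites))
        after = sites[anchor_pos - 1].col if anchor_pos > 0 else None
        block = []
        for _ in range(scenario.exon_length):
            site = ev.new_site(False, after)
            block.append(site)
            after = site.col
        loci[target] = (sites[:anchor_pos] + block + sites[anchor_pos:],
                        True)

    def walk(node: dendropy.Node,
             loci: dict[str, tuple[list[_Site], bool]]) -> None:
        if node.is_leaf():
            leaves[node.taxon.label] = loci
            return
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            branch_loci = {lc: ([s.copy() for s in sites], exon)
                           for lc, (sites, exon) in loci.items()}
            if dup_node is not None and child is dup_node:
                duplicate(branch_loci)
            if iso_mrca is not None and child is iso_mrca:
                insert_exon(branch_loci)
            for sites, _ in branch_loci.values():
                ev.evolve_branch(sites, t)
            walk(child, branch_loci)

    root_loci: dict[str, tuple[list[_Site], bool]] = {
        PROTO_LOCUS: (root_sites, False)}
    if dup_node is not None and dup_node is species_tree.tree.seed_node:
        duplicate(root_loci)
    if iso_mrca is not None and iso_mrca is species_tree.tree.seed_node:
        insert_exon(root_loci)
    walk(species_tree.tree.seed_node, root_loci)

    dup_taxa = (species_tree.clade_leafset(dup_node)
                if dup_node is not None else None)
    sequences: dict[str, str] = {}
    rows = []
    aln_sites: dict[str, dict[int, str]] = {}
    for taxon in taxa:
        loci = leaves[taxon]
        duplicated = dup_taxa is not None and taxon in dup_taxa
        for locus in scenario.loci_for(taxon, duplicated):
            if locus not in loci:
                continue
            sid = f"{taxon}_{locus}"
            sites, has_exon = loci[locus]
            sequences[sid] = "".join(AA20[s.state] for s in sites)
            aln_sites[sid] = {s.col: AA20[s.state] for s in sites}
            rows.append({"sequence_id": sid, "taxon": taxon, "locus": locus,
                         "family_id": family_id,
                         "has_extra_exon": bool(has_exon)})
    if not sequences:
        raise ValueError("empty scenario")

    used_cols = [c for c in ev.column_order
                 if any(c in m for m in aln_sites.values())]
    alignment = {sid: "".join(m.get(c, "-") for c in used_cols)
                 for sid, m in aln_sites.items()}
    col_pos = {c: k for k, c in enumerate(used_cols)}
    constrained_cols = frozenset(
        col_pos[c] for c in params.constrained_columns if c in col_pos)
    root_positions = {c: col_pos[c] for c in range(root_length)
                      if c in col_pos}

    gene_tree = true_gene_tree(species_tree, scenario)
    truth = TruthTable(pd.DataFrame(rows), as_newick(gene_tree), alignment,
                       constrained_cols, dup_taxa, dict(ev.counts),
                       root_positions)
    return sequences, truth


def true_gene_tree(species_tree: SpeciesTree,
                   scenario: DuplicationScenario) -> dendropy.Tree:
    """The gene tree implied by the scenario: the species tree with the
    duplication node inserted at the top of the duplication edge and lost
    copies pruned; leaves are named ``{taxon}_{locus}``."""
    dup_node = None
    if scenario.duplication_clade is not None:
        dup_node = species_tree.mrca(scenario.duplication_clade)
    dup_taxa = (species_tree.clade_leafset(dup_node)
                if dup_node is not None else None)
    tns = dendropy.TaxonNamespace()

    def build(sp: dendropy.Node, locus: str) -> dendropy.Node | None:
        length = sp.edge.length or 0.0
        if dup_node is not None and sp is dup_node and locus == PROTO_LOCUS:
            kids = [build_subtree(sp, lc) for lc in (LOCUS_A, LOCUS_B)]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].edge.length += length
                return kids[0]
            nd = dendropy.Node()
            nd.label = "DUP"
            for k in kids:
                k.edge.length += length
                nd.add_child(k)
            nd.edge.length = 0.0
            return nd
        return build_subtree(sp, locus, length)

    def build_subtree(sp: dendropy.Node, locus: str,
                      length: float | None = None) -> dendropy.Node | None:
        if length is None:
            length = sp.edge.length or 0.0
        if sp.is_leaf():
            taxon = sp.taxon.label
            if (taxon, locus) in scenario.lost_copies:
                return None
            nd = dendropy.Node(
                taxon=tns.require_taxon(label=f"{taxon}_{locus}"))
            nd.edge.length = length
            return nd
        kids = [build(c, locus) for c in sp.child_nodes()]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].edge.length += length
            return kids[0]
        nd = dendropy.Node()
        for k in kids:
            nd.add_child(k)
        nd.edge.length = length
        return nd

    root = build(species_tree.tree.seed_node, PROTO_LOCUS)
    if root is None:
        raise ValueError("empty scenario")
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def realized_rate_distribution(params: EvolverParams, n_sites: int,
                               branch_length: float = 2.0,
                               seed: int | None = None) -> np.ndarray:
    """Per-site substitution counts on a single branch of the given length.

    Suitable for goodness-of-fit checks of the I+G emulation: with
    ``p_invariant = p`` a fraction p of unconstrained sites shows zero
    substitutions beyond the chance Poisson zeros, and as
    ``gamma_shape`` grows the counts approach a single-rate Poisson.
    """
    if n_sites < 100:
        raise ValueError("n_sites must be >= 100")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    ev = _Evolver(params, rng)
    sites = ev.root_sequence(n_sites)
    for s in sites:
        ev.evolve_substitutions(s, branch_length)
    return np.array([ev.counts.get(s.col, 0) for s in sites])
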