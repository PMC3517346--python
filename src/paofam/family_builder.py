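"""Homology filters, reciprocal (two-way) hits, and single-linkage gene
families.

A chained pair passes the filter when its pooled identity, summed bitscore
and coverage of BOTH sequences clear the thresholds (all inclusive, >=) and
it is not a self pair.  Defaults are identity >= 30%, bitscore >= 50 and
coverage >= 50% of both sequence lengths.  A pair of sequences is a two-way
(reciprocal) hit when both of its directions pass; gene families are the
connected components of the two-way-hit graph, i.e. single-linkage clusters:
start with every sequence in its own family and merge the whole families of
any two sequences linked by a two-way hit until no merge remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .hit_chaining import ChainedPair


@dataclass(frozen=True)
class FilterThresholds:
    min_identity: float = 0.30
    min_bitscore: float = 50.0
    min_coverage_both: float = 0.50
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0, 1]")
        if not (0.0 <= self.min_coverage_both <= 1.0):
            raise ValueError("min_coverage_both must be in [0, 1]")


@dataclass(frozen=True)
class HomologyEdge:
    """Unordered pair with per-direction filter outcomes."""

    id_a: str
    id_b: str
    passed_ab: bool
    passed_ba: bool

    @property
    def two_way(self) -> bool:
        return self.passed_ab and self.passed_ba


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: tuple[str, ...]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def passes_filters(chained: ChainedPair, lengths: Mapping[str, int],
                   thresholds: FilterThresholds) -> bool:
    try:
        qlen = lengths[chained.query_id]
        slen = lengths[chained.subject_id]
    except KeyError as exc:
        raise ValueError(f"unknown sequence length: {exc.args[0]}") from None
    if thresholds.exclude_self and chained.query_id == chained.subject_id:
        return False
    return (chained.combined_identity >= thresholds.min_identity
            and chained.combined_bitscore >= thresholds.min_bitscore
            and chained.total_aligned_query
                >= thresholds.min_coverage_both * qlen
            and chained.total_aligned_subject
                >= thresholds.min_coverage_both * slen)


def apply_filters(chained: Iterable[ChainedPair], lengths: Mapping[str, int],
                  thresholds: FilterThresholds | None = None
                  ) -> dict[tuple[str, str], bool]:
    """Directional pass table: (query_id, subject_id) -> passed."""
    if thresholds is None:
        thresholds = FilterThresholds()
    return {(c.query_id, c.subject_id): passes_filters(c, lengths, thresholds)
            for c in chained}


def reciprocal_edges(pass_table: Mapping[tuple[str, str], bool]
                     ) -> list[HomologyEdge]:
    """One edge per unordered non-self pair seen in the pass table.

    A direction absent from the table counts as not passed, so two_way is
    true only when both directions are present and pass.
    """
    pairs = sorted({tuple(sorted((q, s))) for q, s in pass_table if q != s})
    return [HomologyEdge(a, b, pass_table.get((a, b), False),
                         pass_table.get((b, a), False))
            for a, b in pairs]


class _UnionFind:
    """Union-find with path compression and union by size."""

    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in self.parent}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def single_linkage_families(ids: Iterable[str],
                            edges: Iterable[HomologyEdge]) -> list[GeneFamily]:
    """Connected components of the two-way-hit graph as gene families.

    Families are sorted by their smallest member id and numbered F1, F2, ...
    deterministically; edge order does not affect the partition.
    """
    ids = list(ids)
    uf = _UnionFind(ids)
    known = set(ids)
    for e in edges:
        if e.id_a not in known or e.id_b not in known:
            raise ValueError(f"edge references unknown id: {e.id_a}/{e.id_b}")
        if e.two_way:
            uf.union(e.id_a, e.id_b)
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(uf.find(x), []).append(x)
    families = sorted((tuple(sorted(g)) for g in groups.values()))
    return [GeneFamily(f"F{i + 1}", members)
            for i, members in enumerate(families)]


def family_partition(families: Sequence[GeneFamily]) -> dict[str, str]:
    """Member id -> family id mapping."""
    return {m: f.family_id for f in families for m in f.members}


# -- tabular output -------------------------------------------------------

def write_families(families: Iterable[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tmember_count\tmembers\n")
        for f in families:
            fh.write(f"{f.family_id}\t{len(f.members)}\t"
                     f"{','.join(f.members)}\n")


def write_edges(edges: Iterable[HomologyEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tpassed_ab\tpassed_ba\ttwo_way\n")
        for e in edges:
            fh.write(f"{e.id_a}\t{e.id_b}\t{int(e.passed_ab)}\t"
                     f"{int(e.passed_ba)}\t{int(e.two_way)}\n")


def write_manifest(thresholds: FilterThresholds, path: str | Path,
                   **extra) -> None:
    payload = {"thresholds": asdict(thresholds), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
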