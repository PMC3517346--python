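"""Census and clade analysis of the alternatively spliced "long" isoform.

Works from a table of per-taxon isoform records (taxon, accession, isoform
label), a species tree, and optionally an alignment of the nuclear-domain
blocks.  Provides the presence/absence census, Fitch-parsimony placement of
the gain (and any losses) on the species tree, and mean conservation of
domain blocks within chosen clades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .msa_conservation import AlignmentProfile, column_conservation
from .synthetic_data import SpeciesTree

NO_ISOFORM = "no isoform"


@dataclass(frozen=True)
class IsoformRecord:
    taxon: str
    accession: str
    isoform_label: str

    @property
    def has_long_isoform(self) -> bool:
        return self.isoform_label.strip().lower() != NO_ISOFORM


def read_isoform_records(path: str | Path) -> list[IsoformRecord]:
    """Read a records TSV with columns taxon, accession, isoform_label."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    need = {"taxon", "accession", "isoform_label"}
    if not need.issubset(df.columns):
        raise ValueError(f"records TSV must have columns {sorted(need)}")
    return [IsoformRecord(r.taxon, r.accession, r.isoform_label)
            for r in df.itertuples()]


def census(records: Sequence[IsoformRecord]) -> tuple[int, int]:
    """(number with the long isoform, number without)."""
    with_iso = sum(1 for r in records if r.has_long_isoform)
    return with_iso, len(records) - with_iso


# -- Fitch parsimony on presence/absence ---------------------------------

@dataclass(frozen=True)
class CharacterEvent:
    kind: str                    # "gain" | "loss"
    branch_to: frozenset[str]    # leafset under the child end of the branch


def parsimony_gain(species_tree: SpeciesTree,
                   presence: Mapping[str, bool]
                   ) -> tuple[int, list[CharacterEvent]]:
    """Fitch small parsimony for a binary presence/absence character.

    Returns the minimum number of state changes and the branches carrying
    them under one minimum-change labeling (ambiguous internal states
    resolve to the parent's state; an ambiguous root resolves to absent,
    i.e. the trait is treated as ancestrally absent).
    """
    tree = species_tree.tree
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [t for t in leaves if t not in presence]
    if missing:
        raise ValueError(f"presence undefined for taxa: {missing}")

    state_sets: dict[dendropy.Node, frozenset[bool]] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state_sets[node] = frozenset([bool(presence[node.taxon.label])])
            continue
        sets = [state_sets[c] for c in node.child_nodes()]
        inter = frozenset.intersection(*sets)
        if inter:
            state_sets[node] = inter
        else:
            state_sets[node] = frozenset.union(*sets)
            changes += len(sets) - 1 if len(sets) > 2 else 1

    final: dict[dendropy.Node, bool] = {}
    events: list[CharacterEvent] = []
    for node in tree.preorder_node_iter():
        ss = state_sets[node]
        if node.parent_node is None:
            final[node] = False if False in ss else True
        else:
            p = final[node.parent_node]
            final[node] = p if p in ss else next(iter(sorted(ss)))
            if final[node] != p:
                leafset = frozenset(lf.taxon.label
                                    for lf in node.leaf_iter())
                events.append(CharacterEvent(
                    "gain" if final[node] else "loss", leafset))
    return changes, events


def write_events(events: Iterable[CharacterEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("event\tbranch_to\n")
        for e in events:
            fh.write(f"{e.kind}\t{','.join(sorted(e.branch_to))}\n")


# -- domain-block conservation -------------------------------------------

@dataclass(frozen=True)
class DomainBlock:
    """A named stretch of alignment columns (0-based half-open range)."""

    name: str                   # e.g. "NDA" or "NDB"
    columns: tuple[int, int]


def domain_conservation(profile: AlignmentProfile, block: DomainBlock,
                        clades: Mapping[str, Iterable[str]]
                        ) -> dict[str, float]:
    """Mean per-column conservation of a block within each named clade.

    Rows of a clade absent from the alignment are skipped (a taxon without
    the block simply does not contribute); a clade with no aligned members
    is an error.
    """
    lo, hi = block.columns
    if not (0 <= lo < hi <= profile.n_columns):
        raise ValueError(f"block columns {block.columns} out of range")
    out = {}
    for name, members in clades.items():
        present = [m for m in members if m in profile.rows]
        if not present:
            raise ValueError(f"no aligned members for clade {name}")
        sub = profile.subset(present)
        scores = column_conservation(sub)
        out[name] = float(np.mean(scores[lo:hi]))
    return out


def census_json(records: Sequence[IsoformRecord], path: str | Path) -> None:
    w, wo = census(records)
    Path(path).write_text(json.dumps(
        {"with_long_isoform": w, "without_long_isoform": wo,
         "total": len(records)}, indent=2))
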