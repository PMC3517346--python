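"""Combine multiple local hits for one ordered sequence pair into a single
non-overlapping composite hit.

When a pair of proteins produces several local alignments, the subset of
hits maximising the total alignable length (aligned query residues plus
aligned subject residues), subject to pairwise non-overlap in *both*
coordinate systems, is selected by exact branch-and-bound search.  The
composite is then treated as a single hit downstream: its identity is the
pooled ``sum(identities) / sum(aligned_columns)`` and its bitscore the sum
of member bitscores.

Overlap means sharing at least one residue position in either sequence;
half-open intervals that merely touch do not overlap.  Collinearity between
chained hits is NOT required (``require_collinear`` switches it on).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .pairwise_search import LocalHit

MAX_HITS_PER_PAIR = 64

CHAIN_COLUMNS = ["query_id", "subject_id", "n_hits", "total_aligned_q",
                 "total_aligned_s", "combined_identity", "combined_bitscore"]


@dataclass(frozen=True)
class ChainedPair:
    """The chained, per-ordered-pair summary used by the family filters."""

    query_id: str
    subject_id: str
    selected_hits: tuple[LocalHit, ...]
    total_aligned_query: int
    total_aligned_subject: int
    combined_identity: float
    combined_bitscore: float


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def hits_conflict(h1: LocalHit, h2: LocalHit) -> bool:
    return (_overlap(h1.query_span, h2.query_span)
            or _overlap(h1.subject_span, h2.subject_span))


def chain_hits(hits: Sequence[LocalHit],
               require_collinear: bool = False) -> ChainedPair:
    """Select the non-overlapping subset of hits with the longest total
    alignable region, exactly.

    The objective is sum(query span length + subject span length) over the
    selected subset; ties are broken by higher total raw score, then by the
    lexicographically smallest sorted list of input indices.
    """
    if not hits:
        raise ValueError("no hits")
    qid, sid = hits[0].query_id, hits[0].subject_id
    if any(h.query_id != qid or h.subject_id != sid for h in hits):
        raise ValueError("heterogeneous pair")
    if len(hits) > MAX_HITS_PER_PAIR:
        raise ValueError(f"more than {MAX_HITS_PER_PAIR} hits per pair")

    n = len(hits)
    order = sorted(range(n), key=lambda k: (hits[k].query_span,
                                            hits[k].subject_span, k))
    w = [hits[k].query_len + hits[k].subject_len for k in order]
    conflict = [[False] * n for _ in range(n)]
    for a in range(n):
        for b in range(a + 1, n):
            ha, hb = hits[order[a]], hits[order[b]]
            c = hits_conflict(ha, hb)
            if require_collinear and not c:
                # non-collinear pairs are treated as incompatible
                qa, qb = ha.query_span, hb.query_span
                sa, sb = ha.subject_span, hb.subject_span
                c = not ((qa[1] <= qb[0] and sa[1] <= sb[0])
                         or (qb[1] <= qa[0] and sb[1] <= sa[0]))
            conflict[a][b] = conflict[b][a] = c

    suffix = [0] * (n + 1)
    for k in range(n - 1, -1, -1):
        suffix[k] = suffix[k + 1] + w[k]

    # best = (total_weight, total_raw_score, chosen positions)
    best: list = [-1, -1.0, []]

    def consider(weight: float, raw: float, chosen: list[int]) -> None:
        idxs = sorted(order[p] for p in chosen)
        if (weight, raw) > (best[0], best[1]):
            best[:] = [weight, raw, idxs]
        elif (weight, raw) == (best[0], best[1]) and idxs < best[2]:
            best[2] = idxs

    def dfs(k: int, weight: float, raw: float, chosen: list[int]) -> None:
        if weight + suffix[k] < best[0]:
            return
        if k == n:
            consider(weight, raw, chosen)
            return
        if all(not conflict[k][p] for p in chosen):
            chosen.append(k)
            dfs(k + 1, weight + w[k], raw + hits[order[k]].raw_score, chosen)
            chosen.pop()
        dfs(k + 1, weight, raw, chosen)

    dfs(0, 0.0, 0.0, [])

    selected = tuple(hits[i] for i in best[2])
    tq = sum(h.query_len for h in selected)
    ts = sum(h.subject_len for h in selected)
    cols = sum(h.aligned_columns for h in selected)
    ident = sum(h.identities for h in selected) / cols if cols else 0.0
    bit = sum(h.bitscore for h in selected)
    return ChainedPair(qid, sid, selected, tq, ts, ident, bit)


def chain_all(hit_table: Iterable[LocalHit],
              require_collinear: bool = False) -> list[ChainedPair]:
    """One :class:`ChainedPair` per ordered pair present in the hit table."""
    groups: dict[tuple[str, str], list[LocalHit]] = {}
    for h in hit_table:
        groups.setdefault((h.query_id, h.subject_id), []).append(h)
    return [chain_hits(groups[key], require_collinear=require_collinear)
            for key in sorted(groups)]


def write_chain_table(chains: Iterable[ChainedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CHAIN_COLUMNS) + "\n")
        for c in chains:
            fh.write("\t".join(map(str, [
                c.query_id, c.subject_id, len(c.selected_hits),
                c.total_aligned_query, c.total_aligned_subject,
                f"{c.combined_identity:.4f}",
                f"{c.combined_bitscore:.4f}"])) + "\n")
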