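"""All-against-all local protein alignment (the in-package homology search).

This is an exact Smith-Waterman search with affine gaps.  After the optimal
local alignment of a pair is reported, its aligned residues are masked in
both sequences (they score minus infinity against everything) and the search
repeats, so successive hits for the same pair never overlap.  Raw scores are
converted to bitscores and E-values with the Karlin-Altschul transform held
by the :class:`~paofam.scoring.ScoringScheme`.

Coordinates are 0-based half-open in memory and 1-based inclusive in every
TSV written or read.  A reader for 12-column BLAST tabular output (outfmt 6)
is provided so externally computed searches can be injected into the rest of
the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from ._dp import NEG, affine_align
from .scoring import ScoringScheme, encode

HIT_COLUMNS = ["query_id", "subject_id", "q_start", "q_end", "s_start",
               "s_end", "raw_score", "identities", "aligned_columns",
               "bitscore", "evalue"]


@dataclass(frozen=True)
class LocalHit:
    """One local alignment segment between an ordered pair of proteins.

    Spans are 0-based half-open; ``aligned_columns`` counts every alignment
    column including gap columns.
    """

    query_id: str
    subject_id: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    raw_score: float
    identities: int
    aligned_columns: int
    bitscore: float
    evalue: float

    @property
    def query_len(self) -> int:
        return self.query_span[1] - self.query_span[0]

    @property
    def subject_len(self) -> int:
        return self.subject_span[1] - self.subject_span[0]

    def flipped(self) -> "LocalHit":
        """The same alignment seen from the other sequence's side."""
        return replace(self, query_id=self.subject_id,
                       subject_id=self.query_id,
                       query_span=self.subject_span,
                       subject_span=self.query_span)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate id: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def _hit_from_path(path, qid, sid, seq_a, seq_b, score, scoring):
    qpos = [p for p, _ in path if p is not None]
    spos = [q for _, q in path if q is not None]
    qspan = (qpos[0], qpos[-1] + 1)
    sspan = (spos[0], spos[-1] + 1)
    ident = sum(1 for p, q in path
                if p is not None and q is not None and seq_a[p] == seq_b[q])
    bit = scoring.bitscore(score)
    ev = len(seq_a) * len(seq_b) * 2.0 ** (-bit)
    return LocalHit(qid, sid, qspan, sspan, float(score), ident, len(path),
                    bit, ev)


def local_align(seq_a: str, seq_b: str, scoring: ScoringScheme,
                max_hits: int = 25, query_id: str = "query",
                subject_id: str = "subject",
                min_raw_score: float = 0.0) -> list[LocalHit]:
    """Smith-Waterman local alignments of ``seq_a`` (query) vs ``seq_b``.

    The best local alignment is found, reported, and its aligned residues
    masked in both sequences; the search repeats until ``max_hits`` hits are
    reported or no positively scoring alignment remains.  Hits are returned
    sorted by decreasing raw score and are pairwise non-overlapping in both
    coordinate systems by construction.  ``min_raw_score`` stops the search
    once the best remaining alignment drops below it (successive hit scores
    are non-increasing, so no reportable hit is lost).
    """
    a = encode(seq_a)
    b = encode(seq_b)
    cell = scoring.matrix[a[:, None], b[None, :]].astype(float)
    hits: list[LocalHit] = []
    for _ in range(max_hits):
        score, path = affine_align(cell, scoring.gap_open, scoring.gap_extend,
                                   local=True)
        if not path or score <= 0 or score < min_raw_score:
            break
        hit = _hit_from_path(path, query_id, subject_id, seq_a.upper(),
                             seq_b.upper(), score, scoring)
        hits.append(hit)
        cell[hit.query_span[0]:hit.query_span[1], :] = NEG
        cell[:, hit.subject_span[0]:hit.subject_span[1]] = NEG
    return hits


def all_vs_all(sequences: dict[str, str], scoring: ScoringScheme | None = None,
               evalue_cutoff: float = 1e-10,
               max_hits: int = 25) -> list[LocalHit]:
    """Every ordered pair's local hits with E-value <= ``evalue_cutoff``.

    Self pairs are included here (the downstream filter removes them); the
    reverse direction of each pair is derived by flipping, exploiting the
    symmetry of the scoring scheme.
    """
    if scoring is None:
        scoring = ScoringScheme.blosum62()
    ids = list(sequences)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate id")
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    out: list[LocalHit] = []
    for i, qid in enumerate(ids):
        for sid in ids[i:]:
            m, n = len(sequences[qid]), len(sequences[sid])
            # smallest raw score whose E-value can still pass the cutoff
            min_raw = (math.log2(m * n / evalue_cutoff) * math.log(2.0)
                       + math.log(scoring.K)) / scoring.lam
            hits = local_align(sequences[qid], sequences[sid], scoring,
                               max_hits=max_hits, query_id=qid,
                               subject_id=sid, min_raw_score=min_raw)
            kept = [h for h in hits if h.evalue <= evalue_cutoff]
            out.extend(kept)
            if sid != qid:
                out.extend(h.flipped() for h in kept)
    out.sort(key=lambda h: (h.query_id, h.subject_id, -h.raw_score,
                            h.query_span))
    return out


# -- tabular I/O ---------------------------------------------------------

def write_hit_table(hits: Iterable[LocalHit], path: str | Path) -> None:
    """Write hits as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id,
                h.query_span[0] + 1, h.query_span[1],
                h.subject_span[0] + 1, h.subject_span[1],
                f"{h.raw_score:g}", h.identities, h.aligned_columns,
                f"{h.bitscore:.4f}", f"{h.evalue:.6g}"])) + "\n")


def read_hit_table(path: str | Path) -> list[LocalHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HIT_COLUMNS:
            raise ValueError(f"unexpected hit-table header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(LocalHit(
                f[0], f[1], (int(f[2]) - 1, int(f[3])),
                (int(f[4]) - 1, int(f[5])), float(f[6]), int(f[7]),
                int(f[8]), float(f[9]), float(f[10])))
    return hits


def read_blast_tabular(path: str | Path,
                       scoring: ScoringScheme | None = None) -> list[LocalHit]:
    """Read 12-column BLAST outfmt-6 into :class:`LocalHit` records.

    BLAST reports pident, alignment length and bitscore but not the raw
    score; the raw score is recovered by inverting the Karlin-Altschul
    transform of ``scoring`` and identities from pident * length.
    """
    if scoring is None:
        scoring = ScoringScheme.blosum62()
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError("expected 12 tab-separated columns")
            pident, length = float(f[2]), int(f[3])
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            evalue, bit = float(f[10]), float(f[11])
            raw = (bit * math.log(2.0) + math.log(scoring.K)) / scoring.lam
            hits.append(LocalHit(
                f[0], f[1], (min(qs, qe) - 1, max(qs, qe)),
                (min(ss, se) - 1, max(ss, se)), raw,
                int(round(pident * length / 100.0)), length, bit, evalue))
    return hits
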