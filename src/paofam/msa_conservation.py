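"""Multiple alignment, per-column conservation, consensus sequences and
active-site conservation reports.

The built-in aligner is a basic progressive aligner: a UPGMA guide tree on
pairwise global-alignment identity distances, then profile-profile merges
under affine-gap sum-of-pairs scoring.  It is a surrogate for a production
MSA program, so importing an externally computed alignment (aligned FASTA or
Clustal ``.aln``) is first-class and everything downstream is agnostic to
the alignment's origin.

Conservation of a column is the fraction of rows carrying the single most
frequent residue; by default gaps count in the denominator (a gap is a
mismatch).  A column is "conserved" at the classical 90% threshold when its
score is >= 0.90 (``strict=True`` switches to > 0.90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from scipy.cluster.hierarchy import linkage

from ._dp import affine_align
from .scoring import AA_ORDER, N_SYMBOLS, ScoringScheme, encode

GAP = "-"
_PROFILE_ALPHABET = AA_ORDER + GAP  # 22 symbols; gap scores 0 vs everything
_SYM_INDEX = {c: i for i, c in enumerate(_PROFILE_ALPHABET)}


@dataclass
class AlignmentProfile:
    """An MSA as an ordered id -> gapped-row mapping."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def subset(self, ids: Iterable[str]) -> "AlignmentProfile":
        ids = list(ids)
        missing = [i for i in ids if i not in self.rows]
        if missing:
            raise ValueError(f"unknown row ids: {missing}")
        return AlignmentProfile({i: self.rows[i] for i in ids})

    def reference_map(self, reference_id: str) -> dict[int, int]:
        """Alignment column -> 1-based residue number in the reference row
        (non-gap columns of the reference only)."""
        if reference_id not in self.rows:
            raise ValueError(f"unknown reference id: {reference_id}")
        out: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.rows[reference_id]):
            if ch != GAP:
                pos += 1
                out[col] = pos
        return out


# -- progressive alignment ------------------------------------------------

def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    L = len(rows[0])
    f = np.zeros((L, len(_PROFILE_ALPHABET)))
    for r in rows:
        for c, ch in enumerate(r):
            f[c, _SYM_INDEX[ch]] += 1.0
    return f / len(rows)


def _extended_matrix(scoring: ScoringScheme) -> np.ndarray:
    s = np.zeros((len(_PROFILE_ALPHABET),) * 2)
    s[:N_SYMBOLS, :N_SYMBOLS] = scoring.matrix
    return s  # gap row/column score 0 against everything


def _merge(rows_a: list[tuple[str, str]], rows_b: list[tuple[str, str]],
           s_ext: np.ndarray, scoring: ScoringScheme
           ) -> list[tuple[str, str]]:
    fa = _profile_freqs([r for _, r in rows_a])
    fb = _profile_freqs([r for _, r in rows_b])
    cell = fa @ s_ext @ fb.T
    _, path = affine_align(cell, scoring.gap_open, scoring.gap_extend,
                           local=False)
    cols_a: list[str] = []
    cols_b: list[str] = []
    gap_a = GAP * len(rows_a)
    gap_b = GAP * len(rows_b)
    for i, j in path:
        cols_a.append("".join(r[i] for _, r in rows_a) if i is not None
                      else gap_a)
        cols_b.append("".join(r[j] for _, r in rows_b) if j is not None
                      else gap_b)
    merged = []
    for k, (sid, _) in enumerate(rows_a):
        merged.append((sid, "".join(c[k] for c in cols_a)))
    for k, (sid, _) in enumerate(rows_b):
        merged.append((sid, "".join(c[k] for c in cols_b)))
    return merged


def pairwise_global_identity(seq_a: str, seq_b: str,
                             scoring: ScoringScheme) -> float:
    """Identity (matches / alignment columns) of the global alignment."""
    a, b = encode(seq_a), encode(seq_b)
    cell = scoring.matrix[a[:, None], b[None, :]].astype(float)
    _, path = affine_align(cell, scoring.gap_open, scoring.gap_extend,
                           local=False)
    matches = sum(1 for i, j in path
                  if i is not None and j is not None
                  and seq_a[i].upper() == seq_b[j].upper())
    return matches / len(path)


def progressive_align(sequences: Mapping[str, str],
                      scoring: ScoringScheme | None = None
                      ) -> AlignmentProfile:
    """Progressive MSA; row order of the result equals input order."""
    if scoring is None:
        scoring = ScoringScheme.blosum62()
    ids = list(sequences)
    if len(ids) == 0:
        raise ValueError("no sequences")
    if len(ids) == 1:
        warnings.warn("single sequence: returning identity alignment")
        return AlignmentProfile({ids[0]: sequences[ids[0]].upper()})

    n = len(ids)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_global_identity(sequences[ids[i]],
                                             sequences[ids[j]], scoring)
            condensed.append(1.0 - ident)
    s_ext = _extended_matrix(scoring)
    clusters: dict[int, list[tuple[str, str]]] = {
        k: [(ids[k], sequences[ids[k]].upper())] for k in range(n)}
    if n == 2:
        merged = _merge(clusters[0], clusters[1], s_ext, scoring)
    else:
        for step, (a, b, _, _) in enumerate(linkage(condensed,
                                                    method="average")):
            clusters[n + step] = _merge(clusters.pop(int(a)),
                                        clusters.pop(int(b)), s_ext, scoring)
        merged = clusters[2 * n - 2]
    by_id = dict(merged)
    return AlignmentProfile({sid: by_id[sid] for sid in ids})


# -- conservation, consensus ----------------------------------------------

def column_conservation(profile: AlignmentProfile | Mapping[str, str],
                        gaps_in_denominator: bool = True) -> np.ndarray:
    """Per-column score: count of the most frequent residue / row count.

    With ``gaps_in_denominator=False`` the denominator is the number of
    non-gap rows in the column instead (an all-gap column scores 0).
    """
    rows = profile.rows if isinstance(profile, AlignmentProfile) else profile
    seqs = list(rows.values())
    if not seqs:
        raise ValueError("empty alignment")
    n, L = len(seqs), len(seqs[0])
    scores = np.zeros(L)
    for c in range(L):
        counts: dict[str, int] = {}
        gaps = 0
        for r in seqs:
            ch = r[c]
            if ch == GAP:
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        top = max(counts.values(), default=0)
        denom = n if gaps_in_denominator else (n - gaps)
        scores[c] = top / denom if denom else 0.0
    return scores


def conserved_columns(profile: AlignmentProfile | Mapping[str, str],
                      threshold: float = 0.90, strict: bool = False,
                      gaps_in_denominator: bool = True) -> list[int]:
    """0-based indices of columns whose conservation clears the threshold
    (inclusive >= by default; ``strict=True`` uses >)."""
    scores = column_conservation(profile, gaps_in_denominator)
    if strict:
        return [c for c, s in enumerate(scores) if s > threshold]
    return [c for c, s in enumerate(scores) if s >= threshold - 1e-12]


def majority_residue(profile: AlignmentProfile, column: int) -> str:
    """Most frequent non-gap residue of a column ('' if all gaps); ties
    break alphabetically."""
    counts: dict[str, int] = {}
    for r in profile.rows.values():
        ch = r[column]
        if ch != GAP:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return ""
    top = max(counts.values())
    return min(ch for ch, k in counts.items() if k == top)


def consensus_of(profile: AlignmentProfile,
                 subfamily_ids: Iterable[str] | None = None) -> str:
    """Majority-residue consensus over a row subset.

    Per column: the most frequent non-gap residue (alphabetical tie-break);
    the column is dropped when gap is the majority state (more gaps than
    copies of the top residue).
    """
    sub = profile if subfamily_ids is None else profile.subset(subfamily_ids)
    out = []
    n_rows = len(sub.rows)
    for c in range(sub.n_columns):
        counts: dict[str, int] = {}
        gaps = 0
        for r in sub.rows.values():
            ch = r[c]
            if ch == GAP:
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            continue
        top = max(counts.values())
        if gaps > top:
            continue
        out.append(min(ch for ch, k in counts.items() if k == top))
    return "".join(out)


# -- active-site panels ---------------------------------------------------

@dataclass(frozen=True)
class ActiveSitePanel:
    """Residues of interest in a reference sequence's own numbering."""

    reference_id: str
    positions: tuple[tuple[int, str], ...]  # (1-based residue number, aa)

    def __post_init__(self) -> None:
        nums = [p for p, _ in self.positions]
        if any(p <= 0 for p in nums):
            raise ValueError("residue numbers must be positive")
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")


#: Mouse SMO active-site residues (substrate binding, catalysis and the
#: Glu216/Ser218 polar specificity pocket), in mouse SMO numbering.
MOUSE_SMO_SITES: tuple[tuple[int, str], ...] = (
    (80, "W"), (82, "H"), (200, "Q"), (216, "E"), (218, "S"), (224, "E"),
    (367, "K"), (427, "W"), (482, "Y"), (527, "S"), (528, "T"))

#: Mouse APAO active-site residues, in mouse APAO numbering.
MOUSE_APAO_SITES: tuple[tuple[int, str], ...] = (
    (62, "W"), (64, "H"), (315, "K"), (430, "Y"), (473, "S"), (474, "T"))


@dataclass(frozen=True)
class ActiveSiteReport:
    residue_number: int
    expected_aa: str
    column: int
    score: float
    conserved: bool
    majority_aa: str


def map_active_sites(profile: AlignmentProfile, panel: ActiveSitePanel,
                     subset_ids: Iterable[str] | None = None,
                     threshold: float = 0.90, strict: bool = False
                     ) -> list[ActiveSiteReport]:
    """Conservation status of panel positions within a chosen row subset.

    Panel residue numbers are resolved through the reference row; a mismatch
    between the panel's expected residue and the reference sequence raises
    (guards against numbering drift between panel and alignment).
    """
    refmap = profile.reference_map(panel.reference_id)
    pos_to_col = {pos: col for col, pos in refmap.items()}
    sub = profile if subset_ids is None else profile.subset(subset_ids)
    scores = column_conservation(sub)
    reports = []
    for pos, expected in panel.positions:
        if pos not in pos_to_col:
            raise ValueError(f"panel/reference disagreement: reference has "
                             f"no residue {pos}")
        col = pos_to_col[pos]
        observed = profile.rows[panel.reference_id][col]
        if observed != expected:
            raise ValueError(f"panel/reference disagreement at residue "
                             f"{pos}: expected {expected}, found {observed}")
        s = float(scores[col])
        ok = s > threshold if strict else s >= threshold - 1e-12
        reports.append(ActiveSiteReport(pos, expected, col, s, ok,
                                        majority_residue(sub, col)))
    return reports


# -- I/O ------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str = "fasta") -> AlignmentProfile:
    """Import an externally computed MSA (``fasta`` or ``clustal``)."""
    aln = AlignIO.read(str(path), fmt)
    return AlignmentProfile({rec.id: str(rec.seq).upper() for rec in aln})


def write_alignment(profile: AlignmentProfile, path: str | Path,
                    width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, row in profile.rows.items():
            fh.write(f">{sid}\n")
            for k in range(0, len(row), width):
                fh.write(row[k:k + width] + "\n")


def write_conservation_table(profile: AlignmentProfile, path: str | Path,
                             reference_id: str | None = None,
                             threshold: float = 0.90) -> None:
    scores = column_conservation(profile)
    refmap = (profile.reference_map(reference_id)
              if reference_id is not None else {})
    with open(path, "w") as fh:
        fh.write("column\tref_pos\tscore\tflagged\tmajority_aa\n")
        for c, s in enumerate(scores):
            fh.write(f"{c + 1}\t{refmap.get(c, '')}\t{s:.4f}\t"
                     f"{int(s >= threshold - 1e-12)}\t"
                     f"{majority_residue(profile, c)}\n")
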