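"""Protein scoring schemes and local-alignment statistics.

A :class:`ScoringScheme` bundles a substitution matrix with affine gap
penalties and the Karlin-Altschul parameters (lambda, K) used to convert raw
Smith-Waterman scores into bitscores and E-values:

    bitscore = (lambda * raw_score - ln K) / ln 2
    E        = m * n * 2 ** (-bitscore)

where m and n are the lengths of the two sequences being compared.  The
default parameters are the widely used gapped BLOSUM62-11-1 values
(lambda = 0.267, K = 0.041).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical amino-acid order used for all encoded sequences.  ``X`` is the
#: tolerated unknown residue and scores 0 against everything.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
N_SYMBOLS = len(AA_ORDER)


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as integer indices into :data:`AA_ORDER`.

    Raises ``ValueError`` for an empty sequence or for characters outside
    the 20-letter alphabet plus X.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    try:
        return np.fromiter((AA_INDEX[c] for c in seq.upper()), dtype=np.intp,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid residue: {exc.args[0]!r}") from None


def _matrix_from_biopython(name: str) -> np.ndarray:
    src = substitution_matrices.load(name)
    mat = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=float)
    for i, a in enumerate(AA_ORDER[:20]):
        for j, b in enumerate(AA_ORDER[:20]):
            mat[i, j] = src[a, b]
    # X is neutral: scores 0 against everything, including itself.
    mat[20, :] = 0.0
    mat[:, 20] = 0.0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap penalties + Karlin-Altschul stats.

    Gap convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``
    (the first gapped residue pays the opening penalty).
    """

    matrix: np.ndarray = field(repr=False)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError(f"matrix must be {N_SYMBOLS}x{N_SYMBOLS}")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        object.__setattr__(self, "matrix", m)

    # -- constructors -----------------------------------------------------

    @classmethod
    def blosum62(cls, gap_open: float = 11.0, gap_extend: float = 1.0,
                 lam: float = 0.267, K: float = 0.041) -> "ScoringScheme":
        """Default BLOSUM62 scheme with gapped 11/1 Karlin-Altschul stats."""
        return cls(_matrix_from_biopython("BLOSUM62"), gap_open, gap_extend,
                   lam, K)

    @classmethod
    def blosum50(cls, gap_open: float = 10.0, gap_extend: float = 1.0,
                 lam: float = 0.232, K: float = 0.11) -> "ScoringScheme":
        return cls(_matrix_from_biopython("BLOSUM50"), gap_open, gap_extend,
                   lam, K)

    # -- statistics -------------------------------------------------------

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw_score))


def evalue_of(raw_score: float, m: int, n: int,
              scoring: ScoringScheme) -> tuple[float, float]:
    """Karlin-Altschul transform: raw score -> (bitscore, E-value)."""
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    bit = scoring.bitscore(raw_score)
    return bit, m * n * 2.0 ** (-bit)
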