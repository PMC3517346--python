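"""Affine-gap alignment engine shared by the pairwise search and the
progressive aligner.

The engine works on a precomputed cell-score matrix ``cell[i, j]`` (the score
of aligning position i of A with position j of B), so the same code serves
residue-vs-residue Smith-Waterman and profile-vs-profile sum-of-pairs
alignment.  Recurrences are the standard three-state Gotoh formulation; the
inner loops are vectorised over anti-diagonals.

Gap model: a gap of length L costs ``gap_open + (L-1) * gap_extend``.
Gap-to-gap state switches (an insertion immediately followed by a deletion)
are not modelled, as usual for Gotoh.
"""

from __future__ import annotations

import numpy as np

NEG = -np.inf
_TOL = 1e-9


def _fill(cell: np.ndarray, gap_open: float, gap_extend: float,
          local: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, m = cell.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B: consumes A (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A: consumes B (horizontal)
    if local:
        M[0, :] = 0.0
        M[:, 0] = 0.0
    else:
        M[0, 0] = 0.0
        X[1:, 0] = -(gap_open + np.arange(n) * gap_extend)
        Y[0, 1:] = -(gap_open + np.arange(m) * gap_extend)
    for k in range(2, n + m + 1):
        lo, hi = max(1, k - m), min(n, k - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = k - i
        prev = np.maximum(np.maximum(M[i - 1, j - 1], X[i - 1, j - 1]),
                          Y[i - 1, j - 1])
        if local:
            prev = np.maximum(prev, 0.0)
        M[i, j] = cell[i - 1, j - 1] + prev
        X[i, j] = np.maximum(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
        Y[i, j] = np.maximum(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return M, X, Y


def affine_align(cell: np.ndarray, gap_open: float, gap_extend: float,
                 local: bool) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Optimal affine-gap alignment over a cell-score matrix.

    Returns ``(score, path)``; the path is a list of ``(i, j)`` pairs of
    0-based coordinates into A and B, with ``None`` on the gapped side.
    For ``local=True`` this is the single best local alignment
    (Smith-Waterman); an empty path with score 0.0 means no positive cell.
    Ties are broken deterministically (first end cell in row-major order;
    match preferred over vertical over horizontal predecessor).
    """
    cell = np.asarray(cell, dtype=float)
    n, m = cell.shape
    M, X, Y = _fill(cell, gap_open, gap_extend, local)

    if local:
        flat = int(np.argmax(M))
        i, j = divmod(flat, m + 1)
        score = float(M[i, j])
        if score <= _TOL:
            return 0.0, []
        state = "M"
    else:
        vals = {"M": float(M[n, m]), "X": float(X[n, m]), "Y": float(Y[n, m])}
        best = max(vals.values())
        state = next(s for s in ("M", "X", "Y") if vals[s] >= best - _TOL)
        score = vals[state]
        i, j = n, m

    path: list[tuple[int | None, int | None]] = []
    while True:
        if state == "M":
            path.append((i - 1, j - 1))
            prev_needed = M[i, j] - cell[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if local and prev_needed <= _TOL:
                break
            if M[i, j] >= prev_needed - _TOL:
                state = "M"
            elif X[i, j] >= prev_needed - _TOL:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            path.append((i - 1, None))
            xval = X[i, j]
            state = "M" if M[i - 1, j] - gap_open >= xval - _TOL else "X"
            i -= 1
            if i == 0 and j == 0:
                break
        else:
            path.append((None, j - 1))
            yval = Y[i, j]
            state = "M" if M[i, j - 1] - gap_open >= yval - _TOL else "Y"
            j -= 1
            if i == 0 and j == 0:
                break

    path.reverse()
    return score, path
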