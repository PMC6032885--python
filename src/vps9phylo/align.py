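"""Pairwise and profile alignment kernels.

Two dynamic programs live here:

* :func:`smith_waterman` — local alignment with affine gaps (the BLASTP
  surrogate used by the reciprocal-best-hit screen), scored with BLOSUM62 by
  default and converted to bit scores / E-values by Karlin–Altschul
  statistics (:func:`evalue`).
* :func:`global_profile_align` — global alignment of one query against the
  per-column profile of a fixed backbone alignment.  Backbone columns are
  never split: query residues that would have to be inserted between columns
  are dropped (and counted), so every augmented row has exactly the backbone
  width.

Both DPs are vectorised over anti-diagonals, which keeps a 300x300 protein
alignment in the low-millisecond range without any compiled extension.
Unknown residues (X) score 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import log

import numpy as np
from Bio.Align import substitution_matrices

from .seqs import AA20, SequenceError

# BLASTP-style defaults (conventional gapped BLOSUM62 parameters).
GAP_OPEN = 11.0
GAP_EXTEND = 1.0
LAMBDA = 0.267
K = 0.041
E_MAX = 0.05

_NEG = -1e30

#: residue -> code; X gets code 20 and scores 0 against everything.
CODES = {aa: i for i, aa in enumerate(AA20)}
CODES["X"] = 20


@lru_cache(maxsize=1)
def blosum62() -> np.ndarray:
    """21x21 BLOSUM62 over :data:`AA20` + X, with X scoring 0."""
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            mat[i, j] = raw[a, b]
    return mat


def encode(residues: str) -> np.ndarray:
    try:
        return np.array([CODES[c] for c in residues], dtype=np.intp)
    except KeyError as exc:
        raise SequenceError(f"non-amino-acid character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class HitRecord:
    """A scored local-alignment hit between two sequences."""

    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open on the query
    target_span: tuple[int, int]


def bit_score(raw: float, lam: float = LAMBDA, k: float = K) -> float:
    return (lam * raw - log(k)) / log(2.0)


def evalue(
    raw: float, m: int, n: int, lam: float = LAMBDA, k: float = K
) -> float:
    """Karlin–Altschul expectation: E = m*n*2**(-S') with S' the bit score."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    return m * n * 2.0 ** (-bit_score(raw, lam, k))


def _sw_matrices(ca, cb, sub, gap_open, gap_extend):
    m, n = len(ca), len(cb)
    S = sub[np.ix_(ca, cb)]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)  # gap in a (horizontal)
    F = np.full((m + 1, n + 1), _NEG)  # gap in b (vertical)
    go = gap_open + gap_extend
    for k in range(2, m + n + 1):
        lo = max(1, k - n)
        hi = min(m, k - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = k - i
        E[i, j] = np.maximum(H[i, j - 1] - go, E[i, j - 1] - gap_extend)
        F[i, j] = np.maximum(H[i - 1, j] - go, F[i - 1, j] - gap_extend)
        H[i, j] = np.maximum(
            0.0,
            np.maximum(
                H[i - 1, j - 1] + S[i - 1, j - 1], np.maximum(E[i, j], F[i, j])
            ),
        )
    return H, E, F, S


def _sw_traceback(H, E, F, S, gap_open, gap_extend, end):
    """Walk back from ``end`` in state H; returns the (start_a, start_b)."""
    go = gap_open + gap_extend
    i, j = end
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0.0:
                return i, j
            if H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # vertical: consumes a[i-1]
            if F[i, j] == H[i - 1, j] - go:
                state = "H"
            i -= 1
        else:  # horizontal: consumes b[j-1]
            if E[i, j] == H[i, j - 1] - go:
                state = "H"
            j -= 1


def smith_waterman(
    a: str,
    b: str,
    sub: np.ndarray | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Maximal local alignment score of ``a`` vs ``b`` with affine gaps.

    Returns ``(score, span_a, span_b)`` with 0-based half-open spans.  Ties
    between equally scoring alignments are broken toward the smallest
    ``(start_a, start_b)`` lexicographically; an all-negative comparison
    yields score 0 and empty spans.
    """
    if not a or not b:
        raise SequenceError("both sequences must be non-empty")
    sub = blosum62() if sub is None else sub
    ca, cb = encode(a), encode(b)
    H, E, F, S = _sw_matrices(ca, cb, sub, gap_open, gap_extend)
    best = H.max()
    if best <= 0.0:
        return 0.0, (0, 0), (0, 0)
    ends = np.argwhere(H == best)
    picked = None
    for i, j in ends:
        si, sj = _sw_traceback(H, E, F, S, gap_open, gap_extend, (int(i), int(j)))
        key = (si, sj, int(i), int(j))
        if picked is None or key < picked:
            picked = key
    si, sj, ei, ej = picked
    return float(best), (si, ei), (sj, ej)


# ---------------------------------------------------------------------------
# profile alignment against a fixed-width backbone


def profile_scores(
    backbone_rows: list[str],
    sub: np.ndarray | None = None,
    gap_extend: float = GAP_EXTEND,
) -> np.ndarray:
    """Per-column match scores: ``P[c, r]`` is the score of residue code
    ``r`` at backbone column ``c``.

    The score is the average substitution score of the residue against the
    column's characters, where a gap character in a backbone row contributes
    ``-gap_extend`` to the average.  Column 20 of the residue axis is X,
    scoring 0 everywhere.
    """
    sub = blosum62() if sub is None else sub
    if not backbone_rows:
        raise ValueError("backbone must be non-empty")
    width = len(backbone_rows[0])
    if any(len(r) != width for r in backbone_rows):
        raise ValueError("ragged backbone rows")
    nrows = len(backbone_rows)
    P = np.zeros((width, 21))
    for c in range(width):
        total = np.zeros(21)
        for row in backbone_rows:
            ch = row[c]
            if ch == "-":
                total[:20] += -gap_extend
            else:
                total[:20] += sub[:20, CODES[ch]]
        P[c, :20] = total[:20] / nrows
    return P


def global_profile_align(
    residues: str,
    backbone_rows: list[str],
    sub: np.ndarray | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[str, int, float]:
    """Globally align a sequence to a backbone profile without splitting
    backbone columns.

    Returns ``(augmented_row, n_dropped, score)``: the augmented row has
    exactly the backbone width, with ``-`` at skipped columns; residues that
    would insert between columns are dropped and counted.  Traceback prefers
    match over gap, then the residue-consuming gap over the column-consuming
    gap.
    """
    if not residues:
        raise SequenceError("empty sequence")
    P = profile_scores(backbone_rows, sub, gap_extend)
    codes = encode(residues)
    m, W = len(codes), P.shape[0]
    go = gap_open + gap_extend
    # state matrices: M diag, X consumes a residue (dropped), Y consumes a column
    M = np.full((m + 1, W + 1), _NEG)
    X = np.full((m + 1, W + 1), _NEG)
    Y = np.full((m + 1, W + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -go - (i - 1) * gap_extend
    for j in range(1, W + 1):
        Y[0, j] = -go - (j - 1) * gap_extend
    S = P[:, codes].T  # (m, W): S[i-1, j-1] score of residue i at column j
    for k in range(2, m + W + 1):
        lo = max(1, k - W)
        hi = min(m, k - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = k - i
        prev = np.maximum(M[i - 1, j - 1], np.maximum(X[i - 1, j - 1], Y[i - 1, j - 1]))
        M[i, j] = prev + S[i - 1, j - 1]
        X[i, j] = np.maximum(
            np.maximum(M[i - 1, j], Y[i - 1, j]) - go, X[i - 1, j] - gap_extend
        )
        Y[i, j] = np.maximum(
            np.maximum(M[i, j - 1], X[i, j - 1]) - go, Y[i, j - 1] - gap_extend
        )
    i, j = m, W
    score = max(M[i, j], X[i, j], Y[i, j])
    # traceback: preference M > X (consume residue) > Y (consume column)
    row: list[str] = []
    dropped = 0
    if M[i, j] == score:
        state = "M"
    elif X[i, j] == score:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            row.append(residues[i - 1])
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            dropped += 1
            cur = X[i, j]
            i -= 1
            if M[i, j] - go == cur:
                state = "M"
            elif X[i, j] - gap_extend == cur:
                state = "X"
            else:
                state = "Y"
        else:
            row.append("-")
            cur = Y[i, j]
            j -= 1
            if M[i, j] - go == cur:
                state = "M"
            elif X[i, j] - go == cur:
                state = "X"
            else:
                state = "Y"
    row.reverse()
    return "".join(row), dropped, float(score)
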