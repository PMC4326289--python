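"""Independent oracles used by the test suite.

These deliberately avoid the package's seed-and-extend/banded machinery:
the alignment oracle is an exhaustive semi-global affine-gap DP over the
whole reference (every position, both strands), and the CIGAR re-scorer
walks an alignment path and scores it directly.
"""

from __future__ import annotations

import re

import numpy as np

NEG = np.float32(-1e9)
_COMP = dict(zip("ACGT", "TGCA"))


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _full_dp(read: np.ndarray, ref: np.ndarray, match, mismatch, go, ge):
    """Full (unbanded) semi-global DP; returns M, X, Y matrices (L, G)."""
    L, G = len(read), len(ref)
    M = np.empty((L, G), dtype=np.float32)
    X = np.empty((L, G), dtype=np.float32)
    Y = np.empty((L, G), dtype=np.float32)
    jidx = np.arange(G, dtype=np.float32)

    def row_gap(m_row):
        a = m_row + ge * jidx
        run = np.maximum.accumulate(a)
        x = np.full(G, NEG, dtype=np.float32)
        x[1:] = run[:-1] - go - ge * jidx[1:]
        return x

    sub = np.where(ref == read[0], match, mismatch).astype(np.float32)
    M[0] = sub  # free alignment start anywhere
    Y[0] = NEG
    X[0] = row_gap(M[0])
    for i in range(1, L):
        sub = np.where(ref == read[i], match, mismatch)
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 0] = NEG
        M[i, 1:] = prev[:-1] + sub[1:]
        Y[i] = np.maximum(M[i - 1] - go - ge, Y[i - 1] - ge)
        X[i] = row_gap(M[i])
    return M, X, Y


def oracle_best_score(
    read: str, ref: str, match=1, mismatch=-2, gap_open=-4, gap_extend=-1
) -> tuple[int, list[tuple[str, int]]]:
    """Exhaustive best semi-global score over both strands.

    Returns ``(best_score, [(strand, start), ...])`` with one optimal start
    per optimal end column (distinct alignment endpoints).
    """
    go, ge = -gap_open, -gap_extend
    best = -np.inf
    hits: list[tuple[str, int]] = []
    ref_u8 = np.frombuffer(ref.encode(), dtype=np.uint8)
    for strand in "+-":
        oriented = read if strand == "+" else revcomp(read)
        r = np.frombuffer(oriented.encode(), dtype=np.uint8)
        M, X, Y = _full_dp(r, ref_u8, match, mismatch, go, ge)
        ends = np.maximum(M[-1], Y[-1])
        score = float(ends.max())
        if score > best + 1e-6:
            best = score
            hits = []
        if abs(score - best) <= 1e-6:
            for j in np.flatnonzero(np.abs(ends - score) <= 1e-6):
                start = _trace_start(r, ref_u8, M, X, Y, int(j), match, mismatch, go, ge)
                hits.append((strand, start))
    return int(round(best)), sorted(set(hits))


def _trace_start(read, ref, M, X, Y, j, match, mismatch, go, ge) -> int:
    i = len(read) - 1
    eps = 1e-3
    state = "M" if M[i, j] >= Y[i, j] else "Y"
    while True:
        if state == "M":
            if i == 0:
                return j
            sub = match if ref[j] == read[i] else mismatch
            target = M[i, j] - sub
            if abs(M[i - 1, j - 1] - target) < eps:
                state = "M"
            elif abs(X[i - 1, j - 1] - target) < eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
            j -= 1
        elif state == "X":
            if abs(M[i, j - 1] - go - ge - X[i, j]) < eps:
                state = "M"
            j -= 1
        else:  # Y
            if abs(M[i - 1, j] - go - ge - Y[i, j]) < eps:
                state = "M"
            i -= 1


def cigar_score(
    read: str, ref: str, pos: int, strand: str, cigar: str,
    match=1, mismatch=-2, gap_open=-4, gap_extend=-1,
) -> int:
    """Re-score an alignment path directly from its CIGAR (independent
    check that a reported position/CIGAR realizes a claimed score)."""
    oriented = read if strand == "+" else revcomp(read)
    score = 0
    ri = 0
    gi = pos
    for n, op in re.findall(r"(\d+)([MID])", cigar):
        n = int(n)
        if op == "M":
            for _ in range(n):
                score += match if oriented[ri] == ref[gi] else mismatch
                ri += 1
                gi += 1
        elif op == "I":
            score += gap_open + n * gap_extend
            ri += n
        else:
            score += gap_open + n * gap_extend
            gi += n
    assert ri == len(oriented), "CIGAR does not consume the whole read"
    return score
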