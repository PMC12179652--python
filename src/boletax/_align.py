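"""Low-level alignment kernels for tandem-array detection.

The detector scores a candidate array by locally aligning the sequence
against an *unrolled tiling* of a candidate pattern (the pattern repeated
until it is longer than the scanned window).  This is equivalent to the
classical wraparound dynamic programme over a cyclic pattern, but the
unrolled form is exactly optimal without any in-row fix-up passes.

Codes: A=0, C=1, G=2, T=3; anything else (N, IUPAC ambiguity) = 4 and
scores as a mismatch against every base, including itself.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_fill(seq, tile, w_match, w_mismatch, w_indel):
    """Local alignment of `seq` vs `tile`; returns (best, bi, bj, ptr).

    ptr codes: 0 stop, 1 diagonal, 2 up (tile gap), 3 left (seq gap).
    Ties broken diagonal > up > left so substitutions are preferred to
    indels of equal score.
    """
    n = seq.shape[0]
    m = tile.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        si = seq[i - 1]
        for j in range(1, m + 1):
            tj = tile[j - 1]
            if si == tj and si < 4:
                d = H[i - 1, j - 1] + w_match
            else:
                d = H[i - 1, j - 1] - w_mismatch
            u = H[i - 1, j] - w_indel
            l = H[i, j - 1] - w_indel
            h = np.int32(0)
            p = np.int8(0)
            if d >= h:
                h = d
                p = np.int8(1)
            if u > h:
                h = u
                p = np.int8(2)
            if l > h:
                h = l
                p = np.int8(3)
            if h == 0:
                p = np.int8(0)
            H[i, j] = h
            P[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, P


@njit(cache=True)
def sw_score_only(seq, tile, w_match, w_mismatch, w_indel):
    """Best local alignment score of `seq` vs `tile` (two rolling rows)."""
    n = seq.shape[0]
    m = tile.shape[0]
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        si = seq[i - 1]
        cur[0] = 0
        for j in range(1, m + 1):
            tj = tile[j - 1]
            if si == tj and si < 4:
                d = prev[j - 1] + w_match
            else:
                d = prev[j - 1] - w_mismatch
            u = prev[j] - w_indel
            l = cur[j - 1] - w_indel
            h = np.int32(0)
            if d > h:
                h = d
            if u > h:
                h = u
            if l > h:
                h = l
            cur[j] = h
            if h > best:
                best = h
        prev, cur = cur, prev
    return best


@njit(cache=True)
def traceback(P, bi, bj):
    """Walk pointers from (bi, bj); returns op/seq-pos/tile-pos arrays
    in alignment order (left to right).  Positions are 0-based; -1 marks
    a gap on that side."""
    maxlen = bi + bj
    ops = np.empty(maxlen, dtype=np.int8)
    spos = np.empty(maxlen, dtype=np.int64)
    tpos = np.empty(maxlen, dtype=np.int64)
    k = 0
    i = bi
    j = bj
    while i > 0 and j > 0 and P[i, j] != 0:
        p = P[i, j]
        if p == 1:
            ops[k] = 1
            spos[k] = i - 1
            tpos[k] = j - 1
            i -= 1
            j -= 1
        elif p == 2:
            ops[k] = 2
            spos[k] = i - 1
            tpos[k] = -1
            i -= 1
        else:
            ops[k] = 3
            spos[k] = -1
            tpos[k] = j - 1
            j -= 1
        k += 1
    return ops[:k][::-1].copy(), spos[:k][::-1].copy(), tpos[:k][::-1].copy()


def make_tile(pattern: np.ndarray, min_len: int) -> np.ndarray:
    """Unroll `pattern` cyclically to at least `min_len` codes."""
    p = pattern.shape[0]
    reps = max(1, -(-min_len // p))
    return np.tile(pattern, reps)


@njit(cache=True)
def nw_tiled_best(seq, start, end, tile, w_match, w_mismatch, w_indel):
    """Global-on-segment alignment score of seq[start:end] against a
    pattern tiling, with a free choice of starting phase and end point on
    the tiling side.  Used by the brute-force oracle; the segment itself
    is aligned end to end (no free segment gaps)."""
    L = end - start
    m = tile.shape[0]
    NEG = np.int32(-(10 ** 8))
    prev = np.empty(m + 1, dtype=np.int32)
    cur = np.empty(m + 1, dtype=np.int32)
    for j in range(m + 1):
        prev[j] = 0  # free start anywhere on the tiling
    for i in range(1, L + 1):
        si = seq[start + i - 1]
        cur[0] = NEG
        for j in range(1, m + 1):
            tj = tile[j - 1]
            if si == tj and si < 4:
                d = prev[j - 1] + w_match
            else:
                d = prev[j - 1] - w_mismatch
            u = prev[j] - w_indel
            l = cur[j - 1] - w_indel
            h = d
            if u > h:
                h = u
            if l > h:
                h = l
            cur[j] = h
        prev, cur = cur, prev
    best = NEG
    for j in range(m + 1):
        if prev[j] > best:
            best = prev[j]
    return best


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of two strings
    under unit match/mismatch/gap costs (edit distance), with identity
    defined as matches / alignment length * 100."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ca, cb = encode(a), encode(b)
    n, m = len(ca), len(cb)
    # maximise matches*(big) - edits so the reported identity corresponds
    # to a minimum-edit alignment with maximal matches among those
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = (cb != ca[i - 1]) | (cb >= 4)
        D[i, 1:] = np.minimum(D[i - 1, :-1] + sub, D[i - 1, 1:] + 1)
        # horizontal pass cannot be vectorised
        row = D[i]
        for j in range(1, m + 1):
            if row[j - 1] + 1 < row[j]:
                row[j] = row[j - 1] + 1
    dist = int(D[n, m])
    # alignment length of a minimal-edit alignment: matches + mismatches
    # + gaps; recover via the standard identity len = (n + m + dist_gap)…
    # walk back once to count columns and matches
    i, j = n, m
    cols = 0
    matches = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = 0 if (ca[i - 1] == cb[j - 1] and ca[i - 1] < 4) else 1
            if D[i, j] == D[i - 1, j - 1] + sub:
                matches += 1 - sub
                i -= 1
                j -= 1
                cols += 1
                continue
        if i > 0 and D[i, j] == D[i - 1, j] + 1:
            i -= 1
            cols += 1
            continue
        j -= 1
        cols += 1
    return matches / cols * 100.0
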