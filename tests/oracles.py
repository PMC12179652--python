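"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or
direct definition, sharing no code path with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
from numba import njit

from boletax._align import encode


@njit(cache=True)
def _oracle_pattern_best(seq, pat, wm, wmm, wi):
    """Max over (start, end) of the global-on-segment alignment score of
    seq[start:end] against a tiling of `pat`, free tiling phase at both
    ends.  One forward DP per start; all ends read off each row."""
    n = seq.shape[0]
    p = pat.shape[0]
    m = n + 2 * p
    tile = np.empty(m, np.uint8)
    for j in range(m):
        tile[j] = pat[j % p]
    NEG = -(10 ** 8)
    best = 0
    prev = np.empty(m + 1, np.int64)
    cur = np.empty(m + 1, np.int64)
    for s in range(n):
        for j in range(m + 1):
            prev[j] = 0
        for i in range(s + 1, n + 1):
            si = seq[i - 1]
            cur[0] = NEG
            rowmax = NEG
            for j in range(1, m + 1):
                tj = tile[j - 1]
                if si == tj and si < 4:
                    d = prev[j - 1] + wm
                else:
                    d = prev[j - 1] - wmm
                u = prev[j] - wi
                l = cur[j - 1] - wi
                h = d
                if u > h:
                    h = u
                if l > h:
                    h = l
                cur[j] = h
                if h > rowmax:
                    rowmax = h
            if rowmax > best:
                best = rowmax
            prev, cur = cur, prev
    return best


def brute_force_best_array_score(seq: str, weights, max_period: int = 10) -> int:
    """Exhaustive maximisation over every (start, end, period) with the
    pattern ranging over all substrings of the given period length."""
    codes = encode(seq)
    n = len(codes)
    best = 0
    seen: set[bytes] = set()
    for p in range(1, min(max_period, n) + 1):
        for i in range(n - p + 1):
            pat = codes[i : i + p]
            key = pat.tobytes()
            if key in seen:
                continue
            seen.add(key)
            s = int(
                _oracle_pattern_best(
                    codes, pat, weights.match, weights.mismatch, weights.indel
                )
            )
            if s > best:
                best = s
    return best


def parsimony_informative_columns(rows: list[str]) -> int:
    """Direct per-column application of the definition: >= 2 distinct
    unambiguous states each in >= 2 sequences."""
    count = 0
    for col in zip(*[r.upper() for r in rows]):
        states = [c for c in col if c in "ACGT"]
        distinct_x2 = {s for s in set(states) if states.count(s) >= 2}
        if len(distinct_x2) >= 2:
            count += 1
    return count


def random_join_monophyly_prob(n_leaves: int, pair=(0, 1)) -> Fraction:
    """Exact probability that a fixed leaf pair forms a clade under the
    uniform random-join (coalescent-style) topology process, computed by
    exhaustive recursion over join choices."""
    a, b = pair

    def rec(units: tuple[frozenset, ...]) -> Fraction:
        # a clade {a,b} exists iff at some point the units {a} and {b}
        # (or a unit equal to {a,b}) merge directly
        for u in units:
            if u == frozenset(pair):
                return Fraction(1)
        if len(units) == 1:
            return Fraction(0)
        pairs = list(combinations(range(len(units)), 2))
        total = Fraction(0)
        for i, j in pairs:
            ua, ub = units[i], units[j]
            if (a in ua and b in ub) or (a in ub and b in ua):
                merged_is_pair = ua | ub == frozenset(pair)
                total += Fraction(1) if merged_is_pair else Fraction(0)
                continue
            rest = tuple(u for k, u in enumerate(units) if k not in (i, j))
            total += rec(rest + (ua | ub,))
        return total / len(pairs)

    return rec(tuple(frozenset([k]) for k in range(n_leaves)))


def edit_distance_min_rotation(a: str, b: str) -> int:
    """Minimum Levenshtein distance between `a` and any rotation of `b`
    (independent route via edlib)."""
    import edlib

    return min(
        edlib.align(a, b[r:] + b[:r], task="distance")["editDistance"]
        for r in range(len(b))
    )
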