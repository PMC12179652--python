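"""Parameterised tandem-repeat detection and ITS-insertion profiling.

Detects minisatellite/microsatellite arrays in ITS rDNA under explicit
(match, mismatch, indel) weights, mirroring the weighted-alignment scoring
used for fungal ITS insertion surveys: an array's score is the sum of the
weights over every aligned position of the whole array against the tiled
consensus, so a perfect array of length L scores ``match * L``.  With the
default weights 2-7-7 and minimum score 50 a pure AC dinucleotide run is
reported from 26 bp upward (24 bp scores 48 and is dropped).

Candidate periods are found by exact k-mer recurrence-distance seeding
(k = 5 for periods > 10, exhaustive anchors for periods <= 10) and refined
by optimal local alignment against the unrolled pattern followed by
column-majority consensus refinement.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._align import (
    _DECODE,
    encode,
    global_identity,
    make_tile,
    sw_fill,
    sw_score_only,
    traceback,
)

__all__ = [
    "ScoringWeights",
    "RepeatHit",
    "MarkerRecord",
    "SpeciesInsertionProfile",
    "QualityError",
    "detect_tandem_repeats",
    "best_array_score",
    "two_pass_its_scan",
    "infer_insertion_boundaries",
    "compare_consensus",
    "summarize_species_profiles",
    "WEIGHTS_277",
    "WEIGHTS_235",
]

#: minimum copies an array must span to be reported (Table-style profiles
#: list arrays down to ~1.9 copies; a single pattern copy is not a repeat)
MIN_COPIES = 1.8

#: sequences longer than this use recurrence seeding instead of trying
#: every (anchor, period) pair
_EXHAUSTIVE_MAX_LEN = 60

_SEED_K = 5
_MAX_CANDIDATES = 60


class QualityError(ValueError):
    """Raised when a sequence fails the <=5% non-ATGC quality screen."""


@dataclass(frozen=True)
class ScoringWeights:
    """Weights of the array-vs-tiled-consensus alignment score."""

    match: int = 2
    mismatch: int = 7
    indel: int = 7
    min_score: int = 50
    max_period: int = 500

    def __post_init__(self):
        if self.match <= 0 or self.mismatch <= 0 or self.indel <= 0:
            raise ValueError("match/mismatch/indel weights must be positive")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.match}-{self.mismatch}-{self.indel}"


WEIGHTS_277 = ScoringWeights(2, 7, 7)
WEIGHTS_235 = ScoringWeights(2, 3, 5)


@dataclass(frozen=True)
class RepeatHit:
    """One detected tandem array (0-based half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    percent_matches: int
    percent_indels: int
    score: int

    def overlaps(self, other: "RepeatHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class MarkerRecord:
    """A marker sequence with optional ITS1/5.8S/ITS2 annotation."""

    seq_id: str
    sequence: str
    annotation: dict[str, tuple[int, int]] | None = None
    non_atgc_fraction: float = field(init=False)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        if n:
            bad = sum(1 for c in self.sequence if c not in "ACGT")
            self.non_atgc_fraction = bad / n
        else:
            self.non_atgc_fraction = 0.0
        if self.annotation:
            for region, (s, e) in self.annotation.items():
                if not (0 <= s <= e <= n):
                    raise ValueError(
                        f"annotation {region} [{s},{e}) outside sequence "
                        f"{self.seq_id} of length {n}"
                    )

    def passes_quality(self, max_fraction: float = 0.05) -> bool:
        return self.non_atgc_fraction <= max_fraction


@dataclass
class SpeciesInsertionProfile:
    """One row of a per-species insertion summary table.

    Ranges are (min, max) tuples; ``None`` marks ND (not detected).
    """

    species: str
    region: str
    weights: str
    n_sequences: int
    its_length_range: tuple[int, int] | None
    insertion_size_range: tuple[int, int] | None
    copy_number_range: tuple[float, float] | None
    percent_matches_range: tuple[int, int] | None
    percent_indels_range: tuple[int, int] | None
    consensus_patterns: list[str]
    similarity_range: tuple[float, float] | None

    @property
    def detected(self) -> bool:
        return bool(self.consensus_patterns)


# ---------------------------------------------------------------------------
# candidate generation


def _exhaustive_candidates(n: int, max_period: int):
    cap = min(max_period, n - 1)
    for p in range(1, cap + 1):
        for i in range(0, n - p + 1):
            yield i, p, 0, n


def _small_period_candidates(codes: np.ndarray, max_period: int):
    """Anchors where a unit repeats exactly once adjacently (p <= 10)."""
    n = codes.shape[0]
    out = []
    for p in range(1, min(10, max_period) + 1):
        if 2 * p > n:
            break
        if p == 1:
            pos = np.nonzero(codes[: n - 1] == codes[1:])[0]
        else:
            eq = codes[: n - p] == codes[p:]
            # position i qualifies if eq[i:i+p] all true
            window = np.lib.stride_tricks.sliding_window_view(eq, p)
            pos = np.nonzero(np.all(window, axis=1))[0]
        if pos.size == 0:
            continue
        # cluster positions separated by <= p into one candidate array
        breaks = np.nonzero(np.diff(pos) > p)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [pos.size - 1]))
        for s, e in zip(starts, ends):
            first, last = int(pos[s]), int(pos[e])
            w0 = max(0, first - 2 * p - 4)
            w1 = min(n, last + 3 * p + 4)
            out.append((first, p, w0, w1, e - s + 1))
    return out


def _kmer_candidates(codes: np.ndarray, max_period: int):
    """Candidate (anchor, period) pairs from exact k-mer recurrences."""
    n = codes.shape[0]
    k = _SEED_K
    if n < 2 * k:
        return []
    occ: dict[bytes, list[int]] = defaultdict(list)
    raw = codes.tobytes()
    for i in range(n - k + 1):
        occ[raw[i : i + k]].append(i)
    votes: dict[int, list[int]] = defaultdict(list)
    for positions in occ.values():
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if 10 < d <= max_period:
                votes[d].append(a)
    out = []
    for d, supp in votes.items():
        if len(supp) < 2:
            continue
        supp.sort()
        cluster_start = supp[0]
        prev = supp[0]
        nvotes = 1
        clusters = []
        for x in supp[1:]:
            if x - prev > 2 * d:
                clusters.append((cluster_start, prev, nvotes))
                cluster_start = x
                nvotes = 0
            prev = x
            nvotes += 1
        clusters.append((cluster_start, prev, nvotes))
        for cmin, cmax, nv in clusters:
            if nv < 2 or cmin + d > n:
                continue
            w0 = max(0, cmin - d - 10)
            w1 = min(n, cmax + 2 * d + k + 10)
            out.append((cmin, d, w0, w1, nv))
    out.sort(key=lambda c: -c[4])
    return out[:_MAX_CANDIDATES]


# ---------------------------------------------------------------------------
# alignment + consensus refinement


def _align_stats(window: np.ndarray, pattern: np.ndarray, w: ScoringWeights):
    """Best local array alignment of window vs tiled pattern.

    Returns (score, start, end, matches, mismatches, indels, columns) with
    window-local coordinates, plus the alignment column arrays, or None.
    """
    p = pattern.shape[0]
    tile = make_tile(pattern, window.shape[0] + 2 * p)
    best, bi, bj, P = sw_fill(window, tile, w.match, w.mismatch, w.indel)
    if best <= 0:
        return None
    ops, spos, tpos = traceback(P, bi, bj)
    if ops.size == 0:
        return None
    seq_positions = spos[spos >= 0]
    start = int(seq_positions.min())
    end = int(seq_positions.max()) + 1
    return int(best), start, end, ops, spos, tpos


def _majority_consensus(
    window: np.ndarray, pattern_len: int, ops, spos, tpos
) -> str:
    """Column-majority consensus over the aligned copies.

    Pattern columns whose majority vote is a deletion are dropped;
    insertion columns (sequence char against tiling gap) do not vote.
    Ties broken alphabetically (A < C < G < T).
    """
    counts = np.zeros((pattern_len, 5), dtype=np.int64)  # A C G T gap
    for op, s, t in zip(ops, spos, tpos):
        if op == 1:
            c = window[s]
            if c < 4:  # ambiguity codes do not vote
                counts[t % pattern_len, c] += 1
        elif op == 3:  # gap in sequence, tile position consumed
            counts[t % pattern_len, 4] += 1
    out: list[int | None] = []
    for q in range(pattern_len):
        col = counts[q]
        total_chars = int(col[:4].sum())
        if total_chars == 0:
            # unvisited column (None -> keep original base) or pure-deletion
            out.append(None if col[4] == 0 else -1)
            continue
        if col[4] > total_chars:
            out.append(-1)  # majority vote is a deletion: drop column
            continue
        out.append(int(np.argmax(col[:4])))  # argmax ties -> lowest = A<C<G<T
    return out


def _refine_consensus(window, pattern, ops, spos, tpos) -> np.ndarray | None:
    cols = _majority_consensus(window, pattern.shape[0], ops, spos, tpos)
    refined = []
    for q, c in enumerate(cols):
        if c is None:
            refined.append(int(pattern[q]))
        elif c >= 0:
            refined.append(c)
    if not refined:
        return None
    return np.asarray(refined, dtype=np.uint8)


def _components(window, tile, ops, spos, tpos):
    matches = mismatches = indels = 0
    for op, s, t in zip(ops, spos, tpos):
        if op == 1:
            a = window[s]
            b = tile[t]
            if a == b and a < 4:
                matches += 1
            else:
                mismatches += 1
        else:
            indels += 1
    return matches, mismatches, indels


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _hit_from_alignment(
    seq_id, window, woffset, pattern, w: ScoringWeights
) -> RepeatHit | None:
    res = _align_stats(window, pattern, w)
    if res is None:
        return None
    score, start, end, ops, spos, tpos = res
    tile = make_tile(pattern, window.shape[0] + 2 * pattern.shape[0])

    best = (score, start, end, pattern, ops, spos, tpos, tile)
    refined = _refine_consensus(window, pattern, ops, spos, tpos)
    if refined is not None and refined.tobytes() != pattern.tobytes():
        res2 = _align_stats(window, refined, w)
        if res2 is not None and res2[0] > score:
            score2, s2, e2, ops2, spos2, tpos2 = res2
            tile2 = make_tile(refined, window.shape[0] + 2 * refined.shape[0])
            best = (score2, s2, e2, refined, ops2, spos2, tpos2, tile2)

    score, start, end, pat, ops, spos, tpos, tile = best
    period = int(pat.shape[0])
    matches, mismatches, indels = _components(window, tile, ops, spos, tpos)
    columns = matches + mismatches + indels
    if columns == 0:
        return None
    length = end - start
    if length < MIN_COPIES * period or length < period:
        return None
    copy_number = round(length / period, 1)
    consensus = "".join(_DECODE[c] if c < 4 else "N" for c in pat)
    return RepeatHit(
        seq_id=seq_id,
        start=woffset + start,
        end=woffset + end,
        period=period,
        copy_number=copy_number,
        consensus=consensus,
        percent_matches=_round_half_up(matches / columns * 100),
        percent_indels=_round_half_up(indels / columns * 100),
        score=int(score),
    )


def _resolve_overlaps(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Among overlapping arrays keep the best score (tie: smaller period,
    then leftmost start)."""
    ordered = sorted(
        hits, key=lambda h: (-h.score, h.period, h.start, h.consensus)
    )
    kept: list[RepeatHit] = []
    for h in ordered:
        if all(not h.overlaps(k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _candidates(codes: np.ndarray, max_period: int):
    n = codes.shape[0]
    if n <= _EXHAUSTIVE_MAX_LEN:
        return list(_exhaustive_candidates(n, max_period))
    cands = [
        (a, p, w0, w1)
        for (a, p, w0, w1, _v) in _small_period_candidates(codes, max_period)
    ]
    cands += [
        (a, p, w0, w1)
        for (a, p, w0, w1, _v) in _kmer_candidates(codes, max_period)
    ]
    return cands


def detect_tandem_repeats(
    record: MarkerRecord | str,
    weights: ScoringWeights = WEIGHTS_277,
    *,
    skip_quality_check: bool = False,
) -> list[RepeatHit]:
    """Detect tandem arrays scoring >= ``weights.min_score``.

    Hits are sorted by start; among overlapping candidate arrays only the
    best-scoring is kept (ties favour the smaller period).  Sequences with
    more than 5% non-ATGC bases are refused unless ``skip_quality_check``.
    """
    if isinstance(record, str):
        record = MarkerRecord(seq_id="<anonymous>", sequence=record)
    if not record.sequence:
        return []
    if not skip_quality_check and not record.passes_quality():
        raise QualityError(
            f"{record.seq_id}: {record.non_atgc_fraction:.1%} non-ATGC bases "
            "exceeds the 5% screen (pass skip_quality_check=True to override)"
        )
    codes = encode(record.sequence)
    hits: list[RepeatHit] = []
    seen: set[tuple] = set()
    for anchor, p, w0, w1 in _candidates(codes, weights.max_period):
        pattern = codes[anchor : anchor + p]
        key = (pattern.tobytes(), w0, w1)
        if key in seen:
            continue
        seen.add(key)
        hit = _hit_from_alignment(
            record.seq_id, codes[w0:w1], w0, pattern, weights
        )
        if hit is not None and hit.score >= weights.min_score:
            hits.append(hit)
    return _resolve_overlaps(hits)


def best_array_score(
    sequence: str, weights: ScoringWeights, max_period: int | None = None
) -> int:
    """Raw maximal array score over every anchor/period pair, with the
    pattern taken as the anchored substring (no consensus refinement, no
    reporting thresholds).  Exhaustive over all anchors; intended for
    short sequences and oracle comparisons."""
    codes = encode(sequence)
    n = codes.shape[0]
    cap = min(max_period or weights.max_period, n)
    best = 0
    seen: set[bytes] = set()
    for p in range(1, cap + 1):
        for i in range(0, n - p + 1):
            pat = codes[i : i + p]
            key = pat.tobytes()
            if key in seen:
                continue
            seen.add(key)
            tile = make_tile(pat, n + 2 * p)
            s = int(
                sw_score_only(
                    codes, tile, weights.match, weights.mismatch, weights.indel
                )
            )
            if s > best:
                best = s
    return best


def two_pass_its_scan(
    record: MarkerRecord,
    pass1: ScoringWeights = WEIGHTS_277,
    pass2: ScoringWeights = WEIGHTS_235,
    its2_window: tuple[int, int] | None = None,
    *,
    skip_quality_check: bool = False,
) -> tuple[list[RepeatHit], list[RepeatHit]]:
    """Two-pass protocol: a primary scan of the full sequence, then a more
    sensitive re-scan (default weights 2-3-5) restricted to the ITS2
    window, with coordinates lifted back to full-sequence space."""
    if its2_window is None:
        if record.annotation and "ITS2" in record.annotation:
            its2_window = record.annotation["ITS2"]
        else:
            raise ValueError(
                f"{record.seq_id}: no ITS2 annotation and no window supplied"
            )
    w0, w1 = its2_window
    n = len(record.sequence)
    if not (0 <= w0 < w1 <= n):
        raise ValueError(f"ITS2 window [{w0},{w1}) outside sequence of length {n}")
    hits1 = detect_tandem_repeats(
        record, pass1, skip_quality_check=skip_quality_check
    )
    sub = MarkerRecord(seq_id=record.seq_id, sequence=record.sequence[w0:w1])
    hits2 = detect_tandem_repeats(
        sub, pass2, skip_quality_check=skip_quality_check
    )
    lifted = [replace(h, start=h.start + w0, end=h.end + w0) for h in hits2]
    return hits1, lifted


def infer_insertion_boundaries(
    aligned: Mapping[str, str],
    with_insertion_ids: Sequence[str],
    without_insertion_ids: Sequence[str],
) -> dict[str, tuple[tuple[int, int], list[tuple[int, int]]]]:
    """Locate the insertion in each target from a multiple alignment.

    The insertion is the maximal contiguous column block that is gap in
    every insertion-free reference; per target the block is reported in
    ungapped target coordinates (0-based half-open).  If several disjoint
    all-gap blocks exist, the longest (in target bases) is returned and
    the others are listed as secondary intervals.  An empty interval
    signals "no insertion".
    """
    if not without_insertion_ids:
        raise ValueError("need at least one insertion-free reference")
    lengths = {len(aligned[i]) for i in (*with_insertion_ids, *without_insertion_ids)}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    ncol = lengths.pop()
    allgap = np.ones(ncol, dtype=bool)
    for rid in without_insertion_ids:
        row = aligned[rid]
        allgap &= np.frombuffer(row.encode(), dtype=np.uint8) == ord("-")
    # maximal runs of all-gap columns
    blocks = []
    c = 0
    while c < ncol:
        if allgap[c]:
            c0 = c
            while c < ncol and allgap[c]:
                c += 1
            blocks.append((c0, c))
        else:
            c += 1
    out = {}
    for tid in with_insertion_ids:
        row = aligned[tid]
        ungapped_before = np.cumsum(
            np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")
        )
        intervals = []
        for c0, c1 in blocks:
            chars = int(ungapped_before[c1 - 1] - (ungapped_before[c0 - 1] if c0 else 0))
            if chars == 0:
                continue
            start = int(ungapped_before[c0 - 1]) if c0 else 0
            intervals.append(((start, start + chars), chars))
        if not intervals:
            out[tid] = ((0, 0), [])
            continue
        intervals.sort(key=lambda iv: (-iv[1], iv[0][0]))
        primary = intervals[0][0]
        secondary = [iv[0] for iv in intervals[1:]]
        out[tid] = (primary, secondary)
    return out


def compare_consensus(a: str, b: str, cyclic: bool = False) -> float:
    """Percent identity of the optimal global alignment of two core
    motifs; with ``cyclic`` the maximum over all rotations of ``b``."""
    if not a or not b:
        raise ValueError("consensus sequences must be non-empty")
    if not cyclic:
        return global_identity(a, b)
    return max(
        global_identity(a, b[r:] + b[:r]) for r in range(len(b))
    )


def _rng(values):
    return (min(values), max(values)) if values else None


def summarize_species_profiles(
    hits_by_group: Mapping[tuple[str, str, str], Sequence[RepeatHit]],
    records: Mapping[str, MarkerRecord],
    species_of: Mapping[str, str],
) -> list[SpeciesInsertionProfile]:
    """Build per-(species, region, weight-setting) insertion profiles.

    ``hits_by_group`` maps (species, region, weights-label) to the hits of
    that group; species with an empty hit list yield an ND row.  Distinct
    consensus patterns are collapsed at 100% cyclic identity.
    """
    for (species, _r, _w), hits in hits_by_group.items():
        for h in hits:
            if species_of.get(h.seq_id) != species:
                raise ValueError(
                    f"hit on {h.seq_id} grouped under {species} but mapped to "
                    f"{species_of.get(h.seq_id)}"
                )
    profiles = []
    for (species, region, wlabel), hits in sorted(hits_by_group.items()):
        ids = sorted(s for s, sp in species_of.items() if sp == species)
        lens = [len(records[s].sequence) for s in ids if s in records]
        n_seq = len(ids)
        if not hits:
            profiles.append(
                SpeciesInsertionProfile(
                    species, region, wlabel, n_seq, _rng(lens),
                    None, None, None, None, [], None,
                )
            )
            continue
        distinct: list[str] = []
        for h in hits:
            if not any(
                len(c) == len(h.consensus)
                and compare_consensus(c, h.consensus, cyclic=True) == 100.0
                for c in distinct
            ):
                distinct.append(h.consensus)
        sims = [
            compare_consensus(x, y, cyclic=True)
            for x, y in itertools.combinations((h.consensus for h in hits), 2)
        ] or [100.0]
        profiles.append(
            SpeciesInsertionProfile(
                species=species,
                region=region,
                weights=wlabel,
                n_sequences=n_seq,
                its_length_range=_rng(lens),
                insertion_size_range=_rng([h.end - h.start for h in hits]),
                copy_number_range=_rng([h.copy_number for h in hits]),
                percent_matches_range=_rng([h.percent_matches for h in hits]),
                percent_indels_range=_rng([h.percent_indels for h in hits]),
                consensus_patterns=distinct,
                similarity_range=_rng([round(s, 1) for s in sims]),
            )
        )
    return profiles
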