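"""Dispersed repeat discovery and inverted-repeat / single-copy partitioning.

Repeats are reported as *maximal exact matches* (direct and inverted) found by
exact k-mer seeding with diagonal chaining, then grouped into repeat *units*
(distinct repeated sequences) by single-linkage over locus identity and
reciprocal overlap.  Circular genomes are scanned on a doubled-sequence view
and hits are canonicalised modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import GenomeRecord, SegmentInterval, reverse_complement

SEED_K = 20
MAX_SEED_OCC = 200  # seeds occurring more often are skipped (tandem blowup guard)


@dataclass(frozen=True)
class RepeatPair:
    unit_length: int
    locus_a: SegmentInterval
    locus_b: SegmentInterval
    orientation: str  # direct | inverted
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.locus_a.as_tuple() == self.locus_b.as_tuple():
            raise ValueError("repeat loci must differ")


@dataclass
class RepeatSummary:
    total_repeat_bp: int
    counts: dict[str, int]  # large / intermediate / small, by repeat unit
    min_len_observed: int
    max_len_observed: int
    n_units: int
    n_pairs: int


@dataclass
class IRPair:
    copy_1: SegmentInterval
    copy_2: SegmentInterval
    ir_length: int
    lsc: SegmentInterval
    ssc: SegmentInterval


# ---------------------------------------------------------------------------
# maximal exact matches
# ---------------------------------------------------------------------------

def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        pos.setdefault(seq[i : i + k], []).append(i)
    return pos


def _runs_on_diagonal(a: str, b: str, offset: int, seeds: list[int], k: int, min_len: int):
    """Maximal runs where a[x] == b[x + offset], visiting each run once.

    ``seeds`` are positions in ``a`` known to start a k-mer match.
    Yields (start_in_a, length).
    """
    la, lb = len(a), len(b)
    covered_to = -1
    for i in sorted(seeds):
        if i <= covered_to:
            continue
        # extend left
        s = i
        while s > 0 and 0 <= s - 1 + offset < lb and a[s - 1] == b[s - 1 + offset]:
            s -= 1
        # extend right
        e = i + k
        while e < la and e + offset < lb and a[e] == b[e + offset]:
            e += 1
        covered_to = e - k
        if e - s >= min_len:
            yield s, e - s


def _canonical_pair(a: SegmentInterval, b: SegmentInterval) -> tuple:
    ta, tb = a.as_tuple(), b.as_tuple()
    return (ta, tb) if ta <= tb else (tb, ta)


def find_dispersed_repeats(
    genome: GenomeRecord, min_len: int = 30, min_identity: float = 0.90
) -> list[RepeatPair]:
    """All maximal exact repeated units >= ``min_len``, both orientations.

    ``min_identity`` governs unit merging downstream (matches are exact, so
    every reported pair has identity 1.0).  Deterministic output order:
    by locus_a.start, then unit length descending.
    """
    if min_len < 20:
        raise ValueError("min_len < 20: seed scheme unreliable")
    L = genome.length
    seq = genome.doubled()
    k = min(SEED_K, min_len)
    fwd = _seed_positions(seq, k)

    pairs: dict[tuple, RepeatPair] = {}

    def _mod_locus(start: int, length: int, strand: str) -> SegmentInterval:
        s = start % L
        e = s + length
        if e <= L:
            return SegmentInterval(s, e, strand)
        return SegmentInterval(s, e - L, strand, wraps_origin=True)

    def _add(start_a: int, start_b: int, length: int, orientation: str) -> None:
        if length > L:
            length = L
        s_a, s_b = sorted((start_a % L, start_b % L))
        if (s_a, length) == (s_b, length):
            return
        # canonical strands: lower-start locus '+', partner '-' iff inverted
        la = _mod_locus(s_a, length, "+")
        lb = _mod_locus(s_b, length, "+" if orientation == "direct" else "-")
        key = (_canonical_pair(la, lb), orientation)
        if key not in pairs:
            pairs[key] = RepeatPair(length, la, lb, orientation)

    # direct: diagonals of seq vs seq
    by_diag: dict[int, list[int]] = {}
    for kmer, ps in fwd.items():
        if len(ps) < 2 or len(ps) > MAX_SEED_OCC:
            continue
        for ii in range(len(ps)):
            for jj in range(ii + 1, len(ps)):
                d = ps[jj] - ps[ii]
                if genome.is_circular and d % L == 0:
                    continue  # trivial self-image in the doubled view
                by_diag.setdefault(d, []).append(ps[ii])
    for d, seeds in by_diag.items():
        for s, length in _runs_on_diagonal(seq, seq, d, seeds, k, min_len):
            if genome.is_circular:
                if s >= L:
                    continue
                # keep each physical pair once: second locus reduced mod L
                _add(s, s + d, length, "direct")
            else:
                _add(s, s + d, length, "direct")

    # inverted: diagonals of seq vs reverse complement of seq
    rc = reverse_complement(seq)
    rc_pos = _seed_positions(rc, k)
    by_adiag: dict[int, list[int]] = {}
    for kmer, ps in fwd.items():
        qs = rc_pos.get(kmer)
        if not qs or len(ps) * len(qs) > MAX_SEED_OCC * MAX_SEED_OCC:
            continue
        for i in ps:
            for j in qs:
                by_adiag.setdefault(j - i, []).append(i)
    n2 = len(seq)
    seen_inv: set[tuple] = set()
    for d, seeds in by_adiag.items():
        for s, length in _runs_on_diagonal(seq, rc, d, seeds, k, min_len):
            # position in rc -> position in seq: j_rc = s + d, original start
            b_start = n2 - (s + d) - length
            a, b = sorted([s, b_start])
            if genome.is_circular:
                if a >= L:
                    continue
                key = tuple(sorted((a % L, b % L))) + (length,)
                if key in seen_inv:
                    continue
                seen_inv.add(key)
                _add(a, b, length, "inverted")
            else:
                key = (a, b, length)
                if key in seen_inv:
                    continue
                seen_inv.add(key)
                _add(a, b, length, "inverted")

    out = list(pairs.values())
    out.sort(key=lambda p: (p.locus_a.start, -p.unit_length, p.locus_b.start, p.orientation))
    return out


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def _locus_coverage_indices(locus: SegmentInterval, L: int) -> np.ndarray:
    n = locus.length(L)
    return (np.arange(locus.start, locus.start + n)) % L


def _linear_pieces(locus: SegmentInterval, L: int) -> list[tuple[int, int]]:
    if not locus.wraps_origin:
        return [(locus.start, locus.end)]
    return [(locus.start, L), (0, locus.end)]


def _reciprocal_overlap(a: SegmentInterval, b: SegmentInterval, L: int) -> float:
    la, lb = a.length(L), b.length(L)
    inter = 0
    for s1, e1 in _linear_pieces(a, L):
        for s2, e2 in _linear_pieces(b, L):
            inter += max(0, min(e1, e2) - max(s1, s2))
    if inter == 0:
        return 0.0
    return min(inter / la, inter / lb)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def summarize_repeats(
    pairs: list[RepeatPair], genome: GenomeRecord, overlap_merge: float = 0.90
) -> RepeatSummary:
    """Size-class counts of repeat *units* and the union bp of all loci.

    large: unit_length > 1000; intermediate: 100-1000 inclusive;
    small: < 100.  Loci linked by a pair, or overlapping reciprocally by
    >= ``overlap_merge``, belong to one unit (single linkage).
    """
    L = genome.length
    if not pairs:
        return RepeatSummary(0, {"large": 0, "intermediate": 0, "small": 0}, 0, 0, 0, 0)

    loci: list[SegmentInterval] = []
    index: dict[tuple, int] = {}

    def _idx(locus: SegmentInterval) -> int:
        key = locus.as_tuple()
        if key not in index:
            index[key] = len(loci)
            loci.append(locus)
        return index[key]

    edges = []
    for p in pairs:
        edges.append((_idx(p.locus_a), _idx(p.locus_b)))

    uf = _UnionFind(len(loci))
    for a, b in edges:
        uf.union(a, b)
    # merge near-duplicate loci (overlapping heavily) into one unit
    order = sorted(range(len(loci)), key=lambda i: loci[i].start)
    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            a, b = loci[order[ii]], loci[order[jj]]
            if not a.wraps_origin and not b.wraps_origin and b.start > a.end:
                break
            if _reciprocal_overlap(a, b, L) >= overlap_merge:
                uf.union(order[ii], order[jj])

    units: dict[int, int] = {}
    for i, locus in enumerate(loci):
        r = uf.find(i)
        units[r] = max(units.get(r, 0), locus.length(L))

    counts = {"large": 0, "intermediate": 0, "small": 0}
    for ulen in units.values():
        if ulen > 1000:
            counts["large"] += 1
        elif ulen >= 100:
            counts["intermediate"] += 1
        else:
            counts["small"] += 1

    cover = np.zeros(L, dtype=bool)
    for locus in loci:
        cover[_locus_coverage_indices(locus, L)] = True

    ulens = [p.unit_length for p in pairs]
    return RepeatSummary(
        total_repeat_bp=int(cover.sum()),
        counts=counts,
        min_len_observed=min(ulens),
        max_len_observed=max(ulens),
        n_units=len(units),
        n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# plastome inverted-repeat pair
# ---------------------------------------------------------------------------

def find_inverted_repeat_pair(genome: GenomeRecord, min_len: int = 100) -> Optional[IRPair]:
    """Longest inverted repeat pair partitioning the circle into two
    single-copy arcs; ``None`` if no inverted repeat >= ``min_len`` exists."""
    if not genome.is_circular:
        raise ValueError("inverted-repeat partitioning requires a circular genome")
    pairs = [
        p
        for p in find_dispersed_repeats(genome, min_len=max(min_len, 20))
        if p.orientation == "inverted" and p.unit_length >= min_len
    ]
    if not pairs:
        return None
    best = max(pairs, key=lambda p: p.unit_length)
    L = genome.length
    c1, c2 = sorted([best.locus_a, best.locus_b], key=lambda x: x.start)
    if c1.wraps_origin or c2.wraps_origin:
        # rotate coordinates so neither copy wraps (report in rotated frame)
        raise ValueError("IR copy wraps the origin; rotate the genome first")
    arc1_len = c2.start - c1.end
    arc2_len = L - c2.end + c1.start
    if arc1_len <= 0 or arc2_len <= 0:
        raise ValueError("IR copies overlap or touch; no single-copy partition")
    arc1 = SegmentInterval(c1.end, c2.start, "+")
    if c1.start == 0:
        arc2 = SegmentInterval(c2.end, L, "+")
    elif c2.end == L:
        arc2 = SegmentInterval(0, c1.start, "+")
    else:
        arc2 = SegmentInterval(c2.end, c1.start, "+", wraps_origin=True)
    lsc, ssc = (arc1, arc2) if arc1_len >= arc2_len else (arc2, arc1)
    ir = IRPair(copy_1=c1, copy_2=c2, ir_length=best.unit_length, lsc=lsc, ssc=ssc)
    assert 2 * ir.ir_length + ir.lsc.length(L) + ir.ssc.length(L) == L
    return ir
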