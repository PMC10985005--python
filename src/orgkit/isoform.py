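"""Plastome isoform construction and long-read conformation typing.

The two conformations (form A = reference, form B) differ by the orientation
of the arc between the two inverted-repeat copies.  Because the IR itself is
shared, reads are typed by *unique anchors*: the four single-copy flanks of
the IR ends.  A read supports a form when it spans an IR copy with the
anchor pairing that only that form produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median

from .core_model import GenomeRecord, SegmentInterval, Topology, reverse_complement
from .repeatscan import IRPair

LABELS = ("form_A", "form_B", "ambiguous", "chimeric")


@dataclass
class IsoformModel:
    form_a: GenomeRecord
    form_b: GenomeRecord
    ir: IRPair
    min_anchor: int
    anchors: dict[str, str]  # R1..R4 single-copy flank sequences (form A sense)
    junctions: dict[str, list[tuple[str, int]]]  # form -> [(junction name, coord)]

    # anchor pairing expected across each IR copy, per form:
    # key: ((anchor, orient), (anchor, orient)) in read order on the forward strand
    pairings: dict[tuple, tuple[str, str]] = field(default_factory=dict)


@dataclass
class IsoformCall:
    read_id: str
    label: str
    junctions_spanned: list[str] = field(default_factory=list)
    anchor_lengths: int = 0


def build_alternative_form(
    plastome: GenomeRecord, ir: IRPair, min_anchor: int = 200
) -> IsoformModel:
    """Construct form B by reverse-complementing the arc between the IR copies
    and catalogue the four junction anchors of both forms."""
    L = plastome.length
    c1, c2 = ir.copy_1, ir.copy_2
    if c1.start > c2.start:
        c1, c2 = c2, c1
    if c2.start < c1.end:
        raise ValueError("IR copies overlap; cannot build the alternative form")
    seq = plastome.sequence
    flipped = (
        seq[: c1.end]
        + reverse_complement(seq[c1.end : c2.start])
        + seq[c2.start :]
    )
    form_b = GenomeRecord(id=plastome.id + "_formB", sequence=flipped, topology=plastome.topology)
    assert form_b.length == plastome.length

    def circ(i: int) -> int:
        return i % L

    def window(end: int) -> str:  # min_anchor bp ending at `end` (exclusive), circular
        return "".join(seq[circ(end - min_anchor + t)] for t in range(min_anchor))

    def window_from(start: int) -> str:
        return "".join(seq[circ(start + t)] for t in range(min_anchor))

    anchors = {
        "R1": window(c1.start),       # single-copy flank entering IR copy 1
        "R2": window_from(c1.end),    # flank leaving IR copy 1 (inner arc)
        "R3": window(c2.start),       # flank entering IR copy 2 (inner arc)
        "R4": window_from(c2.end),    # flank leaving IR copy 2
    }
    # read-order pairing across each IR copy on the forward strand of each form
    pairings = {
        (("R1", "+"), ("R2", "+")): ("form_A", "IR1"),
        (("R3", "+"), ("R4", "+")): ("form_A", "IR2"),
        (("R1", "+"), ("R3", "-")): ("form_B", "IR1"),
        (("R2", "-"), ("R4", "+")): ("form_B", "IR2"),
    }
    junctions = {
        "form_A": [("R1|IR1", c1.start), ("IR1|R2", c1.end), ("R3|IR2", c2.start), ("IR2|R4", c2.end)],
        "form_B": [("R1|IR1", c1.start), ("IR1|R3'", c1.end), ("R2'|IR2", c2.start), ("IR2|R4", c2.end)],
    }
    return IsoformModel(
        form_a=plastome,
        form_b=form_b,
        ir=IRPair(c1, c2, ir.ir_length, ir.lsc, ir.ssc),
        min_anchor=min_anchor,
        anchors=anchors,
        junctions=junctions,
        pairings=pairings,
    )


# ---------------------------------------------------------------------------
# read classification
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _locate_anchor(read_index: dict[str, list[int]], anchor: str, k: int, min_hits: int):
    """Median seed offset of `anchor` within the indexed read, or None."""
    offsets = []
    for i in range(0, len(anchor) - k + 1):
        for p in read_index.get(anchor[i : i + k], ()):
            offsets.append(p - i)
    if len(offsets) < min_hits:
        return None
    offsets.sort()
    mid = offsets[len(offsets) // 2]
    near = [o for o in offsets if abs(o - mid) <= 0.25 * len(anchor) + 50]
    if len(near) < min_hits:
        return None
    return int(median(near)), len(near)


def classify_reads(
    reads: list[tuple[str, str]],
    model: IsoformModel,
    min_anchor: int = 200,
    max_divergence: float = 0.15,
    k: int = 13,
) -> list[IsoformCall]:
    """Label each (read_id, sequence) as form_A / form_B / ambiguous / chimeric.

    A read supports a form when it contains, in order and at a spacing
    compatible with the IR length, the anchor pairing unique to that form at
    one of the two IR copies; conflicting junctions within one read are
    chimeric.  Reads spanning no junction are ambiguous.
    """
    if min_anchor != model.min_anchor:
        model = build_alternative_form(model.form_a, model.ir, min_anchor)
    anchors = model.anchors
    ir_len = model.ir.ir_length
    alen = model.min_anchor
    # seed-count threshold: a k-mer survives (1-e)^k per-base errors
    survive = (1.0 - max_divergence) ** k
    min_hits = max(4, int(0.3 * survive * (alen - k + 1)))

    oriented = {(name, "+"): a for name, a in anchors.items()}
    oriented.update({(name, "-"): reverse_complement(a) for name, a in anchors.items()})

    calls = []
    for read_id, read_seq in reads:
        votes: dict[str, list[str]] = {"form_A": [], "form_B": []}
        for rseq in (read_seq, reverse_complement(read_seq)):
            idx = _kmer_index(rseq.upper(), k)
            hits = []
            for key, aseq in oriented.items():
                loc = _locate_anchor(idx, aseq, k, min_hits)
                if loc is not None:
                    hits.append((loc[0], key, loc[1]))
            hits.sort()
            expected_gap = alen + ir_len
            tol = 0.35 * expected_gap + 100
            for i in range(len(hits)):
                for j in range(i + 1, len(hits)):
                    gap = hits[j][0] - hits[i][0]
                    if abs(gap - expected_gap) > tol:
                        continue
                    pairing = (hits[i][1], hits[j][1])
                    got = model.pairings.get(pairing)
                    if got is not None:
                        form, junction = got
                        votes[form].append(junction)
            if votes["form_A"] or votes["form_B"]:
                break  # orientation resolved
        a, b = votes["form_A"], votes["form_B"]
        if a and b:
            label = "chimeric"
        elif a:
            label = "form_A"
        elif b:
            label = "form_B"
        else:
            label = "ambiguous"
        calls.append(
            IsoformCall(read_id, label, junctions_spanned=sorted(set(a + b)), anchor_lengths=alen)
        )
    return calls


# ---------------------------------------------------------------------------
# ratio estimation
# ---------------------------------------------------------------------------

def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        raise ValueError("no trials")
    p = k / n
    z2 = z * z
    denom = 1 + z2 / n
    centre = p + z2 / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n))
    return ((centre - half) / denom, (centre + half) / denom)


def estimate_isoform_ratio(calls: list[IsoformCall]) -> dict:
    """p(form A) among informative reads with a Wilson 95% CI; ambiguous and
    chimeric reads are excluded from the denominator but reported."""
    n_a = sum(1 for c in calls if c.label == "form_A")
    n_b = sum(1 for c in calls if c.label == "form_B")
    n_amb = sum(1 for c in calls if c.label == "ambiguous")
    n_chi = sum(1 for c in calls if c.label == "chimeric")
    result = {
        "n_form_a": n_a,
        "n_form_b": n_b,
        "n_ambiguous": n_amb,
        "n_chimeric": n_chi,
    }
    if n_a + n_b == 0:
        result.update({"p_form_a": None, "ci_95": None, "defined": False})
        return result
    lo, hi = wilson_interval(n_a, n_a + n_b)
    result.update({"p_form_a": n_a / (n_a + n_b), "ci_95": (lo, hi), "defined": True})
    return result
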