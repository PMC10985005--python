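"""Deterministic, seeded generators with exact ground truth.

Every generator takes either a seed or a ``numpy.random.Generator`` and
produces byte-identical output for identical inputs (integer RNG streams
only).  Background sequence is screened so that it contains no unplanned
duplicate (direct or inverted) at or above the repeat-scan minimum length;
planted features are therefore the only features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    GeneAnnotation,
    GenomeRecord,
    SegmentInterval,
    Topology,
    reverse_complement,
)
from .editing import PileupSite
from .isoform import IsoformModel
from .repeatscan import IRPair

_BASES = np.array(list("ACGT"))


class InfeasiblePacking(ValueError):
    """Raised when a plan cannot be placed inside the genome."""


# ---------------------------------------------------------------------------
# config / truth containers
# ---------------------------------------------------------------------------

@dataclass
class EditPlan:
    n_sites: int = 50
    fraction: float = 0.9
    error_rate: float = 0.005
    depth: int = 100


@dataclass
class IsoformPlan:
    ir_length: int = 1000
    lsc: int = 10000
    ssc: int = 4000
    ratio_a: float = 0.7
    n_reads: int = 200
    read_length_mean: int = 3000
    error_rate: float = 0.05


@dataclass
class RecombPlan:
    n_blocks: int = 1
    topologies: Optional[list[str]] = None  # newick strings, one per block


@dataclass
class SimConfig:
    seed: int = 1
    genome_length: int = 50000
    gc: float = 0.45
    n_genes: int = 5
    n_trans_introns: int = 1
    repeat_plan: list[tuple[int, str, int]] = field(default_factory=list)
    mipt_plan: list[tuple[int, float]] = field(default_factory=list)
    edit_plan: EditPlan = field(default_factory=EditPlan)
    isoform_plan: IsoformPlan = field(default_factory=IsoformPlan)
    recomb_plan: RecombPlan = field(default_factory=RecombPlan)
    min_repeat_screen: int = 30


@dataclass
class GroundTruth:
    repeats: list[dict] = field(default_factory=list)
    mipts: list[dict] = field(default_factory=list)
    genes: dict[str, dict] = field(default_factory=dict)
    editing_sites: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# background sequence
# ---------------------------------------------------------------------------

def random_dna(rng, n: int, gc: float = 0.45) -> str:
    rng = _rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def screen_duplicates(seq: str, min_len: int, rng, gc: float = 0.45, max_rounds: int = 60) -> str:
    """Rewrite windows until no duplicate >= ``min_len`` exists, in either
    orientation (self-overlapping palindromic images of one locus allowed)."""
    rng = _rng(rng)
    k = min_len
    chars = list(seq)
    for _ in range(max_rounds):
        s = "".join(chars)
        clash = _first_duplicate(s, k)
        if clash is None:
            return s
        pos = clash
        repl = random_dna(rng, k, gc)
        chars[pos : pos + k] = list(repl)
    raise InfeasiblePacking(f"could not screen duplicates at k={min_len}")


def _first_duplicate(s: str, k: int) -> int | None:
    seen: dict[str, int] = {}
    rc = reverse_complement(s)
    L = len(s)
    for i in range(L - k + 1):
        kmer = s[i : i + k]
        if kmer in seen and seen[kmer] != i:
            return i
        seen[kmer] = i
    for j in range(L - k + 1):
        kmer = rc[j : j + k]
        orig = L - j - k  # genomic start of this rc window
        if kmer in seen and not (abs(seen[kmer] - orig) < k):
            return orig
    return None


# ---------------------------------------------------------------------------
# annotated genome with planted features
# ---------------------------------------------------------------------------

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _break_repeat_extensions(chars: list[str], loci: list[dict], L: int) -> None:
    """Mutate single flank bases so no planted repeat pair extends beyond its
    planted unit (exact-match extension stops at the first mismatch)."""
    for _ in range(6):
        dirty = False
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                a, b = loci[i], loci[j]
                la = a["end"] - a["start"]
                same = a["strand"] == b["strand"]
                if same:
                    cons = [
                        ((a["start"] - 1) % L, (b["start"] - 1) % L, False),
                        (a["end"] % L, b["end"] % L, False),
                    ]
                else:
                    cons = [
                        ((a["start"] - 1) % L, b["end"] % L, True),
                        (a["end"] % L, (b["start"] - 1) % L, True),
                    ]
                for x, y, comp in cons:
                    xy = _COMP1[chars[y]] if comp else chars[y]
                    if chars[x] == xy:
                        chars[x] = next(c for c in "ACGT" if c != xy and c != chars[x])
                        dirty = True
        if not dirty:
            return


def _alloc(rng, L: int, length: int, occupied: list[tuple[int, int]], margin: int = 50, tries: int = 500) -> int:
    rng = _rng(rng)
    for _ in range(tries):
        start = int(rng.integers(0, L - length))
        s, e = start - margin, start + length + margin
        if all(e <= os or s >= oe for os, oe in occupied):
            occupied.append((start, start + length))
            return start
    raise InfeasiblePacking(f"cannot place a {length} bp feature (genome {L} bp)")


def generate_genome(
    config: SimConfig, donor: GenomeRecord | None = None
) -> tuple[GenomeRecord, list[GeneAnnotation], GroundTruth]:
    """Annotated circular genome with planted repeats, MIPT fragments and
    gene models (some multi-exon, some trans-spliced per plan)."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = screen_duplicates(
        random_dna(rng, L, config.gc), config.min_repeat_screen, rng, config.gc
    )
    chars = list(seq)
    occupied: list[tuple[int, int]] = []
    truth = GroundTruth()

    # repeats
    for unit_length, orientation, n_copies in config.repeat_plan:
        if orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {orientation!r}")
        unit = screen_duplicates(
            random_dna(rng, unit_length, config.gc), min(config.min_repeat_screen, unit_length), rng, config.gc
        ) if unit_length >= config.min_repeat_screen else random_dna(rng, unit_length, config.gc)
        loci = []
        for c in range(n_copies):
            start = _alloc(rng, L, unit_length, occupied)
            copy_seq = unit if c == 0 or orientation == "direct" else reverse_complement(unit)
            chars[start : start + unit_length] = list(copy_seq)
            loci.append({"start": start, "end": start + unit_length,
                         "strand": "+" if c == 0 or orientation == "direct" else "-"})
        _break_repeat_extensions(chars, loci, L)
        truth.repeats.append(
            {"unit_length": unit_length, "orientation": orientation, "loci": loci}
        )

    # plastid-derived fragments
    if config.mipt_plan:
        if donor is None:
            donor = GenomeRecord(
                id="donor_plastome",
                sequence=screen_duplicates(
                    random_dna(rng, max(20000, max(l for l, _ in config.mipt_plan) * 4), config.gc),
                    config.min_repeat_screen, rng, config.gc,
                ),
                topology=Topology.circular,
            )
        for frag_len, identity in config.mipt_plan:
            dstart = int(rng.integers(0, donor.length - frag_len))
            frag = donor.sequence[dstart : dstart + frag_len]
            n_mut = int(round((1 - identity) * frag_len))
            if n_mut:
                pos = rng.choice(frag_len, size=n_mut, replace=False)
                fl = list(frag)
                for p in pos:
                    fl[p] = str(rng.choice([b for b in "ACGT" if b != fl[p]]))
                frag = "".join(fl)
            mstart = _alloc(rng, L, frag_len, occupied)
            chars[mstart : mstart + frag_len] = list(frag)
            # six mismatching flank bases per side stop local-alignment
            # extension beyond the planted fragment
            for t in range(6):
                for x, y in (
                    ((mstart - 1 - t) % L, dstart - 1 - t),
                    ((mstart + frag_len + t) % L, dstart + frag_len + t),
                ):
                    if 0 <= y < donor.length and chars[x] == donor.sequence[y]:
                        chars[x] = next(c for c in "ACGT" if c != donor.sequence[y])
            truth.mipts.append(
                {"donor_start": dstart, "donor_end": dstart + frag_len,
                 "mito_start": mstart, "mito_end": mstart + frag_len,
                 "length": frag_len, "identity": identity}
            )

    genome = GenomeRecord(id=f"sim{config.seed}", sequence="".join(chars), topology=Topology.circular)

    # genes (annotations over the final sequence)
    genes: list[GeneAnnotation] = []
    n_trans_left = config.n_trans_introns
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(1, 4))
        trans_here = n_trans_left > 0 and n_exons >= 2
        exons = []
        strand = "+" if rng.random() < 0.5 else "-"
        if trans_here:
            # exons placed independently; one may switch strand
            for ei in range(n_exons):
                elen = int(rng.integers(30, 120)) * 3
                start = _alloc(rng, L, elen, occupied)
                # guarantee at least one trans junction via a strand switch
                st = strand if ei == 0 else ("-" if strand == "+" else "+")
                exons.append(SegmentInterval(start, start + elen, st))
            n_trans_left -= 1
        else:
            total = sum(int(rng.integers(30, 120)) * 3 for _ in range(n_exons))
            introns = [int(rng.integers(50, 1500)) for _ in range(n_exons - 1)]
            span = total + sum(introns)
            start = _alloc(rng, L, span, occupied)
            cursor = start
            lens = []
            remaining = total
            for ei in range(n_exons):
                if ei == n_exons - 1:
                    elen = remaining
                else:
                    elen = max(3, (remaining // (n_exons - ei)) // 3 * 3)
                lens.append(elen)
                remaining -= elen
            for ei, elen in enumerate(lens):
                exons.append(SegmentInterval(cursor, cursor + elen, strand))
                cursor += elen + (introns[ei] if ei < n_exons - 1 else 0)
            if strand == "-":
                exons = exons[::-1]  # transcription order for minus strand
        gene = GeneAnnotation(gene_id=f"gene{gi}", biotype="CDS", exons=exons)
        genes.append(gene)
        mrna = "".join(
            (reverse_complement(genome.sequence[e.start : e.end]) if e.strand == "-" else genome.sequence[e.start : e.end])
            for e in exons
        )
        truth.genes[gene.gene_id] = {
            "mrna": mrna,
            "exons": [e.as_tuple() for e in exons],
            "trans_spliced": trans_here,
        }
    truth.extra["donor_id"] = donor.id if donor is not None else None
    return genome, genes, truth


# ---------------------------------------------------------------------------
# editing pileups
# ---------------------------------------------------------------------------

def simulate_editing_pileup(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    edit_plan: EditPlan,
    seed_or_rng=0,
) -> tuple[list[PileupSite], GroundTruth]:
    """Pileup over all spliced CDS positions with planted C->T edit sites.

    At a planted site each read reports T with probability ``fraction``; all
    reads then suffer uniform sequencing error at ``error_rate``.
    """
    from .core_model import extract_spliced_cds

    rng = _rng(seed_or_rng)
    truth = GroundTruth()
    cds_by_gene = {g.gene_id: extract_spliced_cds(genome, g) for g in genes if g.biotype == "CDS"}
    c_positions = [
        (gid, i) for gid, cds in sorted(cds_by_gene.items()) for i, b in enumerate(cds) if b == "C"
    ]
    if edit_plan.n_sites > len(c_positions):
        raise InfeasiblePacking(
            f"edit plan wants {edit_plan.n_sites} C sites, only {len(c_positions)} available"
        )
    chosen_idx = rng.choice(len(c_positions), size=edit_plan.n_sites, replace=False)
    chosen = {c_positions[i] for i in chosen_idx}
    for gid, pos in sorted(chosen):
        truth.editing_sites.append({"gene": gid, "cds_pos": pos, "fraction": edit_plan.fraction})

    sites = []
    e = edit_plan.error_rate
    for gid, cds in sorted(cds_by_gene.items()):
        for i, ref in enumerate(cds):
            depth = edit_plan.depth
            if (gid, i) in chosen:
                n_t = int(rng.binomial(depth, edit_plan.fraction))
                counts = _with_errors(rng, {"T": n_t, ref: depth - n_t}, e)
            else:
                counts = _with_errors(rng, {ref: depth}, e)
            base_counts = {b: counts.get(b, 0) for b in "ACGTN"}
            sites.append(PileupSite(gid, i, ref, depth, base_counts))
    return sites, truth


def _with_errors(rng, true_counts: dict[str, int], error_rate: float) -> dict[str, int]:
    out: dict[str, int] = {}
    for base, n in true_counts.items():
        if n <= 0:
            continue
        n_err = int(rng.binomial(n, error_rate)) if error_rate > 0 else 0
        out[base] = out.get(base, 0) + n - n_err
        if n_err:
            others = [b for b in "ACGT" if b != base]
            for b in rng.choice(others, size=n_err):
                out[b] = out.get(b, 0) + 1
    return out


# ---------------------------------------------------------------------------
# plastome + long reads
# ---------------------------------------------------------------------------

def make_synthetic_plastome(
    lsc: int, ir: int, ssc: int, seed_or_rng=0, gc: float = 0.38
) -> tuple[GenomeRecord, IRPair, str]:
    """Circular LSC + IR + SSC + IR' plastome.

    Returns (genome, true IRPair, independently constructed form-B sequence).
    """
    rng = _rng(seed_or_rng)
    lsc_seq = screen_duplicates(random_dna(rng, lsc, gc), 30, rng, gc)
    ir_seq = screen_duplicates(random_dna(rng, ir, gc), 30, rng, gc)
    ssc_seq = screen_duplicates(random_dna(rng, ssc, gc), 30, rng, gc)
    # stop the inverted match from extending past the planted IR boundaries:
    # left: seq[lsc-1] vs comp(seq[0]); right: first vs comp(last) SSC base
    if lsc_seq[-1] == _COMP1[lsc_seq[0]]:
        lsc_seq = lsc_seq[:-1] + next(c for c in "ACGT" if c != _COMP1[lsc_seq[0]])
    if ssc_seq[0] == _COMP1[ssc_seq[-1]]:
        ssc_seq = next(c for c in "ACGT" if c != _COMP1[ssc_seq[-1]]) + ssc_seq[1:]
    form_a = lsc_seq + ir_seq + ssc_seq + reverse_complement(ir_seq)
    form_b = lsc_seq + ir_seq + reverse_complement(ssc_seq) + reverse_complement(ir_seq)
    genome = GenomeRecord(id="sim_plastome", sequence=form_a, topology=Topology.circular)
    L = len(form_a)
    c1 = SegmentInterval(lsc, lsc + ir, "+")
    c2 = SegmentInterval(lsc + ir + ssc, L, "-")
    ir_pair = IRPair(
        copy_1=c1,
        copy_2=c2,
        ir_length=ir,
        lsc=SegmentInterval(0, lsc, "+"),
        ssc=SegmentInterval(lsc + ir, lsc + ir + ssc, "+"),
    )
    return genome, ir_pair, form_b


def simulate_long_reads(
    model: IsoformModel, plan: IsoformPlan, seed_or_rng=0
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """ONT-like reads from a two-isoform mixture on a circular plastome.

    Start positions uniform on the chosen form; lengths log-normal around the
    mean; substitution/indel errors at ``error_rate`` split 60/40.
    """
    rng = _rng(seed_or_rng)
    truth = GroundTruth()
    reads = []
    forms = {"form_A": model.form_a.sequence, "form_B": model.form_b.sequence}
    L = model.form_a.length
    sigma = 0.35
    mu = np.log(plan.read_length_mean) - sigma**2 / 2
    for i in range(plan.n_reads):
        form = "form_A" if rng.random() < plan.ratio_a else "form_B"
        length = int(np.clip(rng.lognormal(mu, sigma), 200, 3 * plan.read_length_mean))
        length = min(length, L)
        start = int(rng.integers(0, L))
        src = forms[form]
        frag = (src * 2)[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        seq = _apply_read_errors(rng, frag, plan.error_rate)
        rid = f"read{i}"
        reads.append((rid, seq))
        truth.reads.append(
            {"read_id": rid, "form": form, "start": start, "length": length, "strand": strand}
        )
    return reads, truth


def _apply_read_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r >= rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.6:  # substitution
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        elif kind < 0.8:  # insertion
            out.append(ch)
            out.append(str(rng.choice(list("ACGT"))))
        # else deletion: emit nothing
    return "".join(out)


# ---------------------------------------------------------------------------
# alignments for the PHI test
# ---------------------------------------------------------------------------

def random_coalescent_tree(n_taxa: int, rng, scale: float = 0.05) -> str:
    """Random coalescent topology with exponential coalescence times, branch
    lengths in substitutions/site (coalescent units x ``scale``)."""
    rng = _rng(rng)
    nodes = [(f"t{i}", 0.0, f"t{i}") for i in range(n_taxa)]  # (newick, height, label)
    t = 0.0
    k = n_taxa
    while k > 1:
        t += float(rng.exponential(1.0 / (k * (k - 1) / 2)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_i, h_i, _), (nwk_j, h_j, _) = nodes[i], nodes[j]
        bl_i, bl_j = (t - h_i) * scale, (t - h_j) * scale
        merged = (f"({nwk_i}:{bl_i:.6f},{nwk_j}:{bl_j:.6f})", t, "")
        nodes = [nodes[x] for x in range(k) if x not in (i, j)] + [merged]
        k -= 1
    return nodes[0][0] + ";"


def _evolve_jc(rng, newick: str, n_sites: int) -> dict[str, str]:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = _rng(rng)
    root_seq = rng.integers(0, 4, size=n_sites)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        p_change = 0.75 * (1 - np.exp(-4.0 * bl / 3.0))
        mask = rng.random(n_sites) < p_change
        child = parent_seq.copy()
        if mask.any():
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            child[mask] = (child[mask] + shifts) % 4
        seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[child])
    return out


def simulate_alignment(
    recomb_plan: RecombPlan, n_taxa: int, block_len: int, seed_or_rng=0, scale: float = 0.05
) -> tuple[dict[str, str], GroundTruth]:
    """Jukes-Cantor site evolution down per-block topologies.

    A single-topology plan yields a recombination-free null; discordant block
    topologies plant a breakpoint at each block boundary.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = _rng(seed_or_rng)
    truth = GroundTruth()
    topologies = recomb_plan.topologies
    if topologies is None:
        topologies = [random_coalescent_tree(n_taxa, rng, scale) for _ in range(recomb_plan.n_blocks)]
    blocks = []
    for bi, nwk in enumerate(topologies):
        blocks.append(_evolve_jc(rng, nwk, block_len))
        if bi:
            truth.breakpoints.append(bi * block_len)
    taxa = sorted(blocks[0])
    matrix = {t: "".join(b[t] for b in blocks) for t in taxa}
    truth.extra["topologies"] = topologies
    return matrix, truth
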