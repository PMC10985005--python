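"""Empirical C-to-U RNA-editing calling and codon-consequence classification.

Pileups are expressed in coding-strand sense over the spliced CDS of each
annotated gene: a genomic C on a minus-strand gene appears here as ref C with
the read counts complemented.  Input is either a tabular pileup
(gene, cds_pos, ref, A, C, G, T[, N]) or a SAM/BAM alignment against the
genome, from which the pileup is computed with MAPQ/baseQ >= 20 filters.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .core_model import (
    CodonChange,
    GeneAnnotation,
    GenomeRecord,
    extract_spliced_cds,
    STANDARD_CODE,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CONSEQUENCES = (
    "silent",
    "missense",
    "stop_gain",
    "start_gain",
    "start_codon_edit",
    "stop_codon_edit",
)


@dataclass
class PileupSite:
    gene_id: str
    cds_pos: int  # 0-based position in the spliced (codon_start-trimmed) CDS
    ref_base: str  # coding-strand sense
    depth: int
    base_counts: dict[str, int]  # coding-strand sense, keys A/C/G/T/N

    def __post_init__(self) -> None:
        if sum(self.base_counts.values()) != self.depth:
            raise ValueError(
                f"{self.gene_id}:{self.cds_pos}: base counts do not sum to depth"
            )


@dataclass
class EditingSite:
    gene_id: str
    cds_pos: int
    edit_fraction: float
    depth: int
    consequence: str | None = None
    codon_change: CodonChange | None = None


@dataclass
class EditingSummary:
    per_gene: dict[str, dict]  # gene -> n_sites, n_codon_changes, cds_length, density
    aa_conversion_matrix: dict[tuple[str, str], int]  # (aa_before, aa_after) -> n
    codon_position_counts: dict[int, int]
    consequence_counts: dict[str, int]
    start_gains: list[EditingSite]
    stop_gains: list[EditingSite]
    n_sites: int
    n_silent: int


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def read_pileup_tsv(path: str | Path) -> list[PileupSite]:
    sites = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0].lower() not in ("gene", "gene_id"):
            fh.seek(0)
            reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            gene, pos, ref = row[0], int(row[1]), row[2].upper()
            counts = {b: int(v) for b, v in zip("ACGT", row[3:7])}
            counts["N"] = int(row[7]) if len(row) > 7 else 0
            sites.append(
                PileupSite(gene, pos, ref, sum(counts.values()), counts)
            )
    return sites


def write_pileup_tsv(sites: list[PileupSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcds_pos\tref\tA\tC\tG\tT\tN\n")
        for s in sites:
            c = s.base_counts
            fh.write(
                f"{s.gene_id}\t{s.cds_pos}\t{s.ref_base}\t"
                f"{c.get('A',0)}\t{c.get('C',0)}\t{c.get('G',0)}\t{c.get('T',0)}\t{c.get('N',0)}\n"
            )


def _cds_position_map(
    genome: GenomeRecord, genes: list[GeneAnnotation]
) -> dict[tuple[str, int], tuple[str, int, str, str]]:
    """(genome_id, genomic_pos) -> (gene, cds_pos, strand, ref_base coding sense)."""
    mapping: dict[tuple[str, int], tuple[str, int, str, str]] = {}
    L = genome.length
    for g in genes:
        if g.biotype != "CDS":
            continue
        cds_pos = -g.codon_start
        for exon in g.exons:
            n = exon.length(L)
            positions = [(exon.start + t) % L for t in range(n)]
            if exon.strand == "-":
                positions = positions[::-1]
            for gp in positions:
                if cds_pos >= 0:
                    base = genome.sequence[gp]
                    ref = _COMP[base] if exon.strand == "-" else base
                    mapping[(genome.id, gp)] = (g.gene_id, cds_pos, exon.strand, ref)
                cds_pos += 1
    return mapping


def pileup_genes(
    alignments: str | Path,
    genome: GenomeRecord,
    gene_annotations: list[GeneAnnotation],
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> list[PileupSite]:
    """Pileup over spliced CDS positions from a SAM/BAM file or a pileup TSV.

    One site per CDS position with depth > 0, counts in coding-strand sense.
    """
    path = Path(alignments)
    if path.suffix.lower() not in (".sam", ".bam", ".cram"):
        return read_pileup_tsv(path)

    import pysam

    mapping = _cds_position_map(genome, gene_annotations)
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        refs = set(fh.references or ())
        if refs and genome.id not in refs:
            raise ValueError(
                f"alignment references {sorted(refs)} do not include genome id "
                f"{genome.id!r}"
            )
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if read.reference_name != genome.id:
                raise ValueError(
                    f"alignment reference {read.reference_name!r} does not match "
                    f"genome id {genome.id!r}"
                )
            quals = read.query_qualities
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                hit = mapping.get((genome.id, rpos))
                if hit is None:
                    continue
                gene, cds_pos, strand, _ = hit
                base = seq[qpos].upper()
                if strand == "-":
                    base = _COMP.get(base, "N")
                counts[(gene, cds_pos)][base if base in "ACGTN" else "N"] += 1

    sites = []
    ref_lookup = {(g, p): ref for (_, _), (g, p, _, ref) in mapping.items()}
    for (gene, cds_pos), ctr in sorted(counts.items()):
        base_counts = {b: ctr.get(b, 0) for b in "ACGTN"}
        sites.append(
            PileupSite(gene, cds_pos, ref_lookup[(gene, cds_pos)], sum(base_counts.values()), base_counts)
        )
    return sites


# ---------------------------------------------------------------------------
# calling and classification
# ---------------------------------------------------------------------------

def call_c_to_u(
    sites: list[PileupSite], min_depth: int = 10, min_fraction: float = 0.10
) -> list[EditingSite]:
    """Call a site iff ref is C, depth >= min_depth and T/(depth-N) >= min_fraction.

    Only the C(genome)->T(reads) class is ever called.
    """
    called = []
    for s in sites:
        if s.ref_base != "C" or s.depth < min_depth:
            continue
        informative = s.depth - s.base_counts.get("N", 0)
        if informative <= 0:
            continue
        frac = s.base_counts.get("T", 0) / informative
        if frac >= min_fraction:
            called.append(EditingSite(s.gene_id, s.cds_pos, frac, s.depth))
    return called


def classify_consequence(
    genome: GenomeRecord, gene: GeneAnnotation, site: EditingSite
) -> EditingSite:
    """Fill in consequence and codon change for a called site.

    Rules: silent if the amino acid is unchanged (including stop->stop);
    stop_gain if a non-stop codon becomes a stop; at codon index 0,
    start_gain if the edited codon is ATG, otherwise start_codon_edit;
    stop_codon_edit if the annotated stop codon loses its stop; missense
    otherwise.
    """
    cds = extract_spliced_cds(genome, gene)
    if not (0 <= site.cds_pos < len(cds)):
        raise ValueError(
            f"{gene.gene_id}: cds_pos {site.cds_pos} outside spliced CDS "
            f"(length {len(cds)}); caller must pre-filter intron/UTR sites"
        )
    if cds[site.cds_pos] != "C":
        raise ValueError(f"{gene.gene_id}:{site.cds_pos}: reference base is not C")
    codon_idx = site.cds_pos // 3
    offset = site.cds_pos % 3
    codon_before = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_before) < 3:
        raise ValueError(f"{gene.gene_id}: trailing partial codon at site {site.cds_pos}")
    codon_after = codon_before[:offset] + "T" + codon_before[offset + 1 :]
    aa_before = STANDARD_CODE.get(codon_before, "X")
    aa_after = STANDARD_CODE.get(codon_after, "X")

    n_codons = len(cds) // 3
    if aa_before == aa_after:
        consequence = "silent"
    elif codon_idx == 0:
        consequence = "start_gain" if codon_after == "ATG" else "start_codon_edit"
    elif aa_after == "*":
        consequence = "stop_gain"
    elif aa_before == "*" and codon_idx == n_codons - 1:
        consequence = "stop_codon_edit"
    else:
        consequence = "missense"

    site.consequence = consequence
    site.codon_change = CodonChange(
        codon_before, codon_after, aa_before, aa_after, offset + 1
    )
    return site


def summarize_editing(
    sites: list[EditingSite], genes: list[GeneAnnotation], genome: GenomeRecord | None = None
) -> EditingSummary:
    """Per-gene and amino-acid-level summaries over classified sites.

    Codon changes are counted per distinct codon (two edits in one codon are
    one codon change); the amino-acid matrix counts nonsilent sites.
    """
    genes_by_id = {g.gene_id: g for g in genes}
    per_gene: dict[str, dict] = {}
    matrix: dict[tuple[str, str], int] = defaultdict(int)
    pos_counts = {1: 0, 2: 0, 3: 0}
    cons_counts: dict[str, int] = defaultdict(int)
    changed_codons: dict[str, set[int]] = defaultdict(set)
    start_gains, stop_gains = [], []

    for s in sites:
        if s.consequence is None or s.codon_change is None:
            raise ValueError(f"site {s.gene_id}:{s.cds_pos} not classified")
        cons_counts[s.consequence] += 1
        pos_counts[s.codon_change.codon_position_edited] += 1
        if s.consequence != "silent":
            matrix[(s.codon_change.aa_before, s.codon_change.aa_after)] += 1
            changed_codons[s.gene_id].add(s.cds_pos // 3)
        if s.consequence == "start_gain":
            start_gains.append(s)
        elif s.consequence == "stop_gain":
            stop_gains.append(s)
        per_gene.setdefault(s.gene_id, {"n_sites": 0})["n_sites"] += 1

    for gid, stats in per_gene.items():
        gene = genes_by_id.get(gid)
        cds_len = None
        if gene is not None:
            cds_len = gene.spliced_length(genome.length if genome else None) - gene.codon_start
        stats["n_codon_changes"] = len(changed_codons.get(gid, ()))
        stats["cds_length"] = cds_len
        stats["density"] = stats["n_sites"] / cds_len if cds_len else None

    return EditingSummary(
        per_gene=per_gene,
        aa_conversion_matrix=dict(matrix),
        codon_position_counts=pos_counts,
        consequence_counts=dict(cons_counts),
        start_gains=start_gains,
        stop_gains=stop_gains,
        n_sites=len(sites),
        n_silent=cons_counts.get("silent", 0),
    )


def compare_with_predictions(
    called: list[EditingSite], predicted: list[tuple[str, int]]
) -> dict[str, set[tuple[str, int]]]:
    """Exact (gene, cds_pos) set algebra against an external prediction list."""
    pred_set = set()
    dupes = 0
    for key in predicted:
        key = (key[0], int(key[1]))
        if key in pred_set:
            dupes += 1
        pred_set.add(key)
    if dupes:
        warnings.warn(f"collapsed {dupes} duplicate predictions", stacklevel=2)
    called_set = {(s.gene_id, s.cds_pos) for s in called}
    return {
        "confirmed": called_set & pred_set,
        "called_only": called_set - pred_set,
        "predicted_only": pred_set - called_set,
    }
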