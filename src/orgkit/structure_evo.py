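"""Gene-cluster retention scoring and cis/trans intron classification.

The default cluster catalog (14 ancestral angiosperm mitochondrial clusters)
ships as a packaged TSV; membership beyond the well-known clusters is a
replaceable default — pass your own catalog to override.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .core_model import GeneAnnotation, GenomeRecord

EVIDENCE = ("adjacent_same_strand", "strand_switch", "distance_exceeded", "order_violation")


@dataclass
class GeneClusterCatalog:
    clusters: list[tuple[str, list[str]]]

    @classmethod
    def default(cls) -> "GeneClusterCatalog":
        path = resources.files("orgkit") / "data" / "ancestral_clusters.tsv"
        return cls.load(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "GeneClusterCatalog":
        clusters = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                clusters.append((row[0], [g.strip() for g in row[1].split(",")]))
        return cls(clusters)

    def all_genes(self) -> set[str]:
        return {g.lower() for _, genes in self.clusters for g in genes}


@dataclass
class IntronCall:
    gene_id: str
    intron_index: int  # 0-based, between exon i and i+1 in transcription order
    mode: str  # cis | trans
    evidence: str


@dataclass
class ClusterVerdict:
    name: str
    status: str  # retained | lost | unevaluable
    genes: list[str]
    missing_genes: list[str]
    breakpoint_genes: list[str]


def _gene_locus(gene: GeneAnnotation, L: int) -> tuple[int, int, str]:
    """Representative genomic span (start, end, strand) over all exons."""
    starts = [e.start for e in gene.exons]
    ends = [e.end for e in gene.exons]
    strands = [e.strand for e in gene.exons]
    strand = max(set(strands), key=strands.count)
    return min(starts), max(ends), strand


def check_cluster_retention(
    annotations: list[GeneAnnotation],
    catalog: GeneClusterCatalog | None = None,
    genome: GenomeRecord | None = None,
    max_gap: int = 5000,
) -> dict[str, ClusterVerdict]:
    """Score each catalog cluster as retained / lost / unevaluable.

    Retained iff its genes appear consecutively in the circular order of
    catalog genes (no intervening catalog gene), in order or exactly reversed,
    all on one strand, with inter-gene gaps <= ``max_gap``.
    A cluster with any member absent from the annotations is unevaluable.
    """
    catalog = catalog or GeneClusterCatalog.default()
    L = genome.length if genome is not None else None
    circular = genome.is_circular if genome is not None else False

    by_name: dict[str, GeneAnnotation] = {}
    for g in annotations:
        by_name.setdefault(g.gene_id.lower(), g)

    catalog_genes = catalog.all_genes()
    present = [
        (name, *_gene_locus(by_name[name], L or 0))
        for name in sorted(by_name)
        if name in catalog_genes
    ]
    present.sort(key=lambda t: t[1])  # circular order of catalog genes by start
    order = [name for name, *_ in present]
    locus = {name: (s, e, st) for name, s, e, st in present}

    verdicts: dict[str, ClusterVerdict] = {}
    for cname, genes in catalog.clusters:
        genes_l = [g.lower() for g in genes]
        missing = [g for g in genes_l if g not in locus]
        if missing:
            verdicts[cname] = ClusterVerdict(cname, "unevaluable", genes_l, missing, [])
            continue
        verdicts[cname] = _score_cluster(cname, genes_l, order, locus, max_gap, L, circular)
    return verdicts


def _score_cluster(cname, genes_l, order, locus, max_gap, L, circular):
    n = len(order)
    idx = {name: i for i, name in enumerate(order)}
    positions = sorted(idx[g] for g in genes_l)
    k = len(genes_l)

    def contiguous(pos: list[int]) -> bool:
        if pos[-1] - pos[0] == k - 1:
            return True
        if circular:
            # a run modulo n: all circular gaps are 1 except the single return gap
            gaps = [(pos[(i + 1) % k] - pos[i]) % n for i in range(k)]
            return sorted(gaps)[:-1] == [1] * (k - 1)
        return False

    if k > 1 and not contiguous(positions):
        intervening = [
            order[i]
            for i in range(positions[0], positions[-1] + 1)
            if order[i] not in genes_l
        ]
        return ClusterVerdict(cname, "lost", genes_l, [], intervening or [order[positions[0]]])

    pos_set = set(positions)
    run_start = next(
        (p for p in positions if (p - 1) % n not in pos_set or k == n), positions[0]
    )
    run = [order[i % n] for i in range(run_start, run_start + k)]
    if run != genes_l and run != genes_l[::-1]:
        if set(run) == set(genes_l):
            return ClusterVerdict(cname, "lost", genes_l, [], ["order_violation"])
        return ClusterVerdict(cname, "lost", genes_l, [], ["order_violation"])

    strands = {locus[g][2] for g in genes_l}
    if len(strands) > 1:
        return ClusterVerdict(cname, "lost", genes_l, [], ["strand_switch"])

    # gaps measured along the run's own adjacency arcs (forward, wrapping)
    for g1, g2 in zip(run, run[1:]):
        gap = locus[g2][0] - locus[g1][1]
        if circular and L:
            gap %= L
        if gap < 0 or gap > max_gap:
            return ClusterVerdict(cname, "lost", genes_l, [], ["distance_exceeded"])
    return ClusterVerdict(cname, "retained", genes_l, [], [])


def classify_intron_splicing(
    gene: GeneAnnotation,
    genome: GenomeRecord | None = None,
    max_intron_span: int = 50000,
) -> list[IntronCall]:
    """One call per adjacent exon pair in transcription order.

    cis iff same strand, genomic order matches transcription order for that
    strand, and the genomic gap (shorter arc on circles) <= ``max_intron_span``;
    otherwise trans with the triggering evidence code.
    """
    calls = []
    L = genome.length if genome is not None else None
    circular = genome.is_circular if genome is not None else False
    for i, (a, b) in enumerate(zip(gene.exons, gene.exons[1:])):
        if a.strand != b.strand:
            calls.append(IntronCall(gene.gene_id, i, "trans", "strand_switch"))
            continue
        if a.strand == "+":
            gap = b.start - a.end  # downstream distance along transcription
        else:
            gap = a.start - b.end
        if circular and L:
            downstream = gap % L
            if downstream <= max_intron_span:
                calls.append(IntronCall(gene.gene_id, i, "cis", "adjacent_same_strand"))
            elif L - downstream <= max_intron_span:
                # next exon lies a short arc *upstream*: rearranged order
                calls.append(IntronCall(gene.gene_id, i, "trans", "order_violation"))
            else:
                calls.append(IntronCall(gene.gene_id, i, "trans", "distance_exceeded"))
            continue
        if gap < 0:
            calls.append(IntronCall(gene.gene_id, i, "trans", "order_violation"))
        elif gap > max_intron_span:
            calls.append(IntronCall(gene.gene_id, i, "trans", "distance_exceeded"))
        else:
            calls.append(IntronCall(gene.gene_id, i, "cis", "adjacent_same_strand"))
    return calls
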