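"""Supermatrix concatenation, PHI recombination test and topology conflict.

The PHI statistic follows the refined-incompatibility formulation: the score
of a site pair is the cycle rank of its partition intersection graph (0 iff
the pair is compatible; for two binary sites showing all four gametes it is
1), and the windowed mean is compared against its permutation distribution
either analytically (exact permutation moments, normal approximation) or by
explicit site-order permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.stats import norm

from .core_model import GenomeRecord  # noqa: F401  (re-export convenience)

MISSING = set("-?NnXx.")
_STATES = "ACGT"


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    taxa: list[str]
    columns: int
    partitions: list[tuple[str, int, int]]  # (gene_id, start, end) 1-based inclusive
    matrix: dict[str, str]  # taxon -> row of length `columns`

    def __post_init__(self) -> None:
        assert self.columns == sum(e - s + 1 for _, s, e in self.partitions), (
            "partition widths do not tile the matrix"
        )
        for taxon, row in self.matrix.items():
            if len(row) != self.columns:
                raise ValueError(f"row {taxon!r} has length {len(row)} != {self.columns}")


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    widths = {len(s) for s in aln.values()}
    if len(widths) > 1:
        rows = {t: len(s) for t, s in aln.items()}
        raise ValueError(f"ragged alignment in {path}: row lengths {rows}")
    return aln


def concatenate(
    alignments: list[tuple[str, dict[str, str]]],
    taxon_map: dict[str, str] | None = None,
) -> Supermatrix:
    """Concatenate per-gene alignments; missing taxa padded with '?'.

    ``alignments`` is a list of (gene_id, {taxon: aligned sequence}); the
    optional ``taxon_map`` renames input taxa before merging.
    """
    taxon_map = taxon_map or {}
    renamed = []
    for gene_id, aln in alignments:
        widths = {len(s) for s in aln.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment for {gene_id}: {sorted(widths)}")
        renamed.append((gene_id, {taxon_map.get(t, t): s for t, s in aln.items()}))

    taxa = sorted({t for _, aln in renamed for t in aln})
    parts: list[tuple[str, int, int]] = []
    rows = {t: [] for t in taxa}
    col = 0
    for gene_id, aln in renamed:
        width = len(next(iter(aln.values()))) if aln else 0
        parts.append((gene_id, col + 1, col + width))
        for t in taxa:
            rows[t].append(aln.get(t, "?" * width))
        col += width
    return Supermatrix(
        taxa=taxa,
        columns=col,
        partitions=parts,
        matrix={t: "".join(chunks) for t, chunks in rows.items()},
    )


def write_supermatrix(sm: Supermatrix, fasta_path: str | Path, partition_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n")
            row = sm.matrix[t]
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")
    with open(partition_path, "w") as fh:
        for gene_id, s, e in sm.partitions:
            fh.write(f"DNA, {gene_id} = {s}-{e}\n")


def read_supermatrix(fasta_path: str | Path, partition_path: str | Path) -> Supermatrix:
    aln = read_fasta_alignment(fasta_path)
    parts = []
    with open(partition_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, rng = line.split("=")
            gene_id = name.split(",")[1].strip()
            s, e = rng.strip().split("-")
            parts.append((gene_id, int(s), int(e)))
    taxa = sorted(aln)
    return Supermatrix(taxa=taxa, columns=len(next(iter(aln.values()))), partitions=parts, matrix=aln)


# ---------------------------------------------------------------------------
# PHI test
# ---------------------------------------------------------------------------

@dataclass
class PhiResult:
    phi_observed: float | None
    p_analytic: float | None
    p_permutation: float | None
    informative_pairs: int
    window_w: int
    n_informative_sites: int
    uninformative: bool = False


def parsimony_informative_columns(matrix: dict[str, str]) -> list[int]:
    """Columns with >= 2 states each present in >= 2 taxa (missing excluded)."""
    taxa = sorted(matrix)
    ncol = len(matrix[taxa[0]])
    out = []
    for j in range(ncol):
        counts: dict[str, int] = {}
        for t in taxa:
            c = matrix[t][j]
            if c in MISSING:
                continue
            counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append(j)
    return out


def pair_incompatibility(col_a: list[str], col_b: list[str]) -> int:
    """Refined incompatibility: cycle rank of the partition intersection graph.

    Rows where either site is missing are excluded.  0 iff compatible.
    """
    pairs = set()
    for a, b in zip(col_a, col_b):
        if a in MISSING or b in MISSING:
            continue
        pairs.add((a, b))
    if not pairs:
        return 0
    va = {a for a, _ in pairs}
    vb = {b for _, b in pairs}
    nodes = {("a", s): i for i, s in enumerate(sorted(va))}
    nodes.update({("b", s): len(nodes) + i for i, s in enumerate(sorted(vb))})
    parent = list(range(len(nodes)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    components = len(nodes)
    for a, b in pairs:
        ra, rb = find(nodes[("a", a)]), find(nodes[("b", b)])
        if ra != rb:
            parent[rb] = ra
            components -= 1
    edges = len(pairs)
    return edges - len(nodes) + components


def _permutation_moments(scores: np.ndarray, window_mask: np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of T = sum_{i!=j} B_ij A_{s(i)s(j)} under a
    uniform permutation s, for symmetric zero-diagonal A (scores) and B
    (window indicator)."""
    n = scores.shape[0]

    def sums(m: np.ndarray) -> tuple[float, float, float, float]:
        s1 = float(m.sum())
        s2 = float((m * m).sum())
        rows = m.sum(axis=1)
        s3 = float((rows * rows).sum()) - s2  # ordered tuples sharing one index
        s4 = s1 * s1 - 2 * s2 - 4 * s3
        return s1, s2, s3, s4

    a1, a2, a3, a4 = sums(scores)
    b1, b2, b3, b4 = sums(window_mask.astype(float))
    d2 = n * (n - 1)
    d3 = d2 * (n - 2)
    d4 = d3 * (n - 3)
    mean = b1 * a1 / d2
    second = 2 * a2 * b2 / d2 + 4 * a3 * b3 / d3 + (a4 * b4 / d4 if n > 3 else 0.0)
    var = second - mean * mean
    return mean, max(var, 0.0)


def phi_test(
    matrix: dict[str, str],
    window_w: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PhiResult:
    """Pairwise homoplasy index over informative-site pairs within ``window_w``
    of each other (distance in informative-site order).

    One-sided: recombination manifests as the windowed mean being *low*
    relative to the permutation distribution of site order.
    """
    if len(matrix) < 4:
        raise ValueError("PHI requires >= 4 taxa")
    taxa = sorted(matrix)
    informative = parsimony_informative_columns(matrix)
    k = len(informative)
    if k < 2:
        return PhiResult(None, None, None, 0, window_w, k, uninformative=True)

    cols = [[matrix[t][j] for t in taxa] for j in informative]
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = pair_incompatibility(cols[i], cols[j])
            scores[i, j] = scores[j, i] = s

    window = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, min(i + window_w + 1, k)):
            window[i, j] = window[j, i] = True
    n_pairs = int(window.sum()) // 2
    t_obs = float((scores * window).sum())  # ordered sum (2x unordered)
    phi_obs = t_obs / (2 * n_pairs)

    mean, var = _permutation_moments(scores, window)
    if var > 0:
        z = (t_obs - mean) / math.sqrt(var)
        p_analytic = float(norm.cdf(z))
    else:
        p_analytic = 1.0

    p_perm = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(k)
            t_p = float((scores[np.ix_(perm, perm)] * window).sum())
            if t_p <= t_obs + 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)

    return PhiResult(
        phi_observed=phi_obs,
        p_analytic=p_analytic,
        p_permutation=p_perm,
        informative_pairs=n_pairs,
        window_w=window_w,
        n_informative_sites=k,
    )


# ---------------------------------------------------------------------------
# topology conflict
# ---------------------------------------------------------------------------

@dataclass
class ConflictReport:
    tree_pair: tuple[str, str]
    shared_bipartitions: int
    conflicting_bipartitions: list[tuple[frozenset, str, float | None]]
    rf_distance: int
    n_leaves: int


def _nontrivial_bipartitions(tree: dendropy.Tree, leaves: frozenset) -> dict[frozenset, float | None]:
    """Canonical nontrivial bipartitions: each split keyed by the side *not*
    containing the alphabetically first leaf; value is the edge support."""
    ref = min(leaves)
    out: dict[frozenset, float | None] = {}
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        support = None
        if node.label:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        out[side] = support
    return out


def compare_topologies(tree_a: str, tree_b: str, labels: tuple[str, str] = ("A", "B")) -> ConflictReport:
    """Unrooted bipartition comparison of two Newick trees after pruning to
    the shared leaf set; RF distance = splits unique to A + unique to B."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=tree_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=tree_b, schema="newick", taxon_namespace=tns)
    la = {lf.taxon.label for lf in ta.leaf_node_iter()}
    lb = {lf.taxon.label for lf in tb.leaf_node_iter()}
    shared = la & lb
    if not shared or len(shared) < 4:
        diff = sorted(la ^ lb)
        raise ValueError(
            f"leaf sets incompatible after pruning (symmetric difference: {diff})"
        )
    if la != shared:
        ta.retain_taxa_with_labels(sorted(shared))
    if lb != shared:
        tb.retain_taxa_with_labels(sorted(shared))
    leaves = frozenset(shared)
    ba = _nontrivial_bipartitions(ta, leaves)
    bb = _nontrivial_bipartitions(tb, leaves)
    shared_splits = set(ba) & set(bb)
    only_a = set(ba) - set(bb)
    only_b = set(bb) - set(ba)
    conflicts = [(s, labels[0], ba[s]) for s in sorted(only_a, key=sorted)] + [
        (s, labels[1], bb[s]) for s in sorted(only_b, key=sorted)
    ]
    return ConflictReport(
        tree_pair=labels,
        shared_bipartitions=len(shared_splits),
        conflicting_bipartitions=conflicts,
        rf_distance=len(only_a) + len(only_b),
        n_leaves=len(shared),
    )
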