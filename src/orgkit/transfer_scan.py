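"""Plastid-to-mitochondrion transfer scanning, ORF finding and chimera flagging.

The local-similarity engine is the BLAST+ ``blastn`` executable (pairwise
``-subject`` mode, no database build needed); this module owns the thresholds,
locus bookkeeping and merge semantics.  Identity is matches / alignment
columns, with gaps counting against identity (blastn's ``pident``).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .core_model import (
    GeneAnnotation,
    GenomeRecord,
    SegmentInterval,
    extract_spliced,
    translate,
    write_genome,
)

_OUTFMT = "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"


@dataclass(frozen=True)
class TransferHit:
    query_locus: SegmentInterval  # on the plastome
    subject_locus: SegmentInterval  # on the mitogenome
    length: int  # alignment columns
    identity: float  # fraction
    evalue: float


@dataclass
class TransferSummary:
    n_fragments: int
    total_bp: int
    fragments: list[SegmentInterval]


@dataclass
class OrfCall:
    locus: SegmentInterval
    length: int  # nt including the stop codon
    protein: str
    partial: bool = False
    chimera_evidence: list[tuple] = field(default_factory=list)
    # evidence entries: (gene_id, fragment_locus_on_orf, identity, length)


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise RuntimeError("blastn executable not found on PATH")
    return exe


def run_blastn(
    query: GenomeRecord | list[GenomeRecord],
    subject: GenomeRecord | list[GenomeRecord],
    evalue: float,
    word_size: int = 11,
    task: str = "blastn",
) -> list[dict]:
    """Pairwise blastn; returns tabular rows as dicts (coordinates kept 1-based)."""
    exe = _require_blastn()
    with tempfile.TemporaryDirectory() as tmp:
        qf, sf = Path(tmp) / "q.fa", Path(tmp) / "s.fa"
        write_genome(query, qf)
        write_genome(subject, sf)
        cmd = [
            exe, "-task", task, "-query", str(qf), "-subject", str(sf),
            "-evalue", str(evalue), "-word_size", str(word_size),
            "-dust", "no", "-outfmt", _OUTFMT,
        ]
        res = subprocess.run(cmd, capture_output=True, text=True, check=True)
    rows = []
    keys = _OUTFMT.split()[1:]
    for line in res.stdout.splitlines():
        vals = line.split("\t")
        row = dict(zip(keys, vals))
        for key in ("pident", "evalue", "bitscore"):
            row[key] = float(row[key])
        for key in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
            row[key] = int(row[key])
        rows.append(row)
    return rows


def _locus_from_blast(start: int, end: int) -> SegmentInterval:
    """1-based blastn coordinates to a stranded 0-based half-open interval."""
    if start <= end:
        return SegmentInterval(start - 1, end, "+")
    return SegmentInterval(end - 1, start, "-")


def find_mipts(
    mitogenome: GenomeRecord,
    plastome: GenomeRecord,
    min_len: int = 50,
    min_identity: float = 0.80,
    max_evalue: float = 1e-10,
    word_size: int = 11,
) -> list[TransferHit]:
    """Plastid-derived fragments in the mitogenome (both strands).

    Hits below the length/identity/e-value thresholds are discarded; the
    trivial full-length self-hit is suppressed when query id == subject id.
    Hits are sorted by mitogenome coordinate; use :func:`summarize_transfers`
    for the merged fragment count and total bp.
    """
    rows = run_blastn(plastome, mitogenome, evalue=max_evalue, word_size=word_size)
    hits = []
    for r in rows:
        if r["length"] < min_len or r["pident"] < min_identity * 100 or r["evalue"] > max_evalue:
            continue
        if (
            r["qseqid"] == r["sseqid"]
            and r["qstart"] == r["sstart"]
            and r["qend"] == r["send"]
        ):
            continue  # degenerate self-comparison
        hits.append(
            TransferHit(
                query_locus=_locus_from_blast(r["qstart"], r["qend"]),
                subject_locus=_locus_from_blast(r["sstart"], r["send"]),
                length=r["length"],
                identity=r["pident"] / 100.0,
                evalue=r["evalue"],
            )
        )
    hits.sort(key=lambda h: (h.subject_locus.start, h.subject_locus.end))
    return hits


def summarize_transfers(hits: list[TransferHit]) -> TransferSummary:
    """Merge mitogenome-side loci overlapping by >= 1 bp; sum merged lengths."""
    ivs = sorted((h.subject_locus.start, h.subject_locus.end) for h in hits)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    frags = [SegmentInterval(s, e, "+") for s, e in merged]
    return TransferSummary(
        n_fragments=len(frags),
        total_bp=sum(e - s for s, e in merged),
        fragments=frags,
    )


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(genome: GenomeRecord, min_len: int = 150) -> list[OrfCall]:
    """ATG-initiated ORFs >= ``min_len`` nt (stop codon included), six frames.

    Longest-per-stop rule: only the first ATG after the previous in-frame stop
    is reported.  Circular wrap honoured via the doubled-sequence view with
    deduplication modulo the genome length.
    """
    L = genome.length
    out: list[OrfCall] = []
    seen: set[tuple] = set()
    for strand in "+-":
        seq = genome.doubled()
        if strand == "-":
            from .core_model import reverse_complement

            seq = reverse_complement(seq)
        n = len(seq)
        for frame in range(3):
            start_atg: int | None = None
            i = frame
            while i + 3 <= n:
                codon = seq[i : i + 3]
                if codon in _STOPS:
                    if start_atg is not None:
                        _emit_orf(out, seen, genome, strand, seq, start_atg, i + 3, L)
                    start_atg = None
                elif codon == "ATG" and start_atg is None:
                    start_atg = i
                i += 3
            if start_atg is not None and not genome.is_circular:
                # runs off the end of a linear genome: declared partial
                end = n - (n - start_atg) % 3
                if end - start_atg >= 3:
                    _emit_orf(out, seen, genome, strand, seq, start_atg, end, L, partial=True)
    out = [o for o in out if o.length >= min_len]
    out.sort(key=lambda o: (o.locus.start, o.locus.strand))
    return out


def _emit_orf(out, seen, genome, strand, frame_seq, s, e, L, partial=False):
    length = e - s
    if length > L:
        return
    n = len(frame_seq)
    if strand == "+":
        g_start = s
    else:
        g_start = n - e  # start on forward strand coordinates
    if genome.is_circular:
        if g_start >= L:
            return
        g_end = g_start + length
        locus = (
            SegmentInterval(g_start, g_end, strand)
            if g_end <= L
            else SegmentInterval(g_start, g_end - L, strand, wraps_origin=True)
        )
    else:
        locus = SegmentInterval(g_start, g_start + length, strand)
    key = locus.as_tuple()
    if key in seen:
        return
    seen.add(key)
    cds = frame_seq[s:e]
    prot = translate(cds)
    if prot.endswith("*"):
        prot = prot[:-1]
    out.append(OrfCall(locus=locus, length=length, protein=prot, partial=partial))


# ---------------------------------------------------------------------------
# chimeric ORFs
# ---------------------------------------------------------------------------

def flag_chimeric_orfs(
    orfs: list[OrfCall],
    gene_annotations: list[GeneAnnotation],
    genome: GenomeRecord,
    min_frag: int = 30,
    min_identity: float = 0.90,
    max_evalue: float = 1e-3,
) -> list[OrfCall]:
    """Populate ``chimera_evidence`` on each ORF from similarity to annotated
    gene sequences (fragments >= ``min_frag`` bp at >= ``min_identity``).

    An ORF overlapping a gene's own genomic exons cannot take that gene as
    evidence for itself.
    """
    if not orfs or not gene_annotations:
        return orfs
    orf_records = [
        GenomeRecord(id=f"orf{i}", sequence=genome.fetch(o.locus))
        for i, o in enumerate(orfs)
    ]
    gene_records = [
        GenomeRecord(id=g.gene_id, sequence=extract_spliced(genome, g))
        for g in gene_annotations
    ]
    genes_by_id = {g.gene_id: g for g in gene_annotations}
    L = genome.length
    rows = run_blastn(orf_records, gene_records, evalue=max_evalue, word_size=11)
    for r in rows:
        if r["length"] < min_frag or r["pident"] < min_identity * 100:
            continue
        orf = orfs[int(r["qseqid"][3:])]
        gene = genes_by_id[r["sseqid"]]
        if _overlaps_gene(orf.locus, gene, L):
            continue
        frag = _locus_from_blast(r["qstart"], r["qend"])
        orf.chimera_evidence.append((gene.gene_id, frag, r["pident"] / 100.0, r["length"]))
    return orfs


def _overlaps_gene(locus: SegmentInterval, gene: GeneAnnotation, L: int) -> bool:
    def _cover(iv: SegmentInterval) -> set[int]:
        n = iv.length(L)
        return {(iv.start + t) % L for t in range(n)}

    oc = _cover(locus)
    return any(oc & _cover(e) for e in gene.exons)
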