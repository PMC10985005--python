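"""Shared data model for annotated organelle genomes.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
1-based inclusive.  Circular genomes are first-class: a :class:`SegmentInterval`
may wrap the sequence origin, and helpers exist to obtain a doubled-sequence
view for window scans (hits are deduplicated modulo the genome length by the
scanning modules).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import unambiguous_dna_by_id

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")

#: translation table 1 (standard code), codon -> one-letter amino acid, '*' for stops
STANDARD_CODE: dict[str, str] = dict(unambiguous_dna_by_id[1].forward_table)
STANDARD_CODE.update({c: "*" for c in unambiguous_dna_by_id[1].stop_codons})


class Topology(str, Enum):
    circular = "circular"
    linear = "linear"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A circular or linear annotated sequence; the substrate of all scans."""

    id: str
    sequence: str
    topology: Topology = Topology.linear

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in _VALID), None)
        if bad is not None:
            raise ValueError(
                f"genome {self.id!r}: non-IUPAC character {self.sequence[bad]!r} "
                f"at offset {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.circular

    def doubled(self) -> str:
        """Doubled-sequence view (length 2L) for circular window scans."""
        return self.sequence * 2 if self.is_circular else self.sequence

    def fetch(self, interval: "SegmentInterval") -> str:
        """Sequence of an interval, wrap and strand honoured."""
        return interval.extract(self.sequence, circular=self.is_circular)


@dataclass(frozen=True)
class SegmentInterval:
    """0-based half-open interval [start, end) with strand.

    ``wraps_origin`` marks a feature crossing the circular origin; in that
    case ``start > end`` in genomic coordinates and the parent genome must be
    circular.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if not self.wraps_origin and self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start
        if genome_length is None:
            raise ValueError("wrapped interval needs the genome length")
        return (genome_length - self.start) + self.end

    def extract(self, sequence: str, circular: bool = False) -> str:
        if self.wraps_origin:
            if not circular:
                raise ValueError("wrapped interval on a linear genome")
            sub = sequence[self.start :] + sequence[: self.end]
        else:
            if self.end > len(sequence):
                raise ValueError(
                    f"interval [{self.start}, {self.end}) outside genome of "
                    f"length {len(sequence)}"
                )
            sub = sequence[self.start : self.end]
        return reverse_complement(sub) if self.strand == "-" else sub

    def as_tuple(self) -> tuple[int, int, str, bool]:
        return (self.start, self.end, self.strand, self.wraps_origin)


@dataclass
class GeneAnnotation:
    """A gene model; exon list order defines the mRNA (enables trans-splicing)."""

    gene_id: str
    biotype: str  # CDS | tRNA | rRNA | ORF
    exons: list[SegmentInterval]
    codon_start: int = 0
    origin: str = ""  # free-form provenance tag (e.g. plastid-derived)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        if self.codon_start not in (0, 1, 2):
            raise ValueError(f"gene {self.gene_id!r}: codon_start {self.codon_start}")

    def spliced_length(self, genome_length: int | None = None) -> int:
        return sum(e.length(genome_length) for e in self.exons)


@dataclass(frozen=True)
class CodonChange:
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str
    codon_position_edited: int  # 1, 2 or 3

    def __post_init__(self) -> None:
        p = self.codon_position_edited - 1
        if not (0 <= p <= 2):
            raise ValueError("codon_position_edited must be 1, 2 or 3")
        if self.codon_before[p] != "C" or self.codon_after[p] != "T":
            raise ValueError(
                f"{self.codon_before}->{self.codon_after} is not a C->T change at "
                f"codon position {self.codon_position_edited}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(fasta_path: str | Path, topology: Topology | str = Topology.linear) -> list[GenomeRecord]:
    """Load FASTA records as :class:`GenomeRecord` objects (case folded up)."""
    topology = Topology(topology)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = re.search(f"[^{''.join(sorted(_VALID))}]", seq)
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-IUPAC character {bad.group()!r} at "
                f"offset {bad.start()}"
            )
        records.append(GenomeRecord(id=rec.id, sequence=seq, topology=topology))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return records


def write_genome(records: GenomeRecord | Iterable[GenomeRecord], fasta_path: str | Path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    if isinstance(records, GenomeRecord):
        records = [records]
    seqrecs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genome: GenomeRecord, genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write gene models as GFF3: a `gene` line plus ordered `exon` children.

    ``exon_number`` encodes transcription order, which may disagree with
    genomic order for trans-spliced genes.  Origin-wrapping exons are not
    representable in GFF3 and are rejected.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in genes:
            starts = [e.start for e in g.exons]
            ends = [e.end for e in g.exons]
            if any(e.wraps_origin for e in g.exons):
                raise ValueError(f"gene {g.gene_id}: wrapped exon not representable in GFF3")
            strand = g.exons[0].strand
            attrs = f"ID={g.gene_id};biotype={g.biotype};codon_start={g.codon_start}"
            if g.origin:
                attrs += f";origin={g.origin}"
            fh.write(
                "\t".join(
                    [genome.id, "orgkit", "gene", str(min(starts) + 1), str(max(ends)),
                     ".", strand, ".", attrs]
                )
                + "\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [genome.id, "orgkit", "exon", str(e.start + 1), str(e.end),
                         ".", e.strand, ".",
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id};exon_number={i}"]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene models written by :func:`write_gff3` (or compatible GFF3)."""
    genes: dict[str, GeneAnnotation] = {}
    exon_buf: dict[str, list[tuple[int, SegmentInterval]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            _, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            kv = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if ftype == "gene":
                gid = kv["ID"]
                genes[gid] = GeneAnnotation(
                    gene_id=gid,
                    biotype=kv.get("biotype", "CDS"),
                    exons=[SegmentInterval(int(start) - 1, int(end), strand)],
                    codon_start=int(kv.get("codon_start", 0)),
                    origin=kv.get("origin", ""),
                )
                exon_buf[gid] = []
            elif ftype == "exon":
                gid = kv.get("Parent", "")
                n = int(kv.get("exon_number", len(exon_buf.get(gid, [])) + 1))
                exon_buf.setdefault(gid, []).append(
                    (n, SegmentInterval(int(start) - 1, int(end), strand))
                )
    out = []
    for gid, gene in genes.items():
        if exon_buf.get(gid):
            gene.exons = [e for _, e in sorted(exon_buf[gid], key=lambda t: t[0])]
        out.append(gene)
    return out


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

def extract_spliced_cds(genome: GenomeRecord, gene: GeneAnnotation) -> str:
    """Spliced CDS: exons in transcription order, minus-strand exons
    reverse-complemented, circular wrap honoured, ``codon_start`` trimmed."""
    if gene.biotype != "CDS":
        raise ValueError(f"gene {gene.gene_id!r}: biotype {gene.biotype!r} is not CDS")
    mrna = "".join(genome.fetch(e) for e in gene.exons)
    mrna = mrna[gene.codon_start :]
    if len(mrna) < 3:
        raise ValueError(f"gene {gene.gene_id!r}: spliced CDS shorter than one codon")
    return mrna


def extract_spliced(genome: GenomeRecord, gene: GeneAnnotation) -> str:
    """Spliced sequence for any biotype (no codon_start trimming)."""
    return "".join(genome.fetch(e) for e in gene.exons)


def translate(cds: str, table: dict[str, str] | None = None) -> str:
    """Translate a CDS with the standard code.

    Does *not* stop at internal stops ('*' emitted) so premature-stop gains can
    be annotated.  A trailing incomplete codon is dropped with a warning; any
    codon containing N translates to 'X'.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    code = table or STANDARD_CODE
    if len(cds) % 3:
        warnings.warn(
            f"dropping trailing incomplete codon of {len(cds) % 3} nt", stacklevel=2
        )
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aas.append(code.get(codon, "X"))
    return "".join(aas)


def gc_content(genome: GenomeRecord | str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator."""
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / acgt


_PRIORITY = {"CDS": 3, "ORF": 3, "rRNA": 2, "tRNA": 1}


def composition_summary(genome: GenomeRecord, annotations: Sequence[GeneAnnotation]) -> dict[str, float]:
    """Fractions of genome length covered by each biotype.

    A base pair belongs to the highest-priority biotype covering it:
    CDS > rRNA > tRNA > noncoding, so the four fractions are disjoint and
    sum to 1.
    """
    L = genome.length
    cover = np.zeros(L, dtype=np.int8)
    for g in annotations:
        pri = _PRIORITY.get(g.biotype, 0)
        for e in g.exons:
            if e.wraps_origin:
                idx = np.r_[np.arange(e.start, L), np.arange(0, e.end)]
            else:
                idx = np.arange(e.start, e.end)
            np.maximum.at(cover, idx, pri)
    counts = np.bincount(cover, minlength=4)
    return {
        "protein_coding": counts[3] / L,
        "rRNA": counts[2] / L,
        "tRNA": counts[1] / L,
        "noncoding": counts[0] / L,
    }
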