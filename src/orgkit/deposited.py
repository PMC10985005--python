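"""Loading locally vendored GenBank/FASTA records for the deposited-data checks.

The deposited organelle genome records are not shipped with the package; drop
them (GenBank flat file preferred, plain FASTA accepted) under
``data/deposited/<ACCESSION>.gb`` at the repository root, e.g. with
``scripts/fetch_deposited.py`` on a machine with NCBI access.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .core_model import GeneAnnotation, GenomeRecord, SegmentInterval, Topology

_SUFFIXES = (".gb", ".gbk", ".genbank", ".fasta", ".fa")

MITO_ACCESSION = "ON897690"
PLASTID_ACCESSION = "ON897689"


def find_record(data_dir: str | Path, accession: str) -> Optional[Path]:
    data_dir = Path(data_dir)
    for suffix in _SUFFIXES:
        p = data_dir / f"{accession}{suffix}"
        if p.exists():
            return p
    return None


def load_record(
    path: str | Path, topology: Topology | str = Topology.circular
) -> tuple[GenomeRecord, list[GeneAnnotation]]:
    """Parse a GenBank flat file (sequence + CDS gene models) or bare FASTA.

    CDS features become gene models whose exon order follows the feature's
    location parts — GenBank encodes trans-spliced mitochondrial genes as
    ``join(...)`` over out-of-order / mixed-strand segments, which is exactly
    the transcription-order contract of :class:`GeneAnnotation`.
    """
    from Bio import SeqIO

    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in (".fasta", ".fa") else "genbank"
    rec = next(SeqIO.parse(str(path), fmt))
    genome = GenomeRecord(
        id=rec.id.split(".")[0], sequence=str(rec.seq).upper(), topology=Topology(topology)
    )
    genes: list[GeneAnnotation] = []
    if fmt == "fasta":
        return genome, genes

    seen: set[str] = set()
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        key = f"{feat.type}:{name}"
        if key in seen:
            continue
        seen.add(key)
        exons = []
        for part in feat.location.parts:
            strand = "-" if part.strand == -1 else "+"
            exons.append(SegmentInterval(int(part.start), int(part.end), strand))
        codon_start = int((quals.get("codon_start") or ["1"])[0]) - 1
        biotype = "CDS" if feat.type == "CDS" else feat.type
        genes.append(GeneAnnotation(name, biotype, exons, codon_start=codon_start))
    return genome, genes
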