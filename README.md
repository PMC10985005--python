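# orgkit

Organelle genome structural analysis toolkit: dispersed repeat discovery and
inverted-repeat/single-copy partitioning, plastid-to-mitochondrion transfer
(MIPT) scanning, ORF and chimeric-ORF detection, empirical C-to-U RNA-editing
calling with codon-consequence classification, plastome isoform (form A /
form B) typing from long reads, ancestral gene-cluster retention and
cis/trans intron classification, and phylogenomic supermatrix construction
with the PHI recombination test and Robinson–Foulds conflict summaries.

Every analysis stage is exercisable end to end on seeded synthetic organelle
genomes with exact ground truth (`orgkit.synthetic_data`), so the whole
pipeline is testable offline.

## Library layout

| module | role |
| --- | --- |
| `orgkit.core_model` | genome/annotation data model, circular coordinates, FASTA + GFF3 I/O, translation |
| `orgkit.repeatscan` | maximal exact dispersed repeats (direct/inverted), size-class summaries, IR pair + LSC/SSC partition |
| `orgkit.transfer_scan` | MIPT scanning (blastn-backed), six-frame ORF finder, chimeric-ORF evidence |
| `orgkit.editing` | pileups over spliced CDS (SAM/BAM or TSV), C-to-U calling, consequence classification, summaries |
| `orgkit.isoform` | form-B construction from the IR pair, junction-anchor read typing, ratio estimation with Wilson CI |
| `orgkit.structure_evo` | gene-cluster retention against a packaged ancestral catalog, cis/trans intron calls |
| `orgkit.phylo_matrix` | supermatrix concatenation + partition files, PHI test (analytic + permutation p), RF conflict reports |
| `orgkit.synthetic_data` | deterministic generators: annotated genomes, edit pileups, two-isoform long reads, block alignments |

## CLI

```bash
orgkit sim genome --seed 1 --out-prefix g      # synthetic genome + GFF3 + truth JSON
orgkit repeats g.fa --min-len 30
orgkit ir plastome.fa
orgkit mipt mito.fa plastome.fa
orgkit orfs genome.fa --min-len 150
orgkit chimera genome.fa genes.gff3
orgkit edit call pileup.tsv genome.fa genes.gff3
orgkit isoform plastome.fa reads.fastq --min-anchor 200
orgkit clusters genes.gff3 genome.fa
orgkit introns genes.gff3 genome.fa
orgkit concat gene1.fa gene2.fa --out sm.fa --partitions sm.part
orgkit phi alignment.fa --window 100 --perm 1000 --seed 1
orgkit treediff a.nwk b.nwk
```

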