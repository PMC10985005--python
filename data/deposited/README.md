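# Deposited organelle genome records

The deposited-record checks (tests/test_acceptance.py criteria 1-3 and
acceptance targets t1-t10) run against the two GenBank records deposited by
the source study:

- `ON897689` — plastid genome (circular, 121,341 bp)
- `ON897690` — mitochondrial genome (circular, 1,174,803 bp)

These records are not redistributed with this repository.  On a machine with
NCBI access, populate this directory with:

    python scripts/fetch_deposited.py

which writes `ON897689.gb` and `ON897690.gb` here (GenBank flat files with
feature tables; plain FASTA named `<ACCESSION>.fasta` is also accepted but
does not support the annotation-dependent checks).

When the files are absent, the deposited-data acceptance tests fail with an
explanatory message and `scripts/acceptance.py` omits the corresponding
targets.
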