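#!/usr/bin/env python
"""Fetch the deposited organelle genome records from NCBI into data/deposited/.

Run this on a machine with internet access before the deposited-data checks:

    python scripts/fetch_deposited.py

It downloads the two GenBank flat files (sequence + feature table) named in
the repository's data/deposited/README.md.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ("ON897689", "ON897690")
EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "deposited"
    out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = EUTILS.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url, timeout=120) as resp:
            text = resp.read().decode()
        if not text.startswith("LOCUS"):
            print(f"unexpected response for {acc}", file=sys.stderr)
            return 1
        dest.write_text(text)
        print(f"wrote {dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
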