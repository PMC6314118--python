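#!/usr/bin/env python
"""Download the nine desaturase family sequences from NCBI (network required).

Writes ``data/accessions/fad_family.fasta``, which enables the opt-in
integration tests in ``tests/test_integration_accessions.py``.  The library
itself never touches the network; this script is the only downloader.

Usage:
    python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

from fadtools.reference_data import FAMILY_ACCESSIONS

OUT = Path(__file__).resolve().parent.parent / "data" / "accessions" / "fad_family.fasta"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="anonymous@example.org",
                        help="contact email passed to NCBI Entrez")
    parser.add_argument("--out", type=Path, default=OUT)
    args = parser.parse_args()

    Entrez.email = args.email
    accessions = [acc for acc, _ in FAMILY_ACCESSIONS.values()]
    with Entrez.efetch(
        db="protein", id=",".join(accessions), rettype="fasta", retmode="text"
    ) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != len(accessions):
        raise SystemExit(
            f"expected {len(accessions)} records, got {len(records)}"
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(args.out), "fasta")
    print(f"wrote {len(records)} sequences -> {args.out}")


if __name__ == "__main__":
    main()
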