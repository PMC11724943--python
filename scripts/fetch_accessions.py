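#!/usr/bin/env python
"""Download the five reference leech mitogenomes from NCBI as GenBank
flat files into data/accessions/ (requires internet access).

Usage:
    python scripts/fetch_accessions.py [--out data/accessions]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = ["NC_023776", "NC_023925", "NC_023928", "NC_023926", "NC_013569"]

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(acc: str) -> str:
    params = urllib.parse.urlencode({
        "db": "nuccore", "id": acc, "rettype": "gb", "retmode": "text",
    })
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        text = resp.read().decode()
    if not text.startswith("LOCUS"):
        raise RuntimeError(f"{acc}: unexpected efetch response")
    return text


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path,
                        default=Path(__file__).resolve().parent.parent
                        / "data" / "accessions")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        print(f"fetching {acc} ...")
        dest.write_text(fetch(acc))
        time.sleep(0.4)  # NCBI rate limit courtesy
    print(f"done; files in {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
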