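#!/usr/bin/env python
"""Download the reference genome accession used by the accession-gated
checks (network required; run once on a connected machine).

Fetches NZ_CP010028.1 as a GenBank flat file with CDS annotation into
data/NZ_CP010028.1.gb via NCBI E-utilities.
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSION = "NZ_CP010028.1"
EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def main() -> int:
    out = Path(__file__).resolve().parent.parent / "data" / f"{ACCESSION}.gb"
    out.parent.mkdir(parents=True, exist_ok=True)
    params = urllib.parse.urlencode({
        "db": "nuccore",
        "id": ACCESSION,
        "rettype": "gbwithparts",
        "retmode": "text",
    })
    url = f"{EUTILS}?{params}"
    print(f"fetching {ACCESSION} ...", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=600) as resp:
        data = resp.read()
    if not data.startswith(b"LOCUS"):
        print("unexpected response (not a GenBank record)", file=sys.stderr)
        return 1
    out.write_bytes(data)
    print(f"wrote {out} ({len(data)/1e6:.1f} MB)", file=sys.stderr)
    return 0


if __name__ == "__main__":
    sys.exit(main())
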