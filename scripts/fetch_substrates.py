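#!/usr/bin/env python
"""One-time download of the pinned substrate sequences and EGF features.

Fetches UniProt FBN1 (P35555), FBN2 (P35556) and LTBP1 (Q14766) — sequences
plus their EGF-like domain feature spans — and writes

    data/uniprot/substrates.fasta
    data/uniprot/egf_features.tsv

which `egfoglc.substrates.load_substrates()` consumes.  The study pinned
sequence versions P35555 SV=4, P35556 SV=3 and Q14766 SV=4; a warning is
printed if the downloaded entry reports a different sequence version.

Requires network access; run once, anywhere, and copy the two files.
"""

from __future__ import annotations

import json
import re
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = {"P35555": 4, "P35556": 3, "Q14766": 4}
BASE = "https://rest.uniprot.org/uniprotkb"


def fetch(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


def main() -> int:
    out_dir = Path(__file__).resolve().parents[1] / "data" / "uniprot"
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_chunks: list[str] = []
    feature_rows: list[tuple[str, int, int, str]] = []
    for accession, pinned_sv in ACCESSIONS.items():
        fasta = fetch(f"{BASE}/{accession}.fasta").decode()
        m = re.search(r"SV=(\d+)", fasta.splitlines()[0])
        if m and int(m.group(1)) != pinned_sv:
            print(
                f"warning: {accession} downloaded with SV={m.group(1)}, "
                f"study pinned SV={pinned_sv}",
                file=sys.stderr,
            )
        fasta_chunks.append(fasta.strip() + "\n")
        entry = json.loads(fetch(f"{BASE}/{accession}.json").decode())
        for feature in entry.get("features", []):
            if feature.get("type") != "Domain":
                continue
            description = feature.get("description", "")
            if "EGF" not in description.upper():
                continue
            start = feature["location"]["start"]["value"]
            end = feature["location"]["end"]["value"]
            feature_rows.append((accession, start, end, description))
    (out_dir / "substrates.fasta").write_text("".join(fasta_chunks))
    with (out_dir / "egf_features.tsv").open("w") as fh:
        fh.write("accession\tstart\tend\ttype\n")
        for accession, start, end, description in feature_rows:
            fh.write(f"{accession}\t{start}\t{end}\t{description}\n")
    print(f"wrote {out_dir / 'substrates.fasta'} and {len(feature_rows)} EGF features")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
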