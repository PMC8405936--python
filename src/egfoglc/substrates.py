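"""Access to the study's pinned substrate sequences (FBN1, FBN2, LTBP1).

The substrates are UniProt P35555 (FBN1, sequence version 4), P35556 (FBN2,
version 3) and Q14766 (LTBP1, version 4).  Their sequences are not shipped
with the package; fetch them once with ``scripts/fetch_substrates.py`` (or
place equivalent files manually) into a data directory containing

* ``substrates.fasta`` — the three sequences, UniProt headers;
* ``egf_features.tsv`` — ``accession<TAB>start<TAB>end<TAB>type`` rows for
  the EGF-like domain features.

:func:`load_substrates` then returns the records plus their EGF repeats,
using annotated features when the table is present and the cysteine-spacing
detector otherwise.
"""

from __future__ import annotations

from pathlib import Path

from .annotation import (
    EGFRepeat,
    ProteinRecord,
    detect_egf_repeats,
    read_domain_features,
    read_fasta,
)

__all__ = ["SUBSTRATE_ACCESSIONS", "default_data_dir", "load_substrates"]

SUBSTRATE_ACCESSIONS = ("P35555", "P35556", "Q14766")


def default_data_dir() -> Path:
    """``data/uniprot`` at the repository root (where the fetch script writes)."""
    return Path(__file__).resolve().parents[2] / "data" / "uniprot"


def load_substrates(
    data_dir: str | Path | None = None,
) -> tuple[list[ProteinRecord], dict[str, list[EGFRepeat]]]:
    """Load the pinned substrates and their EGF repeats from a data directory.

    Raises ``FileNotFoundError`` with fetch instructions when the FASTA is
    absent (the sequences require a one-time download).
    """
    data_dir = Path(data_dir) if data_dir is not None else default_data_dir()
    fasta = data_dir / "substrates.fasta"
    features = data_dir / "egf_features.tsv"
    if not fasta.exists():
        raise FileNotFoundError(
            f"{fasta} not found: the pinned substrate sequences (UniProt "
            f"{', '.join(SUBSTRATE_ACCESSIONS)}) require a one-time download; "
            "run scripts/fetch_substrates.py on a machine with network access"
        )
    records = [r for r in read_fasta(fasta) if r.accession in SUBSTRATE_ACCESSIONS]
    repeats: dict[str, list[EGFRepeat]] = {}
    for record in records:
        if features.exists():
            repeats[record.accession] = read_domain_features(record, features)
        else:
            repeats[record.accession] = detect_egf_repeats(record)
    return records, repeats
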