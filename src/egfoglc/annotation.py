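"""EGF-repeat annotation on protein sequences.

An EGF (epidermal growth factor-like) repeat is a ~40-residue domain with six
conserved cysteines (C1..C6) forming three disulfides.  POGLUT2/3 O-glucosylate
a serine in the loop between C3 and C4, so everything downstream is expressed
in a coordinate frame anchored on those two cysteines: C3 is consensus position
1, the loop residues are positions 2..L+1, and C4 is position L+2 (position 10
for the canonical 8-residue loop, with the acceptor serine at position 7).

Two ways of locating repeats are provided:

* :func:`read_domain_features` — authoritative, from a feature table of
  annotated domain boundaries (e.g. UniProt EGF-like domain features);
* :func:`detect_egf_repeats` — heuristic, a cysteine-spacing scan tuned to
  calcium-binding EGF architecture.

All coordinates are 1-based inclusive (UniProt convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "EGFRepeat",
    "SpacingConfig",
    "read_fasta",
    "read_domain_features",
    "detect_egf_repeats",
    "inter_cysteine_segment",
    "write_repeats_tsv",
    "read_repeats_tsv",
]

#: The 20 standard residues; anything else is rejected on record construction.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class AnnotationError(ValueError):
    """Raised for malformed sequences, feature rows or repeat definitions."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise AnnotationError(
                f"{self.accession}: non-standard residue(s) {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise AnnotationError(
                f"{self.accession}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class EGFRepeat:
    """One EGF repeat with its six conserved cysteines (absolute positions)."""

    accession: str
    ordinal: int
    start: int
    end: int
    c1: int
    c2: int
    c3: int
    c4: int
    c5: int
    c6: int
    source: str = "annotated"  # "annotated" | "detected"

    def __post_init__(self) -> None:
        cys = self.cysteines
        if not (self.start <= cys[0] and cys[-1] <= self.end):
            raise AnnotationError(
                f"{self.accession} EGF{self.ordinal}: cysteines outside [start, end]"
            )
        if any(a >= b for a, b in zip(cys, cys[1:])):
            raise AnnotationError(
                f"{self.accession} EGF{self.ordinal}: cysteines not strictly increasing"
            )
        if self.source not in ("annotated", "detected"):
            raise AnnotationError(f"unknown repeat source {self.source!r}")

    @property
    def cysteines(self) -> tuple[int, int, int, int, int, int]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6)

    def validate_against(self, record: ProteinRecord) -> None:
        """Check every ci really is a cysteine of *record*."""
        for i, pos in enumerate(self.cysteines, start=1):
            if record.residue(pos) != "C":
                raise AnnotationError(
                    f"{self.accession} EGF{self.ordinal}: residue at C{i} "
                    f"position {pos} is {record.residue(pos)!r}, expected 'C'"
                )


@dataclass(frozen=True)
class SpacingConfig:
    """Allowed residue counts between consecutive cysteines for detection.

    Gaps count residues strictly between the two cysteines.  Defaults accept
    canonical calcium-binding EGF architecture (the dominant repeat type in
    fibrillins and LTBPs) and are deliberately permissive at the C3–C4 loop.
    """

    gap12: tuple[int, int] = (3, 14)
    gap23: tuple[int, int] = (3, 12)
    gap34: tuple[int, int] = (1, 16)
    gap45: tuple[int, int] = (1, 3)
    gap56: tuple[int, int] = (4, 23)
    min_total: int = 18
    max_total: int = 60

    def __post_init__(self) -> None:
        for lo, hi in self.gaps:
            if lo < 0 or lo > hi:
                raise AnnotationError(f"invalid gap range ({lo}, {hi})")
        if self.min_total > self.max_total:
            raise AnnotationError("min_total > max_total")

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return (self.gap12, self.gap23, self.gap34, self.gap45, self.gap56)


def _parse_header(header: str) -> tuple[str, str]:
    # UniProt dialect "sp|ACC|NAME desc" or "tr|ACC|NAME"; otherwise bare id.
    fields = header.split()
    token = fields[0]
    rest = " ".join(fields[1:])
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1], parts[2]
    return token, rest or token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; accessions are parsed from UniProt-style
    ``sp|ACC|NAME`` headers or taken as the bare first header token.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, name = _parse_header(entry.description)
        records.append(ProteinRecord(accession, name, str(entry.seq).upper()))
    if not records:
        raise AnnotationError(f"{path}: no FASTA records found")
    return records


def _cysteines_in(record: ProteinRecord, start: int, end: int) -> list[int]:
    return [
        i
        for i in range(start, end + 1)
        if record.sequence[i - 1] == "C"
    ]


def read_domain_features(
    record: ProteinRecord, table_path: str | Path
) -> list[EGFRepeat]:
    """Build repeats from a TSV feature table ``accession<TAB>start<TAB>end<TAB>type``.

    Rows whose type contains "EGF" (case-insensitive) and whose accession
    matches *record* are used; the six cysteines are the first six inside the
    span.  A span with fewer than six cysteines is an error.
    """
    path = Path(table_path)
    rows: list[tuple[int, int, str]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:4]] != ["accession", "start", "end", "type"]:
            raise AnnotationError(
                f"{path}: expected header accession/start/end/type, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected 4 columns")
            acc, start_s, end_s, ftype = parts[0], parts[1], parts[2], parts[3]
            if acc != record.accession or "EGF" not in ftype.upper():
                continue
            rows.append((int(start_s), int(end_s), ftype))

    repeats: list[EGFRepeat] = []
    for ordinal, (start, end, ftype) in enumerate(sorted(rows), start=1):
        if start < 1 or end > len(record) or start > end:
            raise AnnotationError(
                f"{record.accession}: feature span {start}-{end} outside sequence "
                f"of length {len(record)}"
            )
        cys = _cysteines_in(record, start, end)
        if len(cys) < 6:
            raise AnnotationError(
                f"{record.accession}: EGF feature {start}-{end} ({ftype}) has "
                f"{len(cys)} cysteines, need >= 6"
            )
        repeats.append(
            EGFRepeat(record.accession, ordinal, start, end, *cys[:6], source="annotated")
        )
    return repeats


def detect_egf_repeats(
    record: ProteinRecord, config: SpacingConfig | None = None
) -> list[EGFRepeat]:
    """Heuristic six-cysteine scan for EGF repeats.

    Non-overlapping matches are taken greedily N→C; when several cysteine
    assignments share the same C1, the shortest match wins (ties broken on the
    earlier intermediate cysteines).  Returns an empty list when nothing
    matches.
    """
    config = config or SpacingConfig()
    cys = _cysteines_in(record, 1, len(record))
    repeats: list[EGFRepeat] = []
    cursor = 0  # index into cys of the first cysteine still available

    def extend(path: list[int], depth: int) -> list[tuple[int, ...]]:
        if depth == 5:
            total = path[-1] - path[0] + 1
            if config.min_total <= total <= config.max_total:
                return [tuple(path)]
            return []
        lo, hi = config.gaps[depth]
        out: list[tuple[int, ...]] = []
        prev = path[-1]
        for pos in cys:
            if pos <= prev:
                continue
            gap = pos - prev - 1
            if gap > hi:
                break
            if gap >= lo:
                out.extend(extend(path + [pos], depth + 1))
        return out

    while cursor < len(cys):
        c1 = cys[cursor]
        candidates = extend([c1], 0)
        if not candidates:
            cursor += 1
            continue
        # shortest span first, then lexicographically earliest cysteines
        best = min(candidates, key=lambda m: (m[5] - m[0], m))
        repeats.append(
            EGFRepeat(
                record.accession,
                len(repeats) + 1,
                best[0],
                best[5],
                *best,
                source="detected",
            )
        )
        # greedy: skip every cysteine consumed by this match
        cursor = next(i for i, p in enumerate(cys) if p > best[5]) if best[5] < cys[-1] else len(cys)
    return repeats


def inter_cysteine_segment(
    egf: EGFRepeat, record: ProteinRecord
) -> tuple[str, dict[int, int]]:
    """Residues strictly between C3 and C4, plus the consensus numbering map.

    The map sends absolute position C3 to consensus position 1, each loop
    residue to 2..L+1 and C4 to L+2; for the canonical 8-residue loop C4 is
    position 10 and the acceptor serine position 7.
    """
    egf.validate_against(record)
    segment = record.sequence[egf.c3 : egf.c4 - 1]
    numbering = {pos: pos - egf.c3 + 1 for pos in range(egf.c3, egf.c4 + 1)}
    return segment, numbering


_REPEAT_COLUMNS = [
    "accession", "ordinal", "start", "end",
    "c1", "c2", "c3", "c4", "c5", "c6", "source",
]


def write_repeats_tsv(repeats: Iterable[EGFRepeat], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_REPEAT_COLUMNS) + "\n")
        for r in repeats:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.accession, r.ordinal, r.start, r.end,
                        r.c1, r.c2, r.c3, r.c4, r.c5, r.c6, r.source,
                    )
                )
                + "\n"
            )


def read_repeats_tsv(path: str | Path) -> list[EGFRepeat]:
    repeats: list[EGFRepeat] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REPEAT_COLUMNS:
            raise AnnotationError(f"{path}: unexpected repeats header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            acc, ordinal, start, end, c1, c2, c3, c4, c5, c6, source = line.rstrip("\n").split("\t")
            repeats.append(
                EGFRepeat(
                    acc, int(ordinal), int(start), int(end),
                    int(c1), int(c2), int(c3), int(c4), int(c5), int(c6),
                    source=source,
                )
            )
    return repeats
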