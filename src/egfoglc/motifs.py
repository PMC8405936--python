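"""Consensus-pattern matching and O-glucosylation site prediction.

POGLUT2 and POGLUT3 add O-glucose to a serine between cysteines 3 and 4 of an
EGF repeat.  In consensus numbering (C3 = position 1, C4 = position 10 for the
canonical 8-residue loop) the built-in patterns are:

* ``original``            C3-x-N-T-x-G-S-F-x-C4
* ``revised``             C3-x-N-T-x-G-S-(FY)-x-C4   (tyrosine allowed at 8)
* ``broad``               C3-x-x-x-x-x-S-x-x-C4      (general search string)
* ``beta_hydroxylation``  C3-x-(ND)-x-x-x-x-(FY)-x-C4 (Asn/Asp hydroxylation)

Patterns only apply to loops of exactly eight residues; longer or shorter
C3–C4 loops are reported as not evaluable rather than force-fit.  Threonine at
position 7 is not matched by default (it is accepted only at very low
stoichiometry in nature); pass ``allow_thr7=True`` to
:func:`builtin_patterns` for exploratory scans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import EGFRepeat, ProteinRecord, inter_cysteine_segment

__all__ = [
    "ConsensusPattern",
    "PredictedSite",
    "ProteomeScanSummary",
    "builtin_patterns",
    "get_pattern",
    "match_consensus",
    "scan_protein",
    "scan_proteome",
    "apply_point_mutations",
    "parse_mutation",
    "write_sites_tsv",
]

SEGMENT_LENGTH = 8  # canonical inter-C3-C4 loop length for all built-ins


@dataclass(frozen=True)
class ConsensusPattern:
    """A positional residue-set constraint on the inter-C3–C4 loop.

    ``constraints`` maps consensus positions (2..length+1; C3 itself is 1) to
    the residue set allowed there; unconstrained positions accept anything.
    ``modified_position`` is the consensus position of the acceptor residue.
    """

    name: str
    constraints: Mapping[int, frozenset[str]]
    length: int = SEGMENT_LENGTH
    modified_position: int = 7

    def __post_init__(self) -> None:
        for pos in self.constraints:
            if not 2 <= pos <= self.length + 1:
                raise ValueError(
                    f"pattern {self.name}: constrained position {pos} outside "
                    f"2..{self.length + 1}"
                )
        if self.modified_position not in self.constraints:
            raise ValueError(
                f"pattern {self.name}: modified position must be constrained"
            )

    def allowed(self, consensus_position: int) -> frozenset[str] | None:
        return self.constraints.get(consensus_position)


def builtin_patterns(allow_thr7: bool = False) -> dict[str, ConsensusPattern]:
    """The four built-in patterns, keyed by name.

    ``allow_thr7`` additionally accepts threonine at position 7 of the
    glucosylation patterns (exploratory; serine is highly preferred).
    """
    s7 = frozenset("ST") if allow_thr7 else frozenset("S")

    def _c(d: dict[int, str | frozenset[str]]) -> dict[int, frozenset[str]]:
        return {k: (v if isinstance(v, frozenset) else frozenset(v)) for k, v in d.items()}

    return {
        "original": ConsensusPattern(
            "original", _c({3: "N", 4: "T", 6: "G", 7: s7, 8: "F"})
        ),
        "revised": ConsensusPattern(
            "revised", _c({3: "N", 4: "T", 6: "G", 7: s7, 8: "FY"})
        ),
        "broad": ConsensusPattern("broad", _c({7: s7})),
        "beta_hydroxylation": ConsensusPattern(
            "beta_hydroxylation",
            _c({3: "ND", 8: "FY"}),
            modified_position=3,
        ),
    }


def get_pattern(name: str, allow_thr7: bool = False) -> ConsensusPattern:
    patterns = builtin_patterns(allow_thr7=allow_thr7)
    try:
        return patterns[name]
    except KeyError:
        raise ValueError(
            f"unknown pattern {name!r}; choose from {sorted(patterns)}"
        ) from None


def match_consensus(segment: str, pattern: ConsensusPattern) -> int | None:
    """Match a pattern against the exact inter-C3–C4 loop string.

    Returns the acceptor's 1-based position within the segment (consensus
    position − 1), or ``None`` if the segment has the wrong length or any
    constrained position fails.
    """
    if len(segment) != pattern.length:
        return None
    for pos, allowed in pattern.constraints.items():
        if segment[pos - 2] not in allowed:
            return None
    return pattern.modified_position - 1


@dataclass(frozen=True)
class PredictedSite:
    """A predicted acceptor residue, with its EGF and pattern provenance."""

    accession: str
    egf_ordinal: int
    position: int  # absolute 1-based position of the acceptor residue
    residue: str
    pattern: str
    segment: str

    def __post_init__(self) -> None:
        if self.segment and not 1 <= self.position:
            raise ValueError("position must be positive")

    @property
    def site_id(self) -> str:
        return f"{self.accession}:EGF{self.egf_ordinal}:{self.residue}{self.position}"


def scan_protein(
    record: ProteinRecord,
    repeats: Sequence[EGFRepeat],
    pattern: ConsensusPattern,
    return_not_evaluable: bool = False,
) -> list[PredictedSite] | tuple[list[PredictedSite], list[EGFRepeat]]:
    """Predict sites over a protein's EGF repeats, ordered by ordinal.

    Repeats whose C3–C4 loop is not the pattern's required length are "not
    evaluable"; request them with ``return_not_evaluable=True``.
    """
    sites: list[PredictedSite] = []
    not_evaluable: list[EGFRepeat] = []
    for egf in sorted(repeats, key=lambda r: r.ordinal):
        if egf.accession != record.accession:
            raise ValueError(
                f"repeat {egf.accession} EGF{egf.ordinal} does not belong to "
                f"record {record.accession}"
            )
        segment, _ = inter_cysteine_segment(egf, record)
        if len(segment) != pattern.length:
            not_evaluable.append(egf)
            continue
        idx = match_consensus(segment, pattern)
        if idx is None:
            continue
        position = egf.c3 + idx  # segment 1-based index i sits at c3 + i
        sites.append(
            PredictedSite(
                record.accession,
                egf.ordinal,
                position,
                record.residue(position),
                pattern.name,
                segment,
            )
        )
    if return_not_evaluable:
        return sites, not_evaluable
    return sites


@dataclass
class ProteomeScanSummary:
    """Aggregate of a pattern scan over many proteins."""

    pattern: str
    detection_mode: str  # "annotated" | "detected" | "mixed"
    n_proteins: int = 0
    n_proteins_with_sites: int = 0
    n_sites: int = 0
    sites_by_protein: dict[str, list[PredictedSite]] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_proteins_with_sites == sum(
            1 for v in self.sites_by_protein.values() if v
        )
        assert self.n_sites == sum(len(v) for v in self.sites_by_protein.values())


def scan_proteome(
    records: Sequence[ProteinRecord],
    pattern: ConsensusPattern,
    repeats_by_accession: Mapping[str, Sequence[EGFRepeat]] | None = None,
    detector=None,
) -> ProteomeScanSummary:
    """Scan many proteins; repeats come from a mapping or a detector callable.

    When ``repeats_by_accession`` is omitted, ``detector`` (default:
    :func:`egfoglc.annotation.detect_egf_repeats`) is applied per record.
    """
    from .annotation import detect_egf_repeats

    detector = detector or detect_egf_repeats
    modes: set[str] = set()
    summary = ProteomeScanSummary(pattern=pattern.name, detection_mode="detected")
    for record in records:
        if repeats_by_accession is not None:
            repeats = list(repeats_by_accession.get(record.accession, []))
        else:
            repeats = detector(record)
        modes.update(r.source for r in repeats)
        sites = scan_protein(record, repeats, pattern)
        summary.sites_by_protein[record.accession] = sites
        summary.n_proteins += 1
        summary.n_sites += len(sites)
        if sites:
            summary.n_proteins_with_sites += 1
    summary.detection_mode = modes.pop() if len(modes) == 1 else ("mixed" if modes else "detected")
    summary.validate()
    return summary


_MUTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


def parse_mutation(text: str) -> tuple[str, int, str]:
    """Parse point-mutation notation like ``L744T`` into (ref, position, new)."""
    m = _MUTATION_RE.match(text.strip().upper())
    if not m:
        raise ValueError(f"cannot parse mutation {text!r} (expected e.g. 'L744T')")
    return m.group(1), int(m.group(2)), m.group(3)


def apply_point_mutations(
    record: ProteinRecord,
    mutations: Iterable[tuple[str, int, str] | str],
) -> ProteinRecord:
    """Apply point mutations (absolute 1-based positions) to a copy of *record*.

    Each mutation is ``(ref, position, new)`` or a string like ``"L744T"``;
    the reference residue must match the current sequence.
    """
    parsed = [parse_mutation(m) if isinstance(m, str) else m for m in mutations]
    seq = list(record.sequence)
    labels = []
    for ref, pos, new in parsed:
        found = record.residue(pos)
        if found != ref:
            raise ValueError(
                f"{record.accession}: mutation {ref}{pos}{new} — residue at "
                f"{pos} is {found!r}, expected {ref!r}"
            )
        seq[pos - 1] = new
        labels.append(f"{ref}{pos}{new}")
    return ProteinRecord(
        record.accession,
        record.name + "_" + "_".join(labels) if labels else record.name,
        "".join(seq),
    )


def write_sites_tsv(sites: Iterable[PredictedSite], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("accession\tegf_ordinal\tposition\tresidue\tpattern\tsegment\n")
        for s in sites:
            fh.write(
                f"{s.accession}\t{s.egf_ordinal}\t{s.position}\t{s.residue}\t"
                f"{s.pattern}\t{s.segment}\n"
            )
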