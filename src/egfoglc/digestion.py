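"""In-silico protease digestion and glycopeptide mass computation.

Site occupancy is read out at the peptide level: a protease peptide covering
the acceptor serine is searched in four glycoforms — unmodified, +OH
(beta-hydroxylation of the consensus-position-3 Asn/Asp), +hexose (O-glucose
on the acceptor serine), and +hexose+OH.  This module produces the peptides,
picks one reporter peptide per site, and computes theoretical monoisotopic
masses and m/z values for each glycoform and charge state.

Cysteines are carbamidomethylated (fixed, +57.021464 Da) as in standard
iodoacetamide sample preparation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

from .annotation import AMINO_ACIDS, ProteinRecord
from .motifs import PredictedSite

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "DEAMIDATION",
    "AMMONIA_LOSS",
    "HEXOSE",
    "Glycoform",
    "ModificationSpec",
    "PeptideSpan",
    "GlycoPeptide",
    "PROTEASE_RULES",
    "digest",
    "assign_peptides_to_sites",
    "peptide_neutral_mass",
    "glycoform_masses",
    "mz_for_charge",
    "is_unquantifiable",
    "write_glycopeptides_tsv",
]

PROTON_MASS = 1.007276466  # Da, mass of H+
WATER_MASS = 18.0105646    # Da, monoisotopic H2O

#: residue monoisotopic masses (pyteomics reference table)
RESIDUE_MASS: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS
}


@dataclass(frozen=True)
class ModificationSpec:
    """A mass modification: delta, residue targets, fixed/variable placement."""

    name: str
    delta: float  # Da, monoisotopic
    targets: frozenset[str]
    placement: str = "variable"  # "fixed" | "variable"
    terminal: str | None = None  # None | "N-term"

    def __post_init__(self) -> None:
        if self.placement not in ("fixed", "variable"):
            raise ValueError(f"bad placement {self.placement!r}")


CARBAMIDOMETHYL = ModificationSpec(
    "Carbamidomethyl", 57.021464, frozenset("C"), placement="fixed"
)
OXIDATION = ModificationSpec("Oxidation", 15.994915, frozenset("MHND"))
DEAMIDATION = ModificationSpec("Deamidated", 0.984016, frozenset("N"))
AMMONIA_LOSS = ModificationSpec(
    "Ammonia-loss", -17.026549, frozenset("C"), terminal="N-term"
)
HEXOSE = ModificationSpec("Hexose", 162.052824, frozenset("ST"))


class Glycoform(enum.Enum):
    """The four peptide states quantified per site."""

    UNMOD = 0.0
    OH = 15.994915
    HEX = 162.052824
    HEX_OH = 178.047739

    @property
    def delta(self) -> float:
        return self.value

    @property
    def has_hexose(self) -> bool:
        return self in (Glycoform.HEX, Glycoform.HEX_OH)

    @property
    def has_oh(self) -> bool:
        return self in (Glycoform.OH, Glycoform.HEX_OH)


GLYCOFORMS = (Glycoform.UNMOD, Glycoform.OH, Glycoform.HEX, Glycoform.HEX_OH)


@dataclass(frozen=True)
class PeptideSpan:
    """A protease peptide located on its parent protein (1-based inclusive)."""

    accession: str
    start: int
    end: int
    sequence: str
    protease: str
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"{self.accession} {self.start}-{self.end}: span length does "
                f"not match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


#: cleavage C-terminal to these residues, per protease
PROTEASE_RULES: Mapping[str, frozenset[str]] = {
    "trypsin": frozenset("KR"),
    "v8": frozenset("ED"),
    "chymotrypsin": frozenset("YFWLI"),
}


def digest(
    record: ProteinRecord,
    protease: str = "trypsin",
    max_missed: int = 2,
    proline_rule: bool = True,
) -> list[PeptideSpan]:
    """Digest a protein, returning every peptide with 0..max_missed missed cuts.

    Cleavage is C-terminal to the protease's residue set; with the proline
    rule enabled (default) no cut is made before a proline.  Peptides are
    deduplicated by span and ordered by (start, end).
    """
    if protease not in PROTEASE_RULES:
        raise ValueError(
            f"unknown protease {protease!r}; choose from {sorted(PROTEASE_RULES)}"
        )
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    residues = PROTEASE_RULES[protease]
    seq = record.sequence
    # cut points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] in residues and not (proline_rule and seq[i] == "P"):
            cuts.append(i)
    cuts.append(len(seq))

    peptides: list[PeptideSpan] = []
    for a in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            start, end = cuts[a], cuts[b]
            peptides.append(
                PeptideSpan(
                    record.accession,
                    start + 1,
                    end,
                    seq[start:end],
                    protease,
                    missed,
                )
            )
    return peptides


def assign_peptides_to_sites(
    peptides: Sequence[PeptideSpan],
    sites: Sequence[PredictedSite],
    max_length: int = 50,
) -> tuple[dict[str, PeptideSpan], list[PredictedSite]]:
    """Pick one reporter peptide per site.

    Among covering peptides no longer than ``max_length``, the one with the
    fewest missed cleavages wins; ties break to the shortest, then the most
    N-terminal.  Returns (site_id → peptide, uncovered sites).
    """
    chosen: dict[str, PeptideSpan] = {}
    uncovered: list[PredictedSite] = []
    for site in sites:
        candidates = [
            p
            for p in peptides
            if p.accession == site.accession
            and p.covers(site.position)
            and len(p) <= max_length
        ]
        if not candidates:
            uncovered.append(site)
            continue
        chosen[site.site_id] = min(
            candidates, key=lambda p: (p.missed_cleavages, len(p), p.start)
        )
    return chosen, uncovered


def peptide_neutral_mass(
    sequence: str,
    fixed_mods: Iterable[ModificationSpec] = (CARBAMIDOMETHYL,),
    variable_deltas: Iterable[float] = (),
) -> float:
    """Neutral monoisotopic mass: residues + water + fixed mods + extra deltas.

    Fixed modifications are applied once per matching residue (or once at the
    N-terminus for terminally-restricted ones); ``variable_deltas`` are
    already-resolved mass shifts simply added on.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in {sequence!r}")
    total = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    for mod in fixed_mods:
        if mod.placement != "fixed":
            raise ValueError(f"{mod.name} is not a fixed modification")
        if mod.terminal == "N-term":
            if sequence[0] in mod.targets:
                total += mod.delta
        else:
            total += mod.delta * sum(sequence.count(aa) for aa in mod.targets)
    total += sum(variable_deltas)
    return total


def mz_for_charge(neutral_mass: float, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class GlycoPeptide:
    """One glycoform × charge state of a site's reporter peptide."""

    peptide: PeptideSpan
    site_id: str
    site_position: int
    glycoform: Glycoform
    charge: int
    neutral_mass: float
    mz: float

    def __post_init__(self) -> None:
        if not self.peptide.covers(self.site_position):
            raise ValueError(
                f"site position {self.site_position} outside peptide span "
                f"{self.peptide.start}-{self.peptide.end}"
            )
        expected = mz_for_charge(self.neutral_mass, self.charge)
        if abs(expected - self.mz) > 1e-9:
            raise ValueError("m/z inconsistent with neutral mass and charge")


def glycoform_masses(
    peptide: PeptideSpan,
    site: PredictedSite,
    oh_position: int | None = None,
    charges: Sequence[int] = (2, 3, 4),
    fixed_mods: Iterable[ModificationSpec] = (CARBAMIDOMETHYL,),
) -> list[GlycoPeptide]:
    """The four glycoforms of a site's peptide across the given charges.

    ``oh_position`` is the absolute position of the consensus-position-3
    Asn/Asp that carries beta-hydroxylation; when it is None or not covered by
    the peptide, the OH-bearing forms are suppressed (no residue to place the
    hydroxyl on).
    """
    if not peptide.covers(site.position):
        raise ValueError(
            f"site {site.site_id} at {site.position} outside peptide span "
            f"{peptide.start}-{peptide.end}"
        )
    base = peptide_neutral_mass(peptide.sequence, fixed_mods=fixed_mods)
    oh_ok = oh_position is not None and peptide.covers(oh_position)
    out: list[GlycoPeptide] = []
    for form in GLYCOFORMS:
        if form.has_oh and not oh_ok:
            continue
        neutral = base + form.delta
        for z in charges:
            out.append(
                GlycoPeptide(
                    peptide,
                    site.site_id,
                    site.position,
                    form,
                    z,
                    neutral,
                    mz_for_charge(neutral, z),
                )
            )
    return out


def is_unquantifiable(
    glycopeptides: Sequence[GlycoPeptide], scan_min_mz: float = 350.0,
    scan_max_mz: float = 2000.0,
) -> bool:
    """True when the unmodified form falls outside the scan range at every charge.

    Without a detectable unmodified peptide the denominator of the stoichiometry
    is censored, so the site is flagged rather than reported as 100% modified.
    """
    unmod = [g for g in glycopeptides if g.glycoform is Glycoform.UNMOD]
    if not unmod:
        return True
    return all(not scan_min_mz <= g.mz <= scan_max_mz for g in unmod)


def write_glycopeptides_tsv(
    glycopeptides: Iterable[GlycoPeptide], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "site_id\taccession\tpeptide\tstart\tend\tglycoform\tcharge\t"
            "neutral_mass\tmz\n"
        )
        for g in glycopeptides:
            fh.write(
                f"{g.site_id}\t{g.peptide.accession}\t{g.peptide.sequence}\t"
                f"{g.peptide.start}\t{g.peptide.end}\t{g.glycoform.name}\t"
                f"{g.charge}\t{g.neutral_mass:.6f}\t{g.mz:.6f}\n"
            )
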