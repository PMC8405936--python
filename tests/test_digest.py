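"""Protease digestion, peptide assignment, and glycopeptide mass computation."""

import itertools
import re

import pytest
from hypothesis import given, strategies as st
from pyteomics import parser as pyteomics_parser

from egfoglc.annotation import ProteinRecord
from egfoglc.digestion import (
    AMMONIA_LOSS,
    CARBAMIDOMETHYL,
    DEAMIDATION,
    GLYCOFORMS,
    HEXOSE,
    OXIDATION,
    Glycoform,
    PeptideSpan,
    assign_peptides_to_sites,
    digest,
    glycoform_masses,
    is_unquantifiable,
    mz_for_charge,
    peptide_neutral_mass,
)
from egfoglc.motifs import PredictedSite
from egfoglc.simulate import build_manifest, generate_protein_set, site_glycopeptides

import oracles


# ---------------------------------------------------------------------------
# digestion


@pytest.mark.parametrize(
    ("sequence", "protease", "max_missed", "expected"),
    [
        ("ACKDEFRGH", "trypsin", 0, {"ACK", "DEFR", "GH"}),
        ("ACKPDE", "trypsin", 0, {"ACKPDE"}),  # no cut before proline
        (
            "ACKDEFRGH",
            "trypsin",
            1,
            {"ACK", "DEFR", "GH", "ACKDEFR", "DEFRGH"},
        ),
        ("AEGDKH", "v8", 0, {"AE", "GD", "KH"}),
        ("AYGFLW", "chymotrypsin", 0, {"AY", "GF", "L", "W"}),
    ],
)
def test_digest_examples(sequence, protease, max_missed, expected):
    record = ProteinRecord("DIG00001", "digest example", sequence)
    spans = digest(record, protease, max_missed)
    assert {p.sequence for p in spans} == expected


def _brute_force_tryptic(sequence: str, max_missed: int) -> set[str]:
    """Enumerate peptides from all cut points directly (independent oracle)."""
    cuts = [0] + [
        m.end() for m in re.finditer(r"[KR](?!P)", sequence) if m.end() < len(sequence)
    ] + [len(sequence)]
    out = set()
    for i, j in itertools.combinations(range(len(cuts)), 2):
        if j - i - 1 <= max_missed:
            out.add(sequence[cuts[i] : cuts[j]])
    return out


def test_digest_matches_brute_force_enumeration():
    sequence = "MKRACKPDEFRGHKLRPQKSTR"
    record = ProteinRecord("DIG00002", "brute force", sequence)
    for max_missed in (0, 1, 2):
        spans = digest(record, "trypsin", max_missed)
        assert {p.sequence for p in spans} == _brute_force_tryptic(sequence, max_missed)
        assert all(p.missed_cleavages <= max_missed for p in spans)


def test_digest_matches_pyteomics_cleave():
    records, _, _ = generate_protein_set(1, 3, seed=13)
    sequence = records[0].sequence
    mine = {p.sequence for p in digest(records[0], "trypsin", 2)}
    reference = pyteomics_parser.cleave(sequence, r"[KR](?!P)", missed_cleavages=2)
    assert mine == set(reference)


def test_digest_zero_missed_reconstructs_protein():
    records, _, _ = generate_protein_set(3, 4, seed=23)
    for record in records:
        spans = digest(record, "trypsin", 0)
        rebuilt = "".join(p.sequence for p in sorted(spans, key=lambda p: p.start))
        assert rebuilt == record.sequence


def test_digest_unknown_protease():
    record = ProteinRecord("DIG00003", "x", "ACK")
    with pytest.raises(ValueError, match="unknown protease"):
        digest(record, "pepsin", 0)


def test_assign_peptides_tie_rules():
    site = PredictedSite("TIE00001", 1, 10, "S", "broad", "ANTAGSFA")
    make = lambda start, end, missed: PeptideSpan(
        "TIE00001", start, end, "A" * (end - start + 1), "trypsin", missed
    )
    fewest_missed = make(5, 15, 0)
    more_missed = make(5, 20, 1)
    chosen, uncovered = assign_peptides_to_sites([more_missed, fewest_missed], [site])
    assert chosen[site.site_id] == fewest_missed
    assert uncovered == []
    # shortest among equal missed cleavages, then most N-terminal
    shorter = make(8, 12, 0)
    chosen, _ = assign_peptides_to_sites([fewest_missed, shorter], [site])
    assert chosen[site.site_id] == shorter
    # no covering peptide within the length cap -> uncovered
    long_only = make(1, 90, 0)
    chosen, uncovered = assign_peptides_to_sites([long_only], [site], max_length=50)
    assert chosen == {} and uncovered == [site]


# ---------------------------------------------------------------------------
# masses


def test_glycine_mass_matches_composition_oracle():
    assert peptide_neutral_mass("G", fixed_mods=()) == pytest.approx(
        oracles.peptide_mass("G"), abs=1e-6
    )
    assert peptide_neutral_mass("G", fixed_mods=()) == pytest.approx(75.032028, abs=1e-6)


@pytest.mark.parametrize(
    ("spec", "oracle_name"),
    [
        (CARBAMIDOMETHYL, "carbamidomethyl"),
        (OXIDATION, "hydroxylation"),
        (DEAMIDATION, "deamidation"),
        (AMMONIA_LOSS, "ammonia_loss"),
        (HEXOSE, "hexose"),
    ],
)
def test_modification_deltas_match_elemental_compositions(spec, oracle_name):
    assert spec.delta == pytest.approx(oracles.mod_delta(oracle_name), abs=1e-6)


def test_carbamidomethyl_applied_per_cysteine():
    delta = peptide_neutral_mass("C") - peptide_neutral_mass("C", fixed_mods=())
    assert delta == pytest.approx(57.021464, abs=1e-6)
    two = peptide_neutral_mass("CAC") - peptide_neutral_mass("CAC", fixed_mods=())
    assert two == pytest.approx(2 * 57.021464, abs=1e-6)


def test_egf33_peptide_mass_and_glycoform_mz_against_oracle():
    peptide = "CVNTYGSYECK"  # FBN1 EGF33 tryptic peptide, 2 carbamidomethyls
    mass = peptide_neutral_mass(peptide)
    assert mass == pytest.approx(oracles.peptide_mass(peptide, n_carbamidomethyl=2), abs=1e-5)
    span = PeptideSpan("P35555", 1, 11, peptide, "trypsin", 0)
    site = PredictedSite("P35555", 33, 7, "S", "revised", "VNTYGSYE")
    glycopeptides = glycoform_masses(span, site, oh_position=3, charges=(2,))
    assert len(glycopeptides) == 4
    for gp in glycopeptides:
        deltas = {
            Glycoform.UNMOD: (),
            Glycoform.OH: (oracles.mod_delta("hydroxylation"),),
            Glycoform.HEX: (oracles.mod_delta("hexose"),),
            Glycoform.HEX_OH: (
                oracles.mod_delta("hexose"),
                oracles.mod_delta("hydroxylation"),
            ),
        }[gp.glycoform]
        expected = oracles.mz(
            oracles.peptide_mass(peptide, n_carbamidomethyl=2, extra_deltas=deltas), 2
        )
        assert gp.mz == pytest.approx(expected, abs=1e-5)


def test_glycoform_delta_additivity():
    assert Glycoform.HEX.delta - Glycoform.UNMOD.delta == pytest.approx(162.052824)
    assert Glycoform.HEX_OH.delta - Glycoform.OH.delta == pytest.approx(
        Glycoform.HEX.delta - Glycoform.UNMOD.delta, abs=1e-9
    )


def test_oh_forms_suppressed_without_covered_acceptor():
    span = PeptideSpan("OH000001", 1, 8, "ANTAGSFA", "trypsin", 0)
    site = PredictedSite("OH000001", 1, 6, "S", "broad", "ANTAGSFA")
    forms = {g.glycoform for g in glycoform_masses(span, site, oh_position=None)}
    assert forms == {Glycoform.UNMOD, Glycoform.HEX}
    forms = {g.glycoform for g in glycoform_masses(span, site, oh_position=2)}
    assert forms == set(GLYCOFORMS)


@pytest.mark.parametrize(
    ("neutral", "charge", "expected"),
    [(1000.0, 1, 1001.007276), (1000.0, 2, 501.007276)],
)
def test_mz_for_charge(neutral, charge, expected):
    assert mz_for_charge(neutral, charge) == pytest.approx(expected, abs=1e-6)


def test_mz_decreases_with_charge_and_rejects_zero():
    assert mz_for_charge(1500.0, 2) < mz_for_charge(1500.0, 1)
    with pytest.raises(ValueError):
        mz_for_charge(1000.0, 0)


@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=30),
    st.integers(min_value=1, max_value=29),
)
def test_mass_additivity_under_splitting(sequence, cut):
    """mass(AB) = mass(A) + mass(B) − water, for any split point."""
    cut = min(cut, len(sequence) - 1)
    lhs = peptide_neutral_mass(sequence)
    rhs = (
        peptide_neutral_mass(sequence[:cut])
        + peptide_neutral_mass(sequence[cut:])
        - 18.0105646
    )
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_glycoform_mz_values_stay_separated():
    """No two glycoform targets of a site fall within one EIC window (z ≤ 2)."""
    manifest = build_manifest(n_proteins=3, n_egfs_per_protein=4, seed=29, charges=(2,))
    for site in manifest.sites:
        mzs = sorted(g.mz for g in site_glycopeptides(site))
        for a, b in zip(mzs, mzs[1:]):
            assert b - a >= 0.49


def test_unquantifiable_when_unmodified_form_below_scan_range():
    span = PeptideSpan("TINY0001", 1, 2, "GK", "trypsin", 0)
    site = PredictedSite("TINY0001", 1, 1, "S", "broad", "")
    tiny = glycoform_masses(span, site, charges=(1, 2))
    assert is_unquantifiable(tiny)
    big_span = PeptideSpan("TINY0001", 1, 16, "CANTAGSFACAGCAGK", "trypsin", 0)
    big_site = PredictedSite("TINY0001", 1, 7, "S", "broad", "ANTAGSFA")
    assert not is_unquantifiable(glycoform_masses(big_span, big_site, charges=(2,)))
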