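"""Synthetic ground-truth proteins and simulated LC-MS runs.

The generator emulates the study design used to map POGLUT2/3 sites: proteins
built from tandem EGF repeats whose C3–C4 loops carry a chosen mix of
consensus variants, expressed under four conditions (wild type, single
knockouts, double knockout) with replicate LC-MS runs.  Each planted site has
known glycoform fractions on the four-form simplex and a known enzyme
dependency; knockouts transform the fractions deterministically (glucose-
bearing forms collapse onto their glucose-free counterparts, preserving the
hydroxylation marginal).  Runs are rendered as centroided MS1 scans with
Gaussian elution peaks at the theoretical glycopeptide m/z values, optional
ppm jitter and intensity noise — everything the EIC quantifier needs, and
nothing it cannot see (monoisotopic centroids only, no isotope envelopes).

Everything is reproducible from (seed, condition, replicate).
"""

from __future__ import annotations

import base64
import json
import math
import struct
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import EGFRepeat, ProteinRecord, SpacingConfig
from .digestion import (
    GLYCOFORMS,
    Glycoform,
    PeptideSpan,
    digest,
    assign_peptides_to_sites,
    mz_for_charge,
    peptide_neutral_mass,
)
from .motifs import PredictedSite, builtin_patterns, scan_protein
from .quant import CONDITIONS, Scan, SpectraRun

__all__ = [
    "CATEGORIES",
    "DEPENDENCIES",
    "SiteTruth",
    "SyntheticRunManifest",
    "generate_protein_set",
    "build_manifest",
    "knockout_transform",
    "expected_calls",
    "simulate_run",
    "write_manifest",
    "read_manifest",
    "write_fasta",
    "write_mzml",
]

#: consensus-variant categories for planted C3-C4 loops
CATEGORIES = ("original", "revised_only", "broad_only", "non_consensus")
DEPENDENCIES = ("P2", "P3", "both")

_FILLER = "ADEGNQTV"  # loop/linker alphabet: no C/K/R (cuts), no P, no S/F/Y


class ManifestError(ValueError):
    """Invalid synthetic-run manifest."""


#: half-width, in units of the elution sigma, of the per-site integration
#: window used when quantifying simulated runs; symmetric truncation scales
#: every glycoform's AUC identically, so fractions are unaffected
QUANT_WINDOW_SIGMA = 3.0


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_FILLER), size=n))


def _segment_for(rng: np.random.Generator, category: str) -> str:
    """An 8-residue C3–C4 loop matching exactly the requested pattern tier."""
    x = lambda: rng.choice(list(_FILLER))
    if category == "original":
        return f"{x()}NT{x()}GSF{x()}"
    if category == "revised_only":
        return f"{x()}NT{x()}GSY{x()}"
    if category == "broad_only":
        # serine at 7 but position 3 violates N, so only the broad string hits
        return f"{x()}AT{x()}GSF{x()}"
    if category == "non_consensus":
        return f"{x()}NT{x()}GAF{x()}"
    raise ValueError(f"unknown category {category!r}")


def generate_protein_set(
    n_proteins: int,
    n_egfs_per_protein: int,
    consensus_mix: Sequence[float] = (0.4, 0.3, 0.1, 0.2),
    seed: int = 0,
    spacing: SpacingConfig | None = None,
) -> tuple[list[ProteinRecord], dict[str, list[EGFRepeat]], list[tuple[str, int, str]]]:
    """Build synthetic EGF-array proteins with planted consensus variants.

    ``consensus_mix`` gives the proportions of original-matching,
    revised-only (Y at 8), broad-only and non-consensus loops.  Returns the
    records, the planted repeats per accession, and the planted loop list as
    (accession, egf ordinal, category).  Deterministic for a fixed seed; EGF
    scaffolds satisfy the default spacing config, and tryptic cut sites flank
    every C3–C4 loop so each planted site is covered by a short peptide.
    """
    if abs(sum(consensus_mix) - 1.0) > 1e-9 or any(p < 0 for p in consensus_mix):
        raise ValueError("consensus_mix proportions must be >= 0 and sum to 1")
    spacing = spacing or SpacingConfig()
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    repeats_by_acc: dict[str, list[EGFRepeat]] = {}
    planted: list[tuple[str, int, str]] = []
    for p in range(n_proteins):
        accession = f"SYN{p + 1:04d}"
        parts = [_filler(rng, 3)]
        pos = 3
        repeats: list[EGFRepeat] = []
        for ordinal in range(1, n_egfs_per_protein + 1):
            category = str(rng.choice(CATEGORIES, p=list(consensus_mix)))
            segment = _segment_for(rng, category)
            g1 = _filler(rng, int(rng.integers(4, 9)))
            g2 = _filler(rng, int(rng.integers(2, 6))) + "K"  # cut right before C3
            g4 = _filler(rng, 2)
            g5 = _filler(rng, 2) + "K" + _filler(rng, 3)      # cut shortly after C5
            egf_seq = f"C{g1}C{g2}C{segment}C{g4}C{g5}C"
            start = pos + 1
            c1 = start
            c2 = c1 + 1 + len(g1)
            c3 = c2 + 1 + len(g2)
            c4 = c3 + 1 + len(segment)
            c5 = c4 + 1 + len(g4)
            c6 = c5 + 1 + len(g5)
            parts.append(egf_seq)
            pos += len(egf_seq)
            repeats.append(
                EGFRepeat(accession, ordinal, start, pos, c1, c2, c3, c4, c5, c6,
                          source="detected")
            )
            planted.append((accession, ordinal, category))
            linker = _filler(rng, 2) + "R" + _filler(rng, 2)
            parts.append(linker)
            pos += len(linker)
        record = ProteinRecord(accession, f"synthetic EGF array {p + 1}", "".join(parts))
        for r in repeats:
            r.validate_against(record)
        records.append(record)
        repeats_by_acc[accession] = repeats
    return records, repeats_by_acc, planted


@dataclass
class SiteTruth:
    """Ground truth for one planted site in the simulated study."""

    site_id: str
    accession: str
    egf_ordinal: int
    position: int             # absolute acceptor serine position
    oh_position: int | None   # absolute consensus-position-3 N/D, if any
    peptide_start: int
    peptide_end: int
    peptide_sequence: str
    segment: str
    charges: tuple[int, ...]
    fractions: tuple[float, float, float, float]  # UNMOD, OH, HEX, HEX_OH under WT
    dependency: str           # "P2" | "P3" | "both"
    rt_center_min: float
    abundance: float          # total area, intensity x minutes

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9 or any(f < -1e-12 for f in self.fractions):
            raise ManifestError(f"{self.site_id}: fractions not on the simplex")
        if self.dependency not in DEPENDENCIES:
            raise ManifestError(f"{self.site_id}: unknown dependency {self.dependency!r}")


@dataclass
class SyntheticRunManifest:
    """Complete ground-truth description of a simulated study."""

    seed: int
    proteins: list[ProteinRecord]
    repeats: dict[str, list[EGFRepeat]]
    sites: list[SiteTruth]
    replicates: int = 3
    scan_interval_s: float = 1.0
    rt_sigma_min: float = 0.05          # 3-second elution peaks
    noise_fraction: float = 0.05        # Gaussian intensity noise, x peak height
    mz_jitter_ppm: float = 3.0
    scan_mz_range: tuple[float, float] = (350.0, 2000.0)
    run_length_min: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.run_length_min <= 0:
            last = max((s.rt_center_min for s in self.sites), default=1.0)
            self.run_length_min = last + 1.0
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ManifestError("manifest seed must be an integer")
        for site in self.sites:
            SiteTruth.__post_init__(site)
        # collision avoidance: near-identical m/z targets must elute >= 4 sigma apart
        targets: list[tuple[float, float, str]] = []
        for site in self.sites:
            base = peptide_neutral_mass(site.peptide_sequence)
            for form in GLYCOFORMS:
                if form.has_oh and site.oh_position is None:
                    continue
                for z in site.charges:
                    targets.append(
                        (mz_for_charge(base + form.delta, z), site.rt_center_min, site.site_id)
                    )
        # near-m/z sites must be separated by the integration window (3 sigma)
        # plus 4 sigma of clearance, so neither site's window sees the other
        min_sep = (QUANT_WINDOW_SIGMA + 4) * self.rt_sigma_min
        targets.sort()
        for (mz1, rt1, s1), (mz2, rt2, s2) in zip(targets, targets[1:]):
            if s1 == s2:
                continue
            if (mz2 - mz1) / mz1 * 1e6 <= 40.0 and abs(rt2 - rt1) < min_sep:
                raise ManifestError(
                    f"m/z collision between {s1} and {s2} at ~{mz1:.4f} with "
                    f"co-eluting peaks"
                )


def knockout_transform(
    fractions: Sequence[float], dependency: str, condition: str
) -> tuple[float, float, float, float]:
    """Transform WT glycoform fractions (UNMOD, OH, HEX, HEX_OH) to a condition.

    When the condition removes the enzyme(s) the site depends on, the
    glucose-bearing fractions collapse onto the glucose-free forms, preserving
    the hydroxylation marginal: HEX joins UNMOD and HEX_OH joins OH.  "both"
    sites lose glucose only in the double knockout.
    """
    u, o, h, ho = fractions
    if abs(u + o + h + ho - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if dependency not in DEPENDENCIES:
        raise ValueError(f"unknown dependency {dependency!r}")
    lost = condition == "DKO" or (
        condition == "P2KO" and dependency == "P2"
    ) or (condition == "P3KO" and dependency == "P3")
    if lost:
        return (u + h, o + ho, 0.0, 0.0)
    return (u, o, h, ho)


def expected_calls(manifest: SyntheticRunManifest, **classify_kwargs):
    """Truth-derived specificity calls for every planted site.

    Applies the classifier to the exact knockout-transformed glucosylated
    fractions (no measurement noise), so it encodes what a perfect experiment
    would call — including the wild-type floor rule.
    """
    from .specificity import classify_from_fractions

    calls = {}
    for site in manifest.sites:
        gluc = {}
        for condition in ("WT", "P2KO", "P3KO"):
            f = knockout_transform(site.fractions, site.dependency, condition)
            gluc[condition] = f[2] + f[3]
        calls[site.site_id] = classify_from_fractions(
            site.site_id, gluc["WT"], gluc["P2KO"], gluc["P3KO"], **classify_kwargs
        ).call
    return calls


def build_manifest(
    n_proteins: int = 3,
    n_egfs_per_protein: int = 5,
    seed: int = 0,
    consensus_mix: Sequence[float] = (0.4, 0.3, 0.1, 0.2),
    charges: Sequence[int] = (2, 3),
    replicates: int = 3,
    rt_start_min: float = 2.0,
    rt_spacing_min: float = 0.5,
    abundance: float = 1.0e6,
    fractions: Sequence[Sequence[float]] | None = None,
    dependency_probs: Sequence[float] = (0.3, 0.2, 0.5),
    **manifest_kwargs,
) -> SyntheticRunManifest:
    """Generate proteins, predict/assign peptides, and plan a simulated study.

    Planted sites are the loops carrying a serine at consensus position 7
    (found with the broad pattern, so all three serine-bearing categories are
    planned).  WT glycoform fractions are drawn uniformly on the four-form
    simplex unless given explicitly; enzyme dependencies are drawn from
    ``dependency_probs`` over (P2, P3, both).  Retention-time centers are laid
    out on a grid so no two sites with similar m/z co-elute.
    """
    records, repeats_by_acc, _ = generate_protein_set(
        n_proteins, n_egfs_per_protein, consensus_mix, seed
    )
    rng = np.random.default_rng(seed + 1)
    broad = builtin_patterns()["broad"]
    beta = builtin_patterns()["beta_hydroxylation"]
    sites: list[SiteTruth] = []
    idx = 0
    for record in records:
        repeats = repeats_by_acc[record.accession]
        predicted = scan_protein(record, repeats, broad)
        peptides = digest(record, "trypsin", max_missed=2)
        chosen, uncovered = assign_peptides_to_sites(peptides, predicted)
        if uncovered:
            raise ManifestError(
                f"{record.accession}: generator produced uncovered sites "
                f"{[s.site_id for s in uncovered]}"
            )
        beta_sites = {s.egf_ordinal: s for s in scan_protein(record, repeats, beta)}
        for site in predicted:
            peptide = chosen[site.site_id]
            oh_site = beta_sites.get(site.egf_ordinal)
            oh_position = oh_site.position if oh_site and peptide.covers(oh_site.position) else None
            if fractions is not None:
                f = tuple(float(v) for v in fractions[idx])
            else:
                f = tuple(rng.dirichlet(np.ones(4)))
            if oh_position is None:
                # no residue to carry the hydroxyl: fold OH mass fractions away
                f = (f[0] + f[1], 0.0, f[2] + f[3], 0.0)
            dependency = str(rng.choice(DEPENDENCIES, p=list(dependency_probs)))
            sites.append(
                SiteTruth(
                    site.site_id,
                    site.accession,
                    site.egf_ordinal,
                    site.position,
                    oh_position,
                    peptide.start,
                    peptide.end,
                    peptide.sequence,
                    site.segment,
                    tuple(int(z) for z in charges),
                    f,
                    dependency,
                    rt_start_min + idx * rt_spacing_min,
                    float(abundance),
                )
            )
            idx += 1
    return SyntheticRunManifest(
        seed=seed,
        proteins=records,
        repeats=repeats_by_acc,
        sites=sites,
        replicates=replicates,
        **manifest_kwargs,
    )


_COND_INDEX = {c: i for i, c in enumerate(CONDITIONS)}


def simulate_run(
    manifest: SyntheticRunManifest, condition: str, replicate: int
) -> SpectraRun:
    """Render one condition × replicate as centroided MS1 scans.

    Each site × glycoform × charge becomes a Gaussian elution peak whose area
    equals (condition-transformed fraction) × (site abundance) / (number of
    charges), centered at the site's retention time.  Centroids are placed at
    the theoretical monoisotopic m/z with per-scan ppm jitter; Gaussian
    intensity noise scaled to peak height is added.  Peaks whose m/z falls
    outside the scan range are dropped with a warning (emulating peptides the
    instrument cannot see).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        [manifest.seed % (2**31), _COND_INDEX[condition], replicate]
    )
    dt_min = manifest.scan_interval_s / 60.0
    times = np.arange(0.0, manifest.run_length_min, dt_min)
    peaks_mz: list[list[float]] = [[] for _ in times]
    peaks_int: list[list[float]] = [[] for _ in times]
    sigma = manifest.rt_sigma_min
    lo_mz, hi_mz = manifest.scan_mz_range

    for site in manifest.sites:
        cond_fractions = knockout_transform(site.fractions, site.dependency, condition)
        base = peptide_neutral_mass(site.peptide_sequence)
        for form, fraction in zip(GLYCOFORMS, cond_fractions):
            if form.has_oh and site.oh_position is None:
                continue
            if fraction <= 0.0:
                continue
            for z in site.charges:
                mz = mz_for_charge(base + form.delta, z)
                if not lo_mz <= mz <= hi_mz:
                    warnings.warn(
                        f"{site.site_id} {form.name} z={z}: m/z {mz:.2f} outside "
                        f"scan range {manifest.scan_mz_range}; peak dropped",
                        stacklevel=2,
                    )
                    continue
                area = site.abundance * fraction / len(site.charges)
                height = area / (sigma * math.sqrt(2.0 * math.pi))
                a = int(np.searchsorted(times, site.rt_center_min - 5 * sigma))
                b = int(np.searchsorted(times, site.rt_center_min + 5 * sigma, side="right"))
                t = times[a:b]
                intensity = height * np.exp(-((t - site.rt_center_min) ** 2) / (2 * sigma**2))
                if manifest.mz_jitter_ppm > 0:
                    mzs = mz * (1.0 + rng.normal(0.0, manifest.mz_jitter_ppm, t.size) * 1e-6)
                else:
                    mzs = np.full(t.size, mz)
                if manifest.noise_fraction > 0:
                    intensity = intensity + rng.normal(
                        0.0, manifest.noise_fraction * height, t.size
                    )
                    intensity = np.clip(intensity, 0.0, None)
                for k, (m, y) in enumerate(zip(mzs, intensity)):
                    if y > 0:
                        peaks_mz[a + k].append(float(m))
                        peaks_int[a + k].append(float(y))

    scans = []
    for rt, mzs, ints in zip(times, peaks_mz, peaks_int):
        order = np.argsort(mzs) if mzs else []
        scans.append(
            Scan(
                float(rt),
                np.array(mzs, dtype=float)[order] if len(mzs) else np.empty(0),
                np.array(ints, dtype=float)[order] if len(ints) else np.empty(0),
            )
        )
    run_id = f"sim_seed{manifest.seed}_{condition}_rep{replicate}"
    return SpectraRun(run_id, condition, replicate, scans, manifest.scan_mz_range)


def site_glycopeptides(site: SiteTruth):
    """The four-glycoform m/z targets of a planted site (all its charges)."""
    from .digestion import glycoform_masses

    span = PeptideSpan(
        site.accession, site.peptide_start, site.peptide_end,
        site.peptide_sequence, "trypsin", 0,
    )
    predicted = PredictedSite(
        site.accession, site.egf_ordinal, site.position, "S", "broad", site.segment
    )
    return glycoform_masses(
        span, predicted, oh_position=site.oh_position, charges=site.charges
    )


def quantify_manifest(
    manifest: SyntheticRunManifest,
    conditions: Sequence[str] = CONDITIONS,
    ppm: float = 20.0,
):
    """Simulate and quantify every condition × replicate of a manifest.

    Returns a flat list of per-run :class:`~egfoglc.quant.GlycoformQuant`
    results for all planted sites — the full pipeline from ground truth to
    measured stoichiometry.  Each site is integrated over its own elution
    window (the manifest is the peak list), so sites that merely share an m/z
    neighbourhood do not contaminate each other; the deamidation-satellite
    check is disabled because the simulator emits no deamidated species.
    """
    from .quant import quantify_site

    targets = {site.site_id: site_glycopeptides(site) for site in manifest.sites}
    half = QUANT_WINDOW_SIGMA * manifest.rt_sigma_min
    quants = []
    for condition in conditions:
        for replicate in range(1, manifest.replicates + 1):
            run = simulate_run(manifest, condition, replicate)
            for site in manifest.sites:
                window = (site.rt_center_min - half, site.rt_center_min + half)
                quants.append(
                    quantify_site(
                        run,
                        targets[site.site_id],
                        ppm=ppm,
                        rt_window=window,
                        check_deamidation=False,
                    )
                )
    return quants


# ---------------------------------------------------------------------------
# manifest serialization

def _manifest_to_dict(manifest: SyntheticRunManifest) -> dict:
    return {
        "seed": manifest.seed,
        "replicates": manifest.replicates,
        "scan_interval_s": manifest.scan_interval_s,
        "rt_sigma_min": manifest.rt_sigma_min,
        "noise_fraction": manifest.noise_fraction,
        "mz_jitter_ppm": manifest.mz_jitter_ppm,
        "scan_mz_range": list(manifest.scan_mz_range),
        "run_length_min": manifest.run_length_min,
        "proteins": [
            {
                "accession": r.accession,
                "name": r.name,
                "sequence": r.sequence,
                "repeats": [asdict(e) for e in manifest.repeats.get(r.accession, [])],
            }
            for r in manifest.proteins
        ],
        "sites": [asdict(s) for s in manifest.sites],
    }


def write_manifest(manifest: SyntheticRunManifest, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(_manifest_to_dict(manifest), fh, indent=1)


def read_manifest(path: str | Path) -> SyntheticRunManifest:
    with Path(path).open() as fh:
        doc = json.load(fh)
    for key in ("seed", "proteins", "sites"):
        if key not in doc:
            raise ManifestError(f"{path}: manifest missing field {key!r}")
    proteins = []
    repeats: dict[str, list[EGFRepeat]] = {}
    for p in doc["proteins"]:
        proteins.append(ProteinRecord(p["accession"], p["name"], p["sequence"]))
        repeats[p["accession"]] = [EGFRepeat(**e) for e in p.get("repeats", [])]
    sites = []
    for s in doc["sites"]:
        s = dict(s)
        s["charges"] = tuple(s["charges"])
        s["fractions"] = tuple(s["fractions"])
        sites.append(SiteTruth(**s))
    return SyntheticRunManifest(
        seed=doc["seed"],
        proteins=proteins,
        repeats=repeats,
        sites=sites,
        replicates=doc.get("replicates", 3),
        scan_interval_s=doc.get("scan_interval_s", 1.0),
        rt_sigma_min=doc.get("rt_sigma_min", 0.05),
        noise_fraction=doc.get("noise_fraction", 0.05),
        mz_jitter_ppm=doc.get("mz_jitter_ppm", 3.0),
        scan_mz_range=tuple(doc.get("scan_mz_range", (350.0, 2000.0))),
        run_length_min=doc.get("run_length_min", 0.0),
    )


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(f">{r.accession} {r.name}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# minimal mzML writer (MS1 centroid spectra with scan start times)

def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: SpectraRun, path: str | Path) -> None:
    """Write the minimal mzML subset the package's reader consumes.

    64-bit little-endian uncompressed arrays, one MS1 centroid spectrum per
    scan with its start time in minutes.  Round-trips through
    :func:`egfoglc.quant.read_run` (which uses the pyteomics mzML parser).
    """
    from lxml import etree

    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element("mzML", nsmap={None: NS}, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    etree.SubElement(fcontent, "cvParam", cvRef="MS", accession="MS:1000579",
                     name="MS1 spectrum", value="")
    etree.SubElement(fcontent, "cvParam", cvRef="MS", accession="MS:1000127",
                     name="centroid spectrum", value="")
    soft_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(soft_list, "software", id="egfoglc", version="0.1.0")
    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="egfoglc")
    etree.SubElement(pm, "cvParam", cvRef="MS", accession="MS:1000544",
                     name="Conversion to mzML", value="")
    run_el = etree.SubElement(root, "run", id=run.run_id,
                              defaultInstrumentConfigurationRef="IC1")
    spectra = etree.SubElement(
        run_el, "spectrumList", count=str(len(run.scans)), defaultDataProcessingRef="DP1"
    )
    for i, scan in enumerate(run.scans):
        spectrum = etree.SubElement(
            spectra, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(scan.mz.size),
        )
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession="MS:1000511",
                         name="ms level", value="1")
        etree.SubElement(spectrum, "cvParam", cvRef="MS", accession="MS:1000127",
                         name="centroid spectrum", value="")
        scan_list = etree.SubElement(spectrum, "scanList", count="1")
        etree.SubElement(scan_list, "cvParam", cvRef="MS", accession="MS:1000795",
                         name="no combination", value="")
        scan_el = etree.SubElement(scan_list, "scan")
        etree.SubElement(
            scan_el, "cvParam", cvRef="MS", accession="MS:1000016",
            name="scan start time", value=str(scan.rt),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        bdal = etree.SubElement(spectrum, "binaryDataArrayList", count="2")
        for accession, name, values in (
            ("MS:1000514", "m/z array", scan.mz),
            ("MS:1000515", "intensity array", scan.intensity),
        ):
            encoded = _b64(values)
            bda = etree.SubElement(bdal, "binaryDataArray", encodedLength=str(len(encoded)))
            etree.SubElement(bda, "cvParam", cvRef="MS", accession="MS:1000523",
                             name="64-bit float", value="")
            etree.SubElement(bda, "cvParam", cvRef="MS", accession="MS:1000576",
                             name="no compression", value="")
            etree.SubElement(bda, "cvParam", cvRef="MS", accession=accession,
                             name=name, value="")
            etree.SubElement(bda, "binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
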