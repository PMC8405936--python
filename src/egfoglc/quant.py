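"""Extracted-ion-chromatogram quantification of glycoform stoichiometry.

For each site, an EIC is built per glycoform × charge by summing MS1 centroid
intensities within a ppm window around the theoretical m/z.  Areas under the
curve (trapezoidal, no baseline subtraction) are summed across charge states
per glycoform; a glycoform's relative abundance is its AUC divided by the
total AUC of all four glycoforms of the same peptide.  Replicates are
summarised as mean ± sample SD, and only sites with at least two replicate
values are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .digestion import DEAMIDATION, GLYCOFORMS, Glycoform, GlycoPeptide

__all__ = [
    "CONDITIONS",
    "Scan",
    "SpectraRun",
    "ChromatogramTrace",
    "GlycoformQuant",
    "ReplicateSummary",
    "read_run",
    "write_runjson",
    "extract_eic",
    "integrate_auc",
    "quantify_site",
    "aggregate_replicates",
    "write_quant_tsv",
    "write_summary_tsv",
]

CONDITIONS = ("WT", "P2KO", "P3KO", "DKO")


class RunFormatError(ValueError):
    """Malformed or unsupported spectra input."""


@dataclass(frozen=True)
class Scan:
    """One MS1 centroid scan: retention time (minutes) + peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise RunFormatError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            raise RunFormatError("scan m/z array not sorted ascending")


@dataclass
class SpectraRun:
    """An ordered list of MS1 centroid scans from one LC-MS run."""

    run_id: str
    condition: str
    replicate: int
    scans: list[Scan]
    mz_range: tuple[float, float] = (350.0, 2000.0)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise RunFormatError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        rts = self.retention_times
        if rts.size > 1 and np.any(np.diff(rts) <= 0):
            raise RunFormatError(f"{self.run_id}: retention times not strictly increasing")

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    def _flat_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids of the run sorted by m/z, with their scan indices.

        Built lazily and cached; lets an EIC be extracted with one binary
        search over the whole run instead of one per scan.
        """
        cached = self.__dict__.get("_flat_cache")
        if cached is not None and cached[0] == len(self.scans):
            return cached[1]
        mz = np.concatenate([s.mz for s in self.scans]) if self.scans else np.empty(0)
        intensity = (
            np.concatenate([s.intensity for s in self.scans]) if self.scans else np.empty(0)
        )
        scan_idx = np.repeat(
            np.arange(len(self.scans)), [s.mz.size for s in self.scans]
        )
        order = np.argsort(mz, kind="stable")
        flat = (mz[order], intensity[order], scan_idx[order])
        self.__dict__["_flat_cache"] = (len(self.scans), flat)
        return flat


def read_run(
    path: str | Path,
    format: str = "runjson",
    condition: str | None = None,
    replicate: int | None = None,
) -> SpectraRun:
    """Read a run from the simulator's runjson dialect or from centroided mzML.

    mzML carries no condition/replicate metadata; pass them explicitly (they
    default to WT / 1).  MS2 scans are ignored; profile-mode spectra are
    rejected.
    """
    path = Path(path)
    if format == "runjson":
        with path.open() as fh:
            doc = json.load(fh)
        for key in ("run_id", "condition", "replicate", "scans"):
            if key not in doc:
                raise RunFormatError(f"{path}: runjson missing field {key!r}")
        scans = [
            Scan(s["rt"], np.array(s["mz"]), np.array(s["intensity"]))
            for s in doc["scans"]
        ]
        return SpectraRun(
            doc["run_id"],
            condition or doc["condition"],
            replicate if replicate is not None else doc["replicate"],
            scans,
            tuple(doc.get("scan_mz_range", (350.0, 2000.0))),
        )
    if format == "mzml":
        scans = _read_mzml_ms1_scans(path)
        scans.sort(key=lambda s: s.rt)
        return SpectraRun(
            path.stem, condition or "WT", replicate if replicate is not None else 1, scans
        )
    raise RunFormatError(f"unknown run format {format!r}")


def _read_mzml_ms1_scans(path: Path) -> list[Scan]:
    """Minimal mzML reader: MS1 centroid spectra with scan start times.

    Handles 32/64-bit float arrays, uncompressed or zlib-compressed, and
    second- or minute-unit scan start times.  MS2+ spectra are skipped;
    profile-mode spectra raise.
    """
    import base64
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    scans: list[Scan] = []
    for _, spectrum in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        params = {
            cv.get("accession"): cv
            for cv in spectrum.iterfind(f"./{ns}cvParam")
        }
        ms_level = params.get("MS:1000511")
        if ms_level is not None and ms_level.get("value") != "1":
            spectrum.clear()
            continue
        if "MS:1000128" in params:  # profile spectrum
            raise RunFormatError(
                f"{path}: profile-mode mzML is unsupported; centroid first"
            )
        rt = 0.0
        for cv in spectrum.iterfind(f".//{ns}scan/{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName", "").startswith("second"):
                    rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iterfind(f".//{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.iterfind(f"./{ns}cvParam")}
            binary = bda.find(f"./{ns}binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in accessions:  # zlib compression
                raw = zlib.decompress(raw)
            dtype = np.float32 if "MS:1000521" in accessions else np.float64
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accessions:
                arrays["mz"] = values
            elif "MS:1000515" in accessions:
                arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise RunFormatError(f"{path}: spectrum without m/z or intensity array")
        scans.append(Scan(rt, arrays["mz"], arrays["intensity"]))
        spectrum.clear()
    if not scans:
        raise RunFormatError(f"{path}: no MS1 spectra found")
    return scans


def write_runjson(run: SpectraRun, path: str | Path) -> None:
    """Write the simple JSON run dialect (exact round-trip with read_run)."""
    doc = {
        "run_id": run.run_id,
        "condition": run.condition,
        "replicate": run.replicate,
        "scan_mz_range": list(run.mz_range),
        "scans": [
            {"rt": s.rt, "mz": s.mz.tolist(), "intensity": s.intensity.tolist()}
            for s in run.scans
        ],
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh)


@dataclass
class ChromatogramTrace:
    """Per-scan summed intensity within a ppm window around a target m/z."""

    target_mz: float
    ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("trace arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in trace")


def extract_eic(run: SpectraRun, target_mz: float, ppm: float = 20.0) -> ChromatogramTrace:
    """Extract an ion chromatogram with a symmetric ppm tolerance window."""
    if ppm <= 0:
        raise ValueError("ppm tolerance must be > 0")
    half = target_mz * ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    flat_mz, flat_intensity, flat_scan = run._flat_index()
    a = np.searchsorted(flat_mz, lo, side="left")
    b = np.searchsorted(flat_mz, hi, side="right")
    intensities = np.zeros(len(run.scans))
    if b > a:
        np.add.at(intensities, flat_scan[a:b], flat_intensity[a:b])
    return ChromatogramTrace(target_mz, ppm, run.retention_times, intensities)


def integrate_auc(
    trace: ChromatogramTrace, rt_window: tuple[float, float] | None = None
) -> float:
    """Trapezoidal area under the trace, optionally restricted to an RT window.

    Units are intensity × minutes.  No baseline subtraction is performed.
    """
    if rt_window is None:
        rt, y = trace.rt, trace.intensity
    else:
        start, end = rt_window
        if start >= end:
            raise ValueError("empty retention-time window")
        mask = (trace.rt >= start) & (trace.rt <= end)
        if not mask.any():
            raise ValueError("retention-time window contains no scans")
        rt, y = trace.rt[mask], trace.intensity[mask]
    if rt.size < 2:
        return 0.0
    return float(np.trapezoid(y, rt))


@dataclass
class GlycoformQuant:
    """Per-site AUCs and relative abundances of the four glycoforms in one run."""

    site_id: str
    run_id: str
    condition: str
    replicate: int
    auc: dict[Glycoform, float]
    fractions: dict[Glycoform, float] = field(default_factory=dict)
    no_signal: bool = False

    def __post_init__(self) -> None:
        total = sum(self.auc.values())
        if total > 0:
            self.fractions = {g: self.auc.get(g, 0.0) / total for g in GLYCOFORMS}
            self.no_signal = False
        else:
            self.fractions = {g: 0.0 for g in GLYCOFORMS}
            self.no_signal = True

    @property
    def glucosylated_fraction(self) -> float:
        return self.fractions[Glycoform.HEX] + self.fractions[Glycoform.HEX_OH]


def quantify_site(
    run: SpectraRun,
    glycopeptides: Sequence[GlycoPeptide],
    ppm: float = 20.0,
    rt_window: tuple[float, float] | None = None,
    deamidation_warning_fraction: float = 0.10,
    check_deamidation: bool = True,
) -> GlycoformQuant:
    """Quantify the four glycoforms of one site's peptide in one run.

    AUCs are summed over all charge states present in ``glycopeptides``;
    fractions are each glycoform's share of the four-form total.  Glycoforms
    absent from ``glycopeptides`` (e.g. suppressed OH forms) score 0.  A
    warning is emitted when a deamidated satellite of the unmodified form
    carries more than ``deamidation_warning_fraction`` of its AUC.
    """
    if not glycopeptides:
        raise ValueError("no glycopeptides supplied")
    site_ids = {g.site_id for g in glycopeptides}
    if len(site_ids) > 1:
        raise ValueError(f"glycopeptides span several sites: {sorted(site_ids)}")
    site_id = site_ids.pop()

    auc: dict[Glycoform, float] = {g: 0.0 for g in GLYCOFORMS}
    unmod_auc = 0.0
    deamidated_auc = 0.0
    for gp in glycopeptides:
        trace = extract_eic(run, gp.mz, ppm)
        area = integrate_auc(trace, rt_window)
        auc[gp.glycoform] += area
        if check_deamidation and gp.glycoform is Glycoform.UNMOD:
            unmod_auc += area
            satellite = gp.mz + DEAMIDATION.delta / gp.charge
            deamidated_auc += integrate_auc(extract_eic(run, satellite, ppm), rt_window)
    if unmod_auc > 0 and deamidated_auc > deamidation_warning_fraction * unmod_auc:
        warnings.warn(
            f"{site_id} in {run.run_id}: deamidated trace carries "
            f"{deamidated_auc / unmod_auc:.0%} of the unmodified AUC",
            stacklevel=2,
        )
    return GlycoformQuant(
        site_id, run.run_id, run.condition, run.replicate, auc
    )


@dataclass
class ReplicateSummary:
    """Mean ± sample SD of glycoform fractions over replicate runs of one site."""

    site_id: str
    condition: str
    n: int
    mean: dict[Glycoform, float]
    sd: dict[Glycoform, float]

    @property
    def glucosylated_fraction(self) -> float:
        return self.mean[Glycoform.HEX] + self.mean[Glycoform.HEX_OH]


def aggregate_replicates(
    quants: Iterable[GlycoformQuant],
) -> tuple[list[ReplicateSummary], list[GlycoformQuant]]:
    """Group quants by (site, condition) and summarise groups with n >= 2.

    SD uses the n−1 denominator.  Quants in groups with a single replicate are
    returned separately rather than summarised (the at-least-two-replicates
    reporting rule).  No-signal quants are excluded from averaging.
    """
    groups: dict[tuple[str, str], list[GlycoformQuant]] = {}
    for q in quants:
        if q.no_signal:
            continue
        groups.setdefault((q.site_id, q.condition), []).append(q)
    summaries: list[ReplicateSummary] = []
    singletons: list[GlycoformQuant] = []
    for (site_id, condition), members in sorted(groups.items()):
        if len(members) < 2:
            singletons.extend(members)
            continue
        mean = {
            g: float(np.mean([m.fractions[g] for m in members])) for g in GLYCOFORMS
        }
        sd = {
            g: float(np.std([m.fractions[g] for m in members], ddof=1))
            for g in GLYCOFORMS
        }
        summaries.append(ReplicateSummary(site_id, condition, len(members), mean, sd))
    return summaries, singletons


def write_quant_tsv(quants: Iterable[GlycoformQuant], path: str | Path) -> None:
    cols = [f"auc_{g.name.lower()}" for g in GLYCOFORMS] + [
        f"frac_{g.name.lower()}" for g in GLYCOFORMS
    ]
    with Path(path).open("w") as fh:
        fh.write("site_id\trun_id\tcondition\treplicate\t" + "\t".join(cols) + "\tno_signal\n")
        for q in quants:
            values = [f"{q.auc[g]:.6g}" for g in GLYCOFORMS] + [
                f"{q.fractions[g]:.6f}" for g in GLYCOFORMS
            ]
            fh.write(
                f"{q.site_id}\t{q.run_id}\t{q.condition}\t{q.replicate}\t"
                + "\t".join(values)
                + f"\t{int(q.no_signal)}\n"
            )


def write_summary_tsv(summaries: Iterable[ReplicateSummary], path: str | Path) -> None:
    cols = [f"mean_{g.name.lower()}" for g in GLYCOFORMS] + [
        f"sd_{g.name.lower()}" for g in GLYCOFORMS
    ]
    with Path(path).open("w") as fh:
        fh.write("site_id\tcondition\tn\t" + "\t".join(cols) + "\n")
        for s in summaries:
            values = [f"{s.mean[g]:.6f}" for g in GLYCOFORMS] + [
                f"{s.sd[g]:.6f}" for g in GLYCOFORMS
            ]
            fh.write(f"{s.site_id}\t{s.condition}\t{s.n}\t" + "\t".join(values) + "\n")
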