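"""Enzyme-specificity calls from knockout comparisons, and consensus logos.

A site's glucosylated fraction (hexose + hexose/OH forms combined) is compared
between wild-type and single-knockout conditions.  A site is called
POGLUT2-preferred when knocking out POGLUT2 reduces glucosylation by at least
the threshold (default 30%, on the relative scale) while the POGLUT3 knockout
does not — and symmetrically for POGLUT3.  Sites reduced in both knockouts,
sites with near-zero wild-type glucosylation, and sites lacking replicate
support are indeterminate; sites reduced in neither are redundant (either
enzyme suffices).

Position-frequency matrices over the inter-C3–C4 loop (consensus positions
2–9) and per-position information content in bits provide the sequence-logo
summary of modified sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation import AMINO_ACIDS
from .quant import ReplicateSummary

__all__ = [
    "SpecificityCall",
    "PositionFrequencyMatrix",
    "classify_specificity",
    "classify_from_fractions",
    "build_pfm",
    "information_content",
    "write_calls_tsv",
    "write_pfm_tsv",
]

CALLS = ("POGLUT2_preferred", "POGLUT3_preferred", "redundant", "indeterminate")


@dataclass(frozen=True)
class SpecificityCall:
    """Per-site enzyme-preference call from WT vs single-knockout fractions."""

    site_id: str
    wt: float     # glucosylated fraction (HEX + HEX_OH) under each condition
    p2ko: float
    p3ko: float
    call: str
    threshold: float
    reduction_p2ko: float
    reduction_p3ko: float

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def _reduction(wt: float, ko: float, mode: str) -> float:
    if mode == "relative":
        return (wt - ko) / wt if wt > 0 else 0.0
    if mode == "absolute":
        return wt - ko
    raise ValueError(f"unknown reduction mode {mode!r}")


def classify_from_fractions(
    site_id: str,
    wt: float,
    p2ko: float,
    p3ko: float,
    threshold: float = 0.30,
    reduction_mode: str = "relative",
    wt_floor: float = 0.05,
    replicates_ok: bool = True,
) -> SpecificityCall:
    """Call specificity from already-averaged glucosylated fractions.

    ``reduction_mode`` selects the drop scale: "relative" ((WT−KO)/WT, the
    default) or "absolute" (WT−KO percentage points).  Sites with WT
    glucosylation below ``wt_floor`` — or without replicate support — are
    indeterminate.
    """
    r2 = _reduction(wt, p2ko, reduction_mode)
    r3 = _reduction(wt, p3ko, reduction_mode)
    if not replicates_ok or wt < wt_floor:
        call = "indeterminate"
    elif r2 >= threshold and r3 < threshold:
        call = "POGLUT2_preferred"
    elif r3 >= threshold and r2 < threshold:
        call = "POGLUT3_preferred"
    elif r2 >= threshold and r3 >= threshold:
        call = "indeterminate"
    else:
        call = "redundant"
    return SpecificityCall(site_id, wt, p2ko, p3ko, call, threshold, r2, r3)


def classify_specificity(
    wt: ReplicateSummary,
    p2ko: ReplicateSummary,
    p3ko: ReplicateSummary,
    threshold: float = 0.30,
    reduction_mode: str = "relative",
    wt_floor: float = 0.05,
    min_replicates: int = 2,
) -> SpecificityCall:
    """Call specificity from replicate summaries of one site under WT/P2KO/P3KO."""
    site_ids = {wt.site_id, p2ko.site_id, p3ko.site_id}
    if len(site_ids) != 1:
        raise ValueError(f"summaries describe different sites: {sorted(site_ids)}")
    replicates_ok = all(s.n >= min_replicates for s in (wt, p2ko, p3ko))
    return classify_from_fractions(
        wt.site_id,
        wt.glucosylated_fraction,
        p2ko.glucosylated_fraction,
        p3ko.glucosylated_fraction,
        threshold=threshold,
        reduction_mode=reduction_mode,
        wt_floor=wt_floor,
        replicates_ok=replicates_ok,
    )


@dataclass
class PositionFrequencyMatrix:
    """Residue counts/frequencies over consensus positions 2..length+1."""

    positions: tuple[int, ...]
    counts: dict[int, dict[str, int]]
    n: int

    def frequencies(self) -> dict[int, dict[str, float]]:
        return {
            pos: {aa: c / self.n for aa, c in col.items()}
            for pos, col in self.counts.items()
        }


def build_pfm(segments: Sequence[str]) -> PositionFrequencyMatrix:
    """Count residues per consensus position over equal-length loop segments.

    The i-th segment residue (0-based) sits at consensus position i + 2.
    """
    if not segments:
        raise ValueError("no segments supplied")
    length = len(segments[0])
    if any(len(s) != length for s in segments):
        raise ValueError("segments of mixed lengths")
    positions = tuple(range(2, length + 2))
    counts: dict[int, dict[str, int]] = {pos: {} for pos in positions}
    for seg in segments:
        for i, aa in enumerate(seg):
            col = counts[positions[i]]
            col[aa] = col.get(aa, 0) + 1
    return PositionFrequencyMatrix(positions, counts, len(segments))


def information_content(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> dict[int, float]:
    """Per-position information content in bits: R = log2(20) − H [− e_n].

    With the small-sample correction enabled, e_n = 19 / (2·ln2·n) is
    subtracted (the standard logo correction for n observed sequences).
    Letter heights for a logo are frequency × R.
    """
    r_max = math.log2(len(AMINO_ACIDS))
    e_n = 19.0 / (2.0 * math.log(2) * pfm.n) if small_sample_correction else 0.0
    out: dict[int, float] = {}
    for pos, col in pfm.counts.items():
        freqs = np.array([c / pfm.n for c in col.values()], dtype=float)
        entropy = float(-(freqs * np.log2(freqs)).sum()) if freqs.size else 0.0
        out[pos] = max(0.0, r_max - entropy - e_n)
    return out


def letter_heights(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> dict[int, dict[str, float]]:
    """Logo letter heights: per position, frequency × information content."""
    info = information_content(pfm, small_sample_correction)
    freqs = pfm.frequencies()
    return {
        pos: {aa: f * info[pos] for aa, f in freqs[pos].items()}
        for pos in pfm.positions
    }


def write_calls_tsv(calls: Iterable[SpecificityCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "site_id\twt_gluc\tp2ko_gluc\tp3ko_gluc\treduction_p2ko\t"
            "reduction_p3ko\tthreshold\tcall\n"
        )
        for c in calls:
            fh.write(
                f"{c.site_id}\t{c.wt:.4f}\t{c.p2ko:.4f}\t{c.p3ko:.4f}\t"
                f"{c.reduction_p2ko:.4f}\t{c.reduction_p3ko:.4f}\t"
                f"{c.threshold:.2f}\t{c.call}\n"
            )


def write_pfm_tsv(
    pfm: PositionFrequencyMatrix,
    path: str | Path,
    small_sample_correction: bool = False,
) -> None:
    """PFM + information content as TSV, consumable by any plotting layer."""
    residues = sorted({aa for col in pfm.counts.values() for aa in col})
    info = information_content(pfm, small_sample_correction)
    with Path(path).open("w") as fh:
        fh.write("position\t" + "\t".join(residues) + "\tinformation_bits\n")
        freqs = pfm.frequencies()
        for pos in pfm.positions:
            row = [f"{freqs[pos].get(aa, 0.0):.6f}" for aa in residues]
            fh.write(f"{pos}\t" + "\t".join(row) + f"\t{info[pos]:.6f}\n")
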