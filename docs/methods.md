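# Methods

## Coordinate frame and domain model

An EGF repeat is modelled by the absolute 1-based positions of its six
conserved cysteines (C1..C6) inside a parent protein. All site-level
reasoning happens in the loop between C3 and C4, in a consensus numbering
where C3 is position 1, the loop residues are positions 2..L+1 and C4 is
position L+2. For the canonical 8-residue loop C4 is position 10 and the
acceptor serine position 7; the β-hydroxylated Asn/Asp sits at position 3.
Repeats come either from an annotated feature table (authoritative; the first
six cysteines inside each span) or from a heuristic cysteine-spacing scan.
Every repeat records which mode produced it (`annotated` / `detected`).

The spacing scan accepts gaps (residues strictly between cysteines) of
C1–C2 3–14, C2–C3 3–12, C3–C4 1–16, C4–C5 1–3, C5–C6 4–23, total length
18–60. These ranges were chosen to cover calcium-binding EGF architecture,
the dominant repeat type in fibrillins and LTBPs, and are configurable.
Candidate matches are resolved greedily N→C; among assignments sharing a C1
the shortest span wins, with earlier intermediate cysteines breaking
remaining ties. Tandem EGF arrays are non-overlapping in all substrates of
interest, so greedy resolution is safe.

## Consensus patterns

Patterns are positional residue-set constraints on loops of exactly eight
residues:

| name | constraints (consensus position: allowed) | acceptor |
|---|---|---|
| original | 3:N 4:T 6:G 7:S 8:F | S at 7 |
| revised | 3:N 4:T 6:G 7:S 8:{F,Y} | S at 7 |
| broad | 7:S | S at 7 |
| beta_hydroxylation | 3:{N,D} 8:{F,Y} | N/D at 3 |

Loops of any other length are reported as "not evaluable" rather than
force-fit; the numbering and all known sites assume the 8-residue loop.
Threonine at position 7 is excluded by default — it is accepted in nature
only at very low stoichiometry — and can be enabled (`allow_thr7`) for
exploratory scans. By construction the match sets nest:
original ⊆ revised ⊆ broad.

## Glycopeptides and masses

Each predicted site is read out on one reporter peptide: among protease
peptides covering the acceptor (length ≤ 50, a practical ceiling for
detectable precursors in the 350–2000 m/z range at z ≤ 4), the one with the
fewest missed cleavages, then shortest, then most N-terminal. Digestion cuts
C-terminal to K/R (trypsin), E/D (V8/Glu-C) or Y/F/W/L/I (chymotrypsin),
never before proline (the common search-engine default; configurable).

Neutral monoisotopic masses are residue masses (pyteomics reference table)
plus water (18.0105646 Da) plus modification deltas; carbamidomethylation
(+57.021464 Da) is fixed on every cysteine. The four glycoforms per site are
UNMOD, +OH (+15.994915), +HEX (+162.052824, C6H10O5) and +HEX+OH
(+178.047739). m/z = (M + z·1.007276466)/z. β-hydroxylation is placed on the
consensus-position-3 Asn/Asp of the same repeat; when the reporter peptide
does not cover that residue (or the loop has none), the OH-bearing forms are
suppressed for that site rather than floated to an arbitrary residue. Sites
whose unmodified form falls outside the scan range at every charge are
flagged unquantifiable instead of being reported as fully modified — without
a detectable unmodified peptide the stoichiometry denominator is censored.

Oxidation at M/H and deamidation are accepted as identification metadata but
excluded from the four-form stoichiometry; a warning is emitted when a
deamidated satellite (+0.984016/z from the unmodified trace) carries more
than 10% of the unmodified AUC, since that mass-shifts part of the
denominator.

## EIC quantification

An extracted ion chromatogram is the per-scan sum of MS1 centroid
intensities within a symmetric ppm window (default 20 ppm, matching the
precursor tolerance used for identification). Areas are trapezoidal
integrals of intensity over retention time, with no baseline subtraction or
peak deconvolution — deterministic and operator-free. AUCs are summed over
the configured charge states per glycoform; a glycoform's relative abundance
is its AUC over the four-form total. When the total is zero the site is
flagged no-signal instead of emitting fractions. Replicate summaries report
mean and sample SD (n−1); groups with fewer than two replicates are excluded
from summaries and listed separately.

The integration window defaults to the full run for user-supplied data
(callers may pass per-peak windows). When quantifying *simulated* runs the
manifest itself is the peak list, so each site is integrated over ±3σ around
its planted elution apex. Symmetric truncation scales all four glycoforms
identically and therefore cancels exactly in the fractions; it also prevents
two sites that merely share an m/z neighbourhood from contaminating each
other across the whole gradient.

## Specificity calls

Per site, the glucosylated fraction g = frac(HEX) + frac(HEX_OH) is compared
between wild type and each single knockout. The reduction is relative by
default, (g_WT − g_KO)/g_WT: a fixed 30% cutoff on the relative scale treats
a 50%-occupied and a 95%-occupied site identically, which matches how
half-occupied sites are called in practice; the absolute scale
(percentage-point drop) is available via `reduction_mode="absolute"` since
the convention is genuinely ambiguous. A site is POGLUT2-preferred iff the
P2KO reduction ≥ 0.30 and the P3KO reduction < 0.30 (symmetrically for
POGLUT3); reduced in both → indeterminate; reduced in neither → redundant.
Sites with wild-type glucosylation below 0.05 are indeterminate (the ratio
is unstable near zero occupancy), as are sites lacking ≥ 2 replicates in any
condition. β-hydroxylation levels do not enter the call.

Sequence-logo summaries use position-frequency matrices over consensus
positions 2–9 and per-position information content
R = log2(20) − H, optionally minus the small-sample correction
e_n = 19/(2·ln2·n); letter heights are frequency × R. Output is TSV,
consumable by any plotting layer.

## Synthetic ground truth

The generator emulates the knockout study design: proteins of tandem EGF
scaffolds whose loops carry a chosen mix of consensus variants
(original-matching, revised-only with Y at 8, broad-only with the
position-3 constraint broken, and non-consensus with no serine at 7).
Scaffolds satisfy the default spacing ranges, and lysines are placed just
before C3 and just after C5 so a short 0-missed-cleavage tryptic peptide
(~16 residues, z = 2/3 well inside 350–2000 m/z) covers every planted site.

Each site gets wild-type glycoform fractions (drawn uniformly on the 4-form
simplex unless given), an enzyme dependency drawn from (P2, P3, both) with
probabilities (0.3, 0.2, 0.5) — echoing that more sites prefer POGLUT2 than
POGLUT3 while most are redundant — a retention-time apex on a 0.5-minute
grid from 2 minutes, σ = 0.05 min (3 s) elution peaks, and total area 10⁶
intensity·min. Knockouts transform fractions deterministically: when a
condition removes the site's enzyme(s), HEX collapses onto UNMOD and HEX_OH
onto OH, preserving the hydroxylation marginal; the double knockout removes
glucose everywhere.

Runs are rendered as centroided MS1 scans at 1-second intervals: one
Gaussian peak per site × glycoform × charge at the theoretical monoisotopic
m/z, with 3 ppm m/z jitter and Gaussian intensity noise of 5% of peak height
(both per scan; defaults chosen so a multi-condition, replicated study
simulates in seconds). Peaks outside the scan range are dropped with a
warning, emulating precursors the instrument cannot see. Everything is
reproducible from (seed, condition, replicate). A manifest validator rejects
layouts where two sites within 40 ppm in m/z elute closer than 7σ (the 3σ
integration window plus 4σ clearance), so quantification errors measure the
method, not an accidental co-elution.

What the simulator deliberately omits — and what passing tests therefore do
not demonstrate about real data: isotope envelopes (targets and centroids
are monoisotopic only), chromatographic tailing and drift, co-eluting
interferences, deamidated or oxidised satellites, MS2 and
identification-level errors. Recovery numbers on simulated runs bound the
quantifier's numerical behaviour, not instrument reality.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive throughout; conversion happens only in
  file readers.
* Mass invariants: additivity mass(AB) = mass(A) + mass(B) − water to 1e-9
  Da; modification deltas agree with elemental compositions to 1e-6 Da.
* Empty EIC windows score zero; traces with fewer than two in-window scans
  integrate to zero rather than erroring.
* Zero-total-AUC sites carry a no-signal flag with all-zero fractions
  (fractions otherwise sum to 1 within 1e-9).
* Ties in reporter-peptide choice break deterministically (missed cleavages,
  length, start).
* The mzML layer writes a minimal MS1-centroid subset (64-bit little-endian,
  uncompressed, scan start times in minutes) and the reader accepts 32/64-bit
  float arrays, zlib or no compression, and second- or minute-unit times;
  MS2 scans are skipped and profile-mode spectra rejected explicitly.

## Known limitations

* Enzyme-specificity is sequence-agnostic beyond the C3–C4 loop; the package
  makes no attempt to predict which enzyme prefers a site, only to call it
  from knockout data (loop sequence does not determine the preference).
* Real published stoichiometries depend on operator-chosen integration
  bounds in vendor software and are not numerically reproducible from raw
  files by a deterministic pipeline; the package's quantification is
  validated against simulated ground truth instead.
* Whole-proteome scans require the caller to supply sequences; no database
  download is bundled. The checks against the real FBN1/FBN2/LTBP1
  substrates require a one-time fetch (`scripts/fetch_substrates.py`).
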