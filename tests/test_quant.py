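"""EIC extraction, integration, glycoform fractions, replicate aggregation."""

import numpy as np
import pytest
from lxml import etree

from egfoglc.digestion import GLYCOFORMS, Glycoform, PeptideSpan, GlycoPeptide
from egfoglc.quant import (
    ChromatogramTrace,
    GlycoformQuant,
    RunFormatError,
    Scan,
    SpectraRun,
    aggregate_replicates,
    extract_eic,
    integrate_auc,
    quantify_site,
    read_run,
    write_runjson,
)
from egfoglc.simulate import simulate_run, write_mzml


def _run(scans, condition="WT", replicate=1):
    return SpectraRun("testrun", condition, replicate, scans)


def _scan(rt, peaks):
    peaks = sorted(peaks)
    return Scan(rt, np.array([p[0] for p in peaks]), np.array([p[1] for p in peaks]))


# ---------------------------------------------------------------------------
# run IO


def test_runjson_round_trip(tmp_path, noiseless_manifest):
    run = simulate_run(noiseless_manifest, "WT", 1)
    path = tmp_path / "run.json"
    write_runjson(run, path)
    back = read_run(path, "runjson")
    assert back.run_id == run.run_id
    assert back.condition == run.condition
    assert back.replicate == run.replicate
    assert back.mz_range == run.mz_range
    assert len(back.scans) == len(run.scans)
    for a, b in zip(back.scans, run.scans):
        assert a.rt == b.rt
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)


def test_mzml_round_trip(tmp_path):
    scans = [
        _scan(0.5, [(400.123456, 1000.0), (900.5, 5.0)]),
        _scan(1.0, [(400.123456, 2000.0)]),
        _scan(1.5, []),
    ]
    run = _run(scans)
    path = tmp_path / "run.mzML"
    write_mzml(run, path)
    back = read_run(path, "mzml", condition="WT", replicate=1)
    assert len(back.scans) == 3
    for a, b in zip(back.scans, scans):
        assert a.rt == pytest.approx(b.rt)
        np.testing.assert_allclose(a.mz, b.mz)
        np.testing.assert_allclose(a.intensity, b.intensity)


def test_mzml_ms2_scans_ignored(tmp_path):
    scans = [_scan(float(i + 1), [(500.0, 10.0)]) for i in range(8)]
    path = tmp_path / "mixed.mzML"
    write_mzml(_run(scans), path)
    tree = etree.parse(str(path))
    ns = {"m": "http://psi.hupo.org/ms/mzml"}
    spectra = tree.findall(".//m:spectrum", ns)
    for spectrum in spectra[3:]:  # turn 5 of the 8 scans into MS2
        level = spectrum.find("m:cvParam[@accession='MS:1000511']", ns)
        level.set("value", "2")
    tree.write(str(path))
    run = read_run(path, "mzml")
    assert len(run.scans) == 3


def test_mzml_profile_mode_rejected(tmp_path):
    path = tmp_path / "profile.mzML"
    write_mzml(_run([_scan(1.0, [(500.0, 10.0)])]), path)
    tree = etree.parse(str(path))
    ns = {"m": "http://psi.hupo.org/ms/mzml"}
    for cv in tree.findall(".//m:spectrum/m:cvParam[@accession='MS:1000127']", ns):
        cv.set("accession", "MS:1000128")
        cv.set("name", "profile spectrum")
    tree.write(str(path))
    with pytest.raises(RunFormatError, match="profile"):
        read_run(path, "mzml")


def test_unsorted_retention_times_rejected():
    with pytest.raises(RunFormatError, match="strictly increasing"):
        _run([_scan(1.0, []), _scan(0.5, [])])


def test_unknown_condition_rejected():
    with pytest.raises(RunFormatError, match="condition"):
        SpectraRun("x", "MOCK", 1, [])


# ---------------------------------------------------------------------------
# EIC extraction and integration


def test_extract_eic_window_rules():
    target = 800.0
    inside = target * (1 + 10e-6)
    outside = target * (1 + 50e-6)
    run = _run(
        [
            _scan(0.0, [(target, 100.0)]),
            _scan(1.0, [(outside, 50.0)]),
            _scan(2.0, [(target, 30.0), (inside, 20.0)]),
        ]
    )
    trace = extract_eic(run, target, ppm=20.0)
    np.testing.assert_allclose(trace.intensity, [100.0, 0.0, 50.0])
    with pytest.raises(ValueError):
        extract_eic(run, target, ppm=0.0)


def test_integrate_constant_and_zero_traces():
    rt = np.linspace(0.0, 2.0, 121)
    constant = ChromatogramTrace(500.0, 20.0, rt, np.full(rt.size, 100.0))
    assert integrate_auc(constant, (0.0, 2.0)) == pytest.approx(200.0)
    zero = ChromatogramTrace(500.0, 20.0, rt, np.zeros(rt.size))
    assert integrate_auc(zero) == 0.0
    with pytest.raises(ValueError):
        integrate_auc(constant, (1.0, 1.0))


def test_integrate_triangular_peak_matches_closed_form():
    # triangle of height 600 over base 1 minute, sampled at 1 s
    rt = np.arange(0.0, 2.0, 1.0 / 60.0)
    apex = 1.0
    y = np.clip(600.0 * (1 - np.abs(rt - apex) / 0.5), 0.0, None)
    trace = ChromatogramTrace(500.0, 20.0, rt, y)
    area = integrate_auc(trace)
    assert area == pytest.approx(600.0 * 1.0 / 2.0, rel=0.01)


# ---------------------------------------------------------------------------
# glycoform fractions


def _quant(aucs):
    return GlycoformQuant("s", "r", "WT", 1, dict(zip(GLYCOFORMS, aucs)))


@pytest.mark.parametrize(
    ("aucs", "expected"),
    [
        ((100.0, 100.0, 100.0, 100.0), (0.25, 0.25, 0.25, 0.25)),
        ((0.0, 0.0, 200.0, 600.0), (0.0, 0.0, 0.25, 0.75)),
    ],
)
def test_fraction_computation(aucs, expected):
    q = _quant(aucs)
    assert [q.fractions[g] for g in GLYCOFORMS] == pytest.approx(list(expected))
    assert not q.no_signal
    assert sum(q.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_no_signal_flag():
    q = _quant((0.0, 0.0, 0.0, 0.0))
    assert q.no_signal
    assert all(v == 0.0 for v in q.fractions.values())


def _glycopeptide(mz, glycoform=Glycoform.UNMOD, charge=2):
    neutral = (mz - 1.007276466) * charge
    span = PeptideSpan("QP000001", 1, 8, "ANTAGSFA", "trypsin", 0)
    return GlycoPeptide(span, "QP000001:EGF1:S6", 6, glycoform, charge, neutral, mz)


def test_quantify_site_sums_charges_and_linearity():
    mz2, mz3 = 700.0, 467.0
    hex2 = 700.0 + 162.052824 / 2
    scans = [
        _scan(t, [(mz2, 100.0 * k), (mz3, 50.0 * k), (hex2, 300.0 * k)])
        for k, t in [(1.0, 0.0), (2.0, 0.5), (1.0, 1.0)]
    ]
    run = _run(scans)
    gps = [
        _glycopeptide(mz2, Glycoform.UNMOD, 2),
        _glycopeptide(mz3, Glycoform.UNMOD, 3),
        _glycopeptide(hex2, Glycoform.HEX, 2),
    ]
    q = quantify_site(run, gps, check_deamidation=False)
    # UNMOD AUC pools both charge states: (100+50) vs HEX 300 per scan
    assert q.fractions[Glycoform.UNMOD] == pytest.approx(1.0 / 3.0)
    assert q.fractions[Glycoform.HEX] == pytest.approx(2.0 / 3.0)
    # scaling all intensities leaves fractions unchanged and scales AUC
    scaled = _run(
        [Scan(s.rt, s.mz, s.intensity * 7.0) for s in scans]
    )
    q7 = quantify_site(scaled, gps, check_deamidation=False)
    assert q7.auc[Glycoform.HEX] == pytest.approx(7.0 * q.auc[Glycoform.HEX])
    assert q7.fractions[Glycoform.UNMOD] == pytest.approx(q.fractions[Glycoform.UNMOD])


def test_deamidation_satellite_warning():
    mz = 700.0
    satellite = mz + 0.984016 / 2
    run = _run([_scan(t, [(mz, 100.0), (satellite, 30.0)]) for t in (0.0, 0.5, 1.0)])
    with pytest.warns(UserWarning, match="deamidated"):
        quantify_site(run, [_glycopeptide(mz)])
    clean = _run([_scan(t, [(mz, 100.0)]) for t in (0.0, 0.5, 1.0)])
    quantify_site(clean, [_glycopeptide(mz)])  # no warning expected


def test_quantify_site_rejects_mixed_sites():
    a = _glycopeptide(700.0)
    span = PeptideSpan("QP000002", 1, 8, "ANTAGSFA", "trypsin", 0)
    b = GlycoPeptide(span, "QP000002:EGF1:S6", 6, Glycoform.HEX, 2,
                     (800.0 - 1.007276466) * 2, 800.0)
    with pytest.raises(ValueError, match="several sites"):
        quantify_site(_run([_scan(0.0, [])]), [a, b])


# ---------------------------------------------------------------------------
# replicate aggregation


def _quant_with_hex_fraction(f, condition="WT", replicate=1):
    aucs = dict(zip(GLYCOFORMS, (1.0 - f, 0.0, f, 0.0)))
    return GlycoformQuant("site", f"run{replicate}", condition, replicate, aucs)


def test_aggregate_mean_and_sample_sd():
    quants = [_quant_with_hex_fraction(f, replicate=i) for i, f in enumerate((0.4, 0.6), 1)]
    summaries, singletons = aggregate_replicates(quants)
    assert singletons == []
    (summary,) = summaries
    assert summary.n == 2
    assert summary.mean[Glycoform.HEX] == pytest.approx(0.5)
    assert summary.sd[Glycoform.HEX] == pytest.approx(0.1414, abs=1e-4)


def test_single_replicate_excluded():
    summaries, singletons = aggregate_replicates([_quant_with_hex_fraction(0.5)])
    assert summaries == []
    assert len(singletons) == 1


def test_identical_replicates_have_zero_sd():
    quants = [_quant_with_hex_fraction(0.3, replicate=i) for i in (1, 2, 3)]
    (summary,), _ = aggregate_replicates(quants)
    assert summary.n == 3
    assert summary.sd[Glycoform.HEX] == 0.0
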