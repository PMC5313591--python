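"""Vendor-format round trips, metadata parsing and set assembly contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinproc import (AxisSpec, FormatError, PeakSpec, SampleTable,
                      SimulationPlan, assemble_spectrum_set, read_bruker_1r,
                      read_bruker_fid, read_nmrml, read_sample_table,
                      read_varian_fid, simulate_fid, simulate_spectrum_set,
                      subset_by_factor, write_bruker_1r_fixture,
                      write_bruker_fixture, write_nmrml_fixture,
                      write_sample_table, write_varian_fixture)


@pytest.fixture
def fid(axis):
    plan = SimulationPlan(
        n_samples=1, peaks=(PeakSpec(5.0, 1e6, 4.0), PeakSpec(2.0, 5e5, 3.0)),
        seed=3)
    return simulate_fid(plan, axis)


# --- Bruker raw -------------------------------------------------------------

def test_bruker_round_trip_int32(fid, tmp_path):
    write_bruker_fixture(fid, tmp_path / "exp")
    back = read_bruker_fid(tmp_path / "exp")
    assert back.signal.size == fid.signal.size
    # int32 quantization: absolute error bounded by one count
    np.testing.assert_allclose(back.signal.real, fid.signal.real, atol=0.5)
    np.testing.assert_allclose(back.signal.imag, fid.signal.imag, atol=0.5)
    assert back.sw_ppm == pytest.approx(fid.sw_ppm, rel=1e-6)
    assert back.sfo_mhz == pytest.approx(fid.sfo_mhz, rel=1e-8)
    assert back.o1_hz == pytest.approx(fid.o1_hz, abs=1e-3)


def test_bruker_round_trip_float64_exact(fid, tmp_path):
    write_bruker_fixture(fid, tmp_path / "exp", dtypa=2)
    back = read_bruker_fid(tmp_path / "exp")
    np.testing.assert_array_equal(back.signal, fid.signal)


def test_bruker_endianness_invariance(fid, tmp_path):
    write_bruker_fixture(fid, tmp_path / "little", byteorda=0)
    write_bruker_fixture(fid, tmp_path / "big", byteorda=1)
    a = read_bruker_fid(tmp_path / "little")
    b = read_bruker_fid(tmp_path / "big")
    np.testing.assert_array_equal(a.signal, b.signal)


def test_bruker_word_type_invariance(fid, tmp_path):
    write_bruker_fixture(fid, tmp_path / "i4", dtypa=0)
    write_bruker_fixture(fid, tmp_path / "f8", dtypa=2)
    a = read_bruker_fid(tmp_path / "i4")
    b = read_bruker_fid(tmp_path / "f8")
    np.testing.assert_allclose(a.signal.real, b.signal.real, atol=0.5)


def test_bruker_truncated_fid_raises(fid, tmp_path):
    d = write_bruker_fixture(fid, tmp_path / "exp")
    data = (d / "fid").read_bytes()
    (d / "fid").write_bytes(data[: len(data) // 2])
    with pytest.raises(FormatError, match="fid"):
        read_bruker_fid(d)


def test_bruker_missing_acqus_raises(tmp_path):
    (tmp_path / "exp").mkdir()
    with pytest.raises(FormatError, match="acqus"):
        read_bruker_fid(tmp_path / "exp")


def test_bruker_group_delay_parsed(fid, tmp_path):
    fid.group_delay = 67.98
    d = write_bruker_fixture(fid, tmp_path / "exp", dtypa=2)
    assert read_bruker_fid(d).group_delay == pytest.approx(67.98)


# --- Bruker processed (1r) --------------------------------------------------

def test_bruker_1r_nc_proc_scaling(tmp_path):
    spectrum = np.round(np.linspace(-1000, 1000, 256))
    ppm = np.linspace(9.5, -0.5, 256)
    write_bruker_1r_fixture(spectrum, ppm, tmp_path / "p0", nc_proc=0)
    write_bruker_1r_fixture(spectrum * 4, ppm, tmp_path / "p2", nc_proc=2)
    s0, _ = read_bruker_1r(tmp_path / "p0")
    s2, _ = read_bruker_1r(tmp_path / "p2")
    np.testing.assert_array_equal(s0, spectrum)        # verbatim at NC_proc=0
    np.testing.assert_array_equal(s2, spectrum * 4.0)  # stored ints scaled by 2^2


def test_bruker_1r_axis_endpoints(tmp_path):
    # hand-derived from procs semantics: first point at OFFSET, spacing
    # (SW_p/SF)/(SI-1), so last point = OFFSET - sw_ppm
    si, offset, sw_ppm, sf = 512, 9.7, 10.0, 500.0
    ppm = offset - np.arange(si) * sw_ppm / (si - 1)
    write_bruker_1r_fixture(np.zeros(si), ppm, tmp_path / "p", sf_mhz=sf)
    _, axis_back = read_bruker_1r(tmp_path / "p")
    assert axis_back[0] == pytest.approx(offset, abs=1e-6)
    assert axis_back[-1] == pytest.approx(offset - sw_ppm, abs=1e-6)
    np.testing.assert_allclose(axis_back, ppm, atol=1e-6)


def test_bruker_1r_size_mismatch_raises(tmp_path):
    d = write_bruker_1r_fixture(np.zeros(128), np.linspace(5, -5, 128), tmp_path / "p")
    (d / "1r").write_bytes(b"\x00" * 64)
    with pytest.raises(FormatError, match="1r"):
        read_bruker_1r(d)


# --- Varian -----------------------------------------------------------------

def test_varian_round_trip(fid, tmp_path):
    write_varian_fixture(fid, tmp_path / "v")
    back = read_varian_fid(tmp_path / "v")
    # float32 storage: relative quantization ~1e-7 of full scale
    scale = np.abs(fid.signal).max()
    np.testing.assert_allclose(back.signal, fid.signal, atol=2e-7 * scale)
    assert back.sw_ppm == pytest.approx(fid.sw_ppm, rel=1e-6)


def test_vendor_equivalence_bruker_vs_varian(fid, tmp_path):
    write_bruker_fixture(fid, tmp_path / "b", dtypa=2)
    write_varian_fixture(fid, tmp_path / "v")
    b = read_bruker_fid(tmp_path / "b")
    v = read_varian_fid(tmp_path / "v")
    scale = np.abs(fid.signal).max()
    np.testing.assert_allclose(b.signal, v.signal, atol=2e-7 * scale)
    assert b.sw_ppm == pytest.approx(v.sw_ppm, rel=1e-5)
    assert b.o1_hz == pytest.approx(v.o1_hz, abs=1e-2)


def test_varian_missing_np_raises(fid, tmp_path):
    d = write_varian_fixture(fid, tmp_path / "v")
    text = (d / "procpar").read_text()
    kept = []
    lines = iter(text.splitlines())
    for line in lines:
        if line.startswith("np "):
            next(lines); next(lines)  # drop its value and trailer lines
            continue
        kept.append(line)
    (d / "procpar").write_text("\n".join(kept) + "\n")
    with pytest.raises(FormatError, match="np"):
        read_varian_fid(d)


def test_varian_header_np_mismatch_raises(fid, tmp_path):
    d = write_varian_fixture(fid, tmp_path / "v")
    text = (d / "procpar").read_text()
    (d / "procpar").write_text(text.replace(f"1 {2 * fid.signal.size}", "1 64", 1))
    with pytest.raises(FormatError, match="np mismatch"):
        read_varian_fid(d)


# --- nmrML ------------------------------------------------------------------

@pytest.mark.parametrize("compressed", [False, True])
def test_nmrml_round_trip(fid, tmp_path, compressed):
    p = write_nmrml_fixture(fid, tmp_path / "s.nmrml", compressed=compressed)
    back = read_nmrml(p)
    np.testing.assert_array_equal(back.signal, fid.signal)
    assert back.sw_ppm == pytest.approx(fid.sw_ppm, rel=1e-7)
    assert back.sfo_mhz == pytest.approx(fid.sfo_mhz, rel=1e-7)


def test_nmrml_2d_rejected(fid, tmp_path):
    p = write_nmrml_fixture(fid, tmp_path / "s.nmrml")
    text = p.read_text().replace("<acquisition1D>", "<acquisition2D></acquisition2D><acquisition1D>")
    p.write_text(text)
    with pytest.raises(FormatError, match="dimensionality"):
        read_nmrml(p)


# --- sample table and assembly ----------------------------------------------

def test_sample_table_round_trip(tmp_path):
    table = SampleTable(pd.DataFrame({
        "sample_id": ["a", "b", "c"], "genotype": ["wt", "mut", "wt"],
        "day": ["1", "1", "2"]}))
    p = write_sample_table(table, tmp_path / "samples.tsv")
    back = read_sample_table(p)
    assert back == table
    assert back.factor_names == ["genotype", "day"]


def test_sample_table_requires_factor_column():
    with pytest.raises(ValueError, match="factor"):
        SampleTable(pd.DataFrame({"sample_id": ["a"]}))


def test_assemble_orders_rows_by_table(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    spectra = [(sid, sset.intensities[i] * (i + 1), sset.ppm_axis)
               for i, sid in enumerate(sset.sample_table.sample_ids)]
    shuffled = [spectra[2], spectra[0], spectra[1]]
    table = sset.sample_table
    out = assemble_spectrum_set(shuffled, table)
    for i in range(3):
        np.testing.assert_array_equal(out.intensities[i], spectra[i][1])


def test_assemble_point_count_mismatch_names_sample(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    spectra = [(sid, sset.intensities[i], sset.ppm_axis)
               for i, sid in enumerate(sset.sample_table.sample_ids)]
    bad_id = spectra[1][0]
    spectra[1] = (bad_id, sset.intensities[1][:-1], sset.ppm_axis[:-1])
    with pytest.raises(ValueError, match=bad_id):
        assemble_spectrum_set(spectra, sset.sample_table)


def test_assemble_duplicate_sample_raises(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    sid = sset.sample_table.sample_ids[0]
    spectra = [(sid, sset.intensities[0], sset.ppm_axis)] * 2
    with pytest.raises(ValueError, match="duplicate"):
        assemble_spectrum_set(spectra, sset.sample_table)


def test_subset_by_factor(axis, mixture_plan):
    sset = simulate_spectrum_set(mixture_plan, axis)
    sel = subset_by_factor(sset, "group", "A")
    assert list(sel) == [0, 1, 2]
    with pytest.raises(KeyError, match="absent"):
        subset_by_factor(sset, "group", "Z")
    with pytest.raises(KeyError, match="unknown factor"):
        subset_by_factor(sset, "nope", "A")


def test_subset_all_same_level(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    sel = subset_by_factor(sset, "group", "all")
    assert list(sel) == list(range(sset.n_spectra))


# --- property: random-plan fixture round trips ------------------------------

@settings(max_examples=15, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    n_peaks=st.integers(1, 4),
    vendor=st.sampled_from(["bruker", "varian", "nmrml"]),
)
def test_fixture_round_trip_random_plans(tmp_path_factory, seed, n_peaks, vendor):
    rng = np.random.default_rng(seed)
    axis = AxisSpec(sfo_mhz=400.0, sw_ppm=10.0, n_points=256, ppm_max=9.0)
    peaks = tuple(
        PeakSpec(float(rng.uniform(0.0, 8.5)), float(rng.uniform(1e4, 1e6)),
                 float(rng.uniform(1.0, 10.0)),
                 multiplicity=int(rng.integers(1, 4)), j_hz=4.0)
        for _ in range(n_peaks))
    plan = SimulationPlan(n_samples=1, peaks=peaks, seed=seed)
    fid = simulate_fid(plan, axis)
    tmp = tmp_path_factory.mktemp(f"rt{seed % 1000}")
    if vendor == "bruker":
        back = read_bruker_fid(write_bruker_fixture(fid, tmp / "d", dtypa=2))
        np.testing.assert_array_equal(back.signal, fid.signal)
    elif vendor == "varian":
        back = read_varian_fid(write_varian_fixture(fid, tmp / "d"))
        scale = max(np.abs(fid.signal).max(), 1.0)
        np.testing.assert_allclose(back.signal, fid.signal, atol=2e-7 * scale)
    else:
        back = read_nmrml(write_nmrml_fixture(fid, tmp / "d.nmrml"))
        np.testing.assert_array_equal(back.signal, fid.signal)
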