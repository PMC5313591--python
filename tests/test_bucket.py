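"""Bucketing strategies, integration, SNR and filtering contracts."""

import numpy as np
import pandas as pd
import pytest

from spinproc import (AxisSpec, PeakSpec, PpmZone, SimulationPlan, aib_buckets,
                      filter_by_snr, integrate, manual_buckets, normalize,
                      read_bucket_table, simulate_spectrum_set, snr,
                      uniform_buckets, write_bucket_table, zero_zones)
from spinproc.bucket import Bucket, BucketTable


# --- uniform ----------------------------------------------------------------

def test_uniform_bucket_count_exact_tiling(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    table = uniform_buckets(sset, PpmZone(3.0, 4.0), 0.04)
    assert len(table) == 25
    widths = [b.width for b in table]
    assert all(w == pytest.approx(0.04, abs=1e-9) for w in widths)


def test_uniform_drops_short_final_bucket(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    # 1.0 ppm zone, width 0.3: three full buckets, final 0.1 < half width -> dropped
    table = uniform_buckets(sset, PpmZone(3.0, 4.0), 0.3)
    assert len(table) == 3


def test_uniform_keeps_final_bucket_at_half_width(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    # 1.0 ppm zone, width 0.4: two full buckets + final 0.2 = half width -> kept
    table = uniform_buckets(sset, PpmZone(3.0, 4.0), 0.4)
    assert len(table) == 3
    assert table[2].width == pytest.approx(0.2, abs=1e-9)


def test_uniform_clips_against_excluded_zone(axis, mixture_plan):
    sset = zero_zones(simulate_spectrum_set(mixture_plan, axis),
                      [PpmZone(3.45, 3.55)])
    table = uniform_buckets(sset, PpmZone(3.0, 4.0), 0.2)
    for b in table:
        assert not (b.ppm_min < 3.55 and b.ppm_max > 3.45)


def test_uniform_fully_excluded_zone_raises(axis, mixture_plan):
    sset = zero_zones(simulate_spectrum_set(mixture_plan, axis),
                      [PpmZone(2.9, 4.1)])
    with pytest.raises(ValueError, match="excluded"):
        uniform_buckets(sset, PpmZone(3.0, 4.0), 0.2)


# --- adaptive intelligent binning -------------------------------------------

def _aib_oracle(seg, r_exp, v_noise):
    """Independent brute-force recursive maximizer over all split choices."""
    def value(lo, hi):
        window = seg[:, lo:hi + 1]
        imax = window.max(axis=1)
        prod = (imax - seg[:, lo]) * (imax - seg[:, hi])
        return float(np.sum(np.maximum(prod, 0.0) ** r_exp))

    def rec(lo, hi, out):
        parent = value(lo, hi)
        options = [(value(lo, j) + value(j + 1, hi), j)
                   for j in range(lo + 1, hi - 1)]
        if options:
            best_sum, best_j = max(options, key=lambda t: t[0])
            if best_sum > parent and value(lo, best_j) > v_noise \
                    and value(best_j + 1, hi) > v_noise:
                rec(lo, best_j, out)
                rec(best_j + 1, hi, out)
                return
        out.append((lo, hi))

    leaves = []
    rec(0, seg.shape[1] - 1, leaves)
    return [lv for lv in leaves if value(*lv) > v_noise]


@pytest.fixture
def two_singlet_set():
    axis = AxisSpec(sfo_mhz=500.0, sw_ppm=10.0, n_points=2048, ppm_max=9.5)
    plan = SimulationPlan(
        n_samples=3,
        peaks=(PeakSpec(5.2, 80.0, 10.0), PeakSpec(4.8, 60.0, 10.0)),
        seed=6)
    return simulate_spectrum_set(plan, axis)


def test_aib_two_singlets_split_in_valley(two_singlet_set):
    sset = two_singlet_set
    zone = PpmZone(4.5, 5.5)
    table = aib_buckets(sset, zone, resolution_exp=0.5, noise_floor=0.5)
    assert len(table) == 2
    # the inner edges fall in the inter-peak valley (+-2 points of minimum)
    idx = sset.zone_indices(zone)
    seg = sset.intensities[:, idx].mean(axis=0)
    valley_ppm = sset.ppm_axis[idx][np.argmin(
        np.where((sset.ppm_axis[idx] > 4.85) & (sset.ppm_axis[idx] < 5.15),
                 seg, np.inf))]
    spacing = sset.spacing
    inner_edges = [table[0].ppm_min, table[1].ppm_max]
    for edge in inner_edges:
        assert abs(edge - valley_ppm) <= 2 * spacing + 1e-9


def test_aib_single_peak_one_bucket(axis):
    plan = SimulationPlan(n_samples=2, peaks=(PeakSpec(5.0, 50.0, 8.0),), seed=1)
    sset = simulate_spectrum_set(plan, axis)
    table = aib_buckets(sset, PpmZone(4.7, 5.3), noise_floor=0.5)
    assert len(table) == 1
    assert table[0].ppm_min <= 5.0 <= table[0].ppm_max


def test_aib_pure_noise_zone_yields_no_buckets(axis):
    plan = SimulationPlan(n_samples=3, peaks=(), noise_sd=1.0, seed=2)
    sset = simulate_spectrum_set(plan, axis)
    table = aib_buckets(sset, PpmZone(4.0, 5.0), noise_floor=8.0)
    assert len(table) == 0


def test_aib_matches_brute_force_oracle_small_zones():
    """Implementation vs independent recursive maximizer on zones <= 64 points."""
    axis = AxisSpec(sfo_mhz=500.0, sw_ppm=2.0, n_points=64, ppm_max=6.0)
    rng_specs = [
        (PeakSpec(5.6, 40.0, 40.0), PeakSpec(5.1, 70.0, 50.0)),
        (PeakSpec(5.35, 55.0, 60.0),),
        (PeakSpec(5.7, 30.0, 30.0), PeakSpec(5.35, 45.0, 40.0),
         PeakSpec(4.9, 60.0, 35.0)),
    ]
    for peaks in rng_specs:
        plan = SimulationPlan(n_samples=2, peaks=peaks, noise_sd=0.3, seed=13)
        sset = simulate_spectrum_set(plan, axis)
        zone = PpmZone(4.5, 5.9)
        idx = sset.zone_indices(zone)
        seg = sset.intensities[:, idx]
        v_noise = sset.n_spectra * 1.0  # noise_floor = 1.0, R = 0.5
        want = _aib_oracle(seg, 0.5, v_noise)
        table = aib_buckets(sset, zone, resolution_exp=0.5, noise_floor=1.0)
        got = [(int(np.where(idx == sset.index_of(b.ppm_max))[0][0]),
                int(np.where(idx == sset.index_of(b.ppm_min))[0][0]))
               for b in table]
        assert sorted(got) == sorted(want)


def test_aib_zone_too_narrow_raises(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    with pytest.raises(ValueError, match="3 points"):
        aib_buckets(sset, PpmZone(5.0, 5.0 + 1.5 * sset.spacing))


# --- manual -----------------------------------------------------------------

def test_manual_buckets_sorted_descending():
    table = manual_buckets([(1.0, 1.2), (3.0, 3.3), (2.0, 2.1)])
    assert len(table) == 3
    centers = [b.center for b in table]
    assert centers == sorted(centers, reverse=True)


def test_manual_buckets_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        manual_buckets([(1.0, 1.5), (1.4, 2.0)])
    with pytest.raises(ValueError, match="overlap"):
        manual_buckets([(1.0, 1.5), (1.0, 1.5)])


def test_bucket_table_tsv_round_trip(tmp_path):
    table = manual_buckets([(1.0, 1.2), (3.0, 3.3)])
    p = write_bucket_table(table, tmp_path / "buckets.tsv")
    assert read_bucket_table(p) == table


# --- integration -------------------------------------------------------------

def test_integrate_constant_closed_form(axis):
    plan = SimulationPlan(n_samples=1, peaks=(PeakSpec(9.0, 1.0, 2.0),), seed=0)
    sset = simulate_spectrum_set(plan, axis)
    h = 7.0
    sset.intensities[0, :] = h
    table = manual_buckets([(2.0, 2.5)])
    dx = sset.spacing
    got_sum = integrate(sset, table, "sum").iloc[0, 0]
    got_trap = integrate(sset, table, "trapezoid").iloc[0, 0]
    assert got_sum == pytest.approx(h * 0.5, abs=h * dx)
    # trapezoid on the in-bucket grid spans the point support exactly
    idx = sset.zone_indices(PpmZone(2.0, 2.5))
    span = sset.ppm_axis[idx][0] - sset.ppm_axis[idx][-1]
    assert got_trap == pytest.approx(h * span, rel=1e-12)


def test_integrate_lorentzian_analytic_area(fine_axis):
    h, w_hz = 50.0, 5.0
    plan = SimulationPlan(n_samples=1, peaks=(PeakSpec(5.0, h, w_hz),), seed=0)
    sset = simulate_spectrum_set(plan, fine_axis)
    hwhm_ppm = (w_hz / 2) / fine_axis.sfo_mhz
    table = manual_buckets([(5.0 - 60 * hwhm_ppm, 5.0 + 60 * hwhm_ppm)])
    analytic = np.pi * h * hwhm_ppm
    got = integrate(sset, table, "sum").iloc[0, 0]
    assert got == pytest.approx(analytic, rel=0.02)


def test_integrate_additive_under_split(axis, mixture_plan):
    sset = simulate_spectrum_set(mixture_plan, axis)
    parent = manual_buckets([(1.0, 2.0)])
    split_at = sset.ppm_axis[sset.index_of(1.4)] + sset.spacing / 2
    children = manual_buckets([(1.0, split_at), (split_at, 2.0)])
    whole = integrate(sset, parent, "sum").iloc[:, 0]
    parts = integrate(sset, children, "sum").sum(axis=1)
    np.testing.assert_allclose(parts, whole, rtol=1e-12)


def test_integrate_zero_spectrum_zero_row(axis):
    plan = SimulationPlan(n_samples=1, peaks=(), seed=0)
    sset = simulate_spectrum_set(plan, axis)
    table = manual_buckets([(1.0, 2.0), (3.0, 4.0)])
    assert (integrate(sset, table).to_numpy() == 0).all()


def test_integrate_refuses_bucket_in_excluded_zone(axis, mixture_plan):
    sset = zero_zones(simulate_spectrum_set(mixture_plan, axis),
                      [PpmZone(4.6, 5.0)])
    table = manual_buckets([(4.7, 4.9)])
    with pytest.raises(ValueError, match="excluded"):
        integrate(sset, table)


# --- SNR ---------------------------------------------------------------------

def _snr_fixture(axis, n_samples=4, noise_sd=2.0, snr_target=10.0, seed=21):
    """Peak of height snr_target * 2 * noise_sd + noise confined to a noise zone."""
    rng = np.random.default_rng(seed)
    plan = SimulationPlan(n_samples=n_samples, peaks=(PeakSpec(5.0, 1.0, 8.0),), seed=0)
    sset = simulate_spectrum_set(plan, axis)
    sset.intensities *= snr_target * 2 * noise_sd  # apex = target * 2 * sd
    nz = PpmZone(8.5, 9.5)
    nidx = sset.zone_indices(nz)
    sset.intensities[:, nidx] += rng.normal(0, noise_sd, (n_samples, nidx.size))
    return sset, nz, noise_sd


def test_snr_calibrated_peak(axis):
    sset, nz, noise_sd = _snr_fixture(axis)
    table = manual_buckets([(4.8, 5.2)])
    got = snr(sset, table, nz)
    n = sset.zone_indices(nz).size
    tol = 3.0 / np.sqrt(2 * (n - 1))  # sd-estimator sampling error
    assert np.allclose(got.to_numpy(), 10.0, rtol=3 * tol)


def test_snr_noise_only_bucket_small(axis):
    sset, nz, noise_sd = _snr_fixture(axis)
    # bucket over a signal-free region holding only zeros -> SNR 0; bucket
    # inside the noise zone itself -> max-of-m statistics
    nidx = sset.zone_indices(PpmZone(8.6, 8.6 + 63 * sset.spacing))
    table = manual_buckets([(8.6, 8.6 + 63 * sset.spacing)])
    got = snr(sset, table, nz).to_numpy()
    assert np.all(got < 5.0)
    # Monte-Carlo oracle for max-of-m Gaussians over 2 sd
    rng = np.random.default_rng(0)
    m = nidx.size
    mc = np.max(rng.normal(0, 1.0, (2000, m)), axis=1) / 2.0
    assert got.mean() < mc.mean() + 3 * mc.std()


def test_snr_degenerate_noise_zone_raises(axis):
    plan = SimulationPlan(n_samples=1, peaks=(), seed=0)  # all-zero spectra
    sset = simulate_spectrum_set(plan, axis)
    table = manual_buckets([(4.8, 5.2)])
    with pytest.raises(ValueError, match="sd = 0"):
        snr(sset, table, PpmZone(8.5, 9.5))


def test_snr_noise_zone_minimum_points(axis, single_peak_plan):
    sset = simulate_spectrum_set(single_peak_plan, axis)
    table = manual_buckets([(4.8, 5.2)])
    with pytest.raises(ValueError, match="32"):
        snr(sset, table, PpmZone(8.5, 8.5 + 10 * sset.spacing))


# --- filtering and normalization ---------------------------------------------

def _dm_sm(labels, snr_values):
    dm = pd.DataFrame({lab: [1.0, 2.0] for lab in labels},
                      index=pd.Index(["s1", "s2"], name="sample_id"))
    sm = pd.DataFrame(dict(zip(labels, np.asarray(snr_values).T)),
                      index=dm.index)
    return dm, sm


def test_filter_keeps_all_when_snr_high():
    table = manual_buckets([(1.0, 1.1), (2.0, 2.1)])
    dm, sm = _dm_sm(table.labels, [[10.0, 10.0], [10.0, 10.0]])
    out, kept = filter_by_snr(dm, sm, table, threshold=3.0)
    assert list(out.columns) == list(dm.columns)
    assert len(kept) == 2


def test_filter_removes_planted_noise_bucket(axis):
    sset, nz, noise_sd = _snr_fixture(axis)
    table = manual_buckets([(4.8, 5.2), (8.6, 8.6 + 63 * sset.spacing)])
    dm = integrate(sset, table)
    sm = snr(sset, table, nz)
    out, kept = filter_by_snr(dm, sm, table, threshold=3.0, min_fraction=0.5)
    assert len(kept) == 1
    assert kept[0].ppm_min == pytest.approx(4.8)


def test_filter_min_fraction_one_boundary():
    table = manual_buckets([(1.0, 1.1), (2.0, 2.1)])
    dm, sm = _dm_sm(table.labels, [[10.0, 1.0], [1.0, 10.0]])  # one failure each
    out, kept = filter_by_snr(dm, sm, table, threshold=3.0, min_fraction=1.0)
    assert len(kept) == 0
    assert out.shape[1] == 0


def test_filter_monotone_in_threshold(axis):
    sset, nz, _ = _snr_fixture(axis)
    table = manual_buckets([(4.8, 5.2), (8.6, 8.6 + 63 * sset.spacing)])
    dm = integrate(sset, table)
    sm = snr(sset, table, nz)
    counts = [filter_by_snr(dm, sm, table, t, 0.5)[0].shape[1]
              for t in (0.5, 1.0, 3.0, 8.0, 12.0, 50.0)]
    assert counts == sorted(counts, reverse=True)


def test_normalize_constant_sum():
    dm = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 6.0]},
                      index=pd.Index(["s1", "s2"], name="sample_id"))
    assert normalize(dm, "none").equals(dm)
    out = normalize(dm, "constant_sum")
    np.testing.assert_allclose(out.sum(axis=1), 100.0)
    with pytest.raises(ValueError, match="row sums"):
        normalize(pd.DataFrame({"a": [0.0]}, index=["s1"]), "constant_sum")


def test_bucket_labels_stable_and_unique():
    # disjoint buckets whose centers agree to 4 decimals: collision suffix
    table = BucketTable([Bucket(1.100010, 1.100030), Bucket(1.100040, 1.100044)])
    assert len(set(table.labels)) == 2
    assert all(lab.startswith("B1.1000") for lab in table.labels)
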