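"""Unit tests for the gridded-photostimulation map pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortmap.exceptions import (
    ConfigError,
    ExcludedPairError,
    MissingSitesError,
    UndefinedResultError,
)
from cortmap.scracm import (
    CellRecording,
    PairComparison,
    SCRACMMap,
    average_map,
    baseline_sd,
    build_map,
    cohort_slope,
    compare_pathways,
    compute_pixel_response,
    laminar_profile,
    mean_epsc_per_area,
    pair_ratio,
    paired_ttest,
    responsive_area,
    time_to_peak,
    total_input,
    wilcoxon_signed_rank,
)
from cortmap.synthetic import (
    ScracmSimConfig,
    generate_scracm_dataset,
    kernel_peak_time,
)

from conftest import FS, N, ONSET, constant_sweeps, make_sweep


# ---------------------------------------------------------------------------
# baseline_sd


def test_baseline_sd_all_zero():
    assert baseline_sd(constant_sweeps(0.0)) == 0.0


def test_baseline_sd_alternating_unit():
    x = np.zeros(N)
    onset_idx = int(ONSET * FS / 1000)
    x[:onset_idx] = np.where(np.arange(onset_idx) % 2 == 0, -1.0, 1.0)
    assert baseline_sd([make_sweep(x)] * 3) == pytest.approx(1.0)


def test_baseline_sd_averaging_reduces_noise(rng):
    # SD of the 5-rep average of white noise sd=2 is 2/sqrt(5)
    estimates = []
    for _ in range(1000):
        reps = [make_sweep(rng.normal(0, 2, N)) for _ in range(5)]
        estimates.append(baseline_sd(reps))
    assert np.mean(estimates) == pytest.approx(2 / math.sqrt(5), rel=0.02)


def test_baseline_sd_requires_prestim_samples():
    sweep = make_sweep(np.zeros(N), onset=0.0)
    with pytest.raises(ConfigError):
        baseline_sd([sweep] * 3)


# ---------------------------------------------------------------------------
# compute_pixel_response


def test_pixel_response_zero_traces():
    assert compute_pixel_response(constant_sweeps(0.0)) == 0.0


def test_pixel_response_constant_current():
    # -10 pA throughout the window with a zero baseline -> 10 pA magnitude
    assert compute_pixel_response(constant_sweeps(-10.0)) == pytest.approx(10.0)


def test_pixel_response_matches_brute_force(rng):
    reps = [make_sweep(rng.normal(0, 5, N)) for _ in range(4)]
    got = compute_pixel_response(reps)

    # independent oracle: plain Python loops and fsum
    onset_idx = int(round(ONSET * FS / 1000))
    w = int(round(75.0 * FS / 1000))
    avg = [
        math.fsum(rep.samples[i] for rep in reps) / len(reps) for i in range(N)
    ]
    base = math.fsum(avg[:onset_idx]) / onset_idx
    mean = math.fsum(avg[onset_idx : onset_idx + w]) / w
    assert got == pytest.approx(abs(mean - base), abs=1e-9)


def test_pixel_response_synthetic_amplitude():
    # a synthetic kernel scaled for a 23.7 pA windowed mean reads back 23.7
    cfg = ScracmSimConfig(
        n_pairs=1, noise_sd=0.0, pyr_peak_amplitude=23.7, pv_fold=1.0,
        sampling_rate=FS, input_sigma_rows=1.0,
    )
    recs, truth = generate_scracm_dataset(cfg)
    pyr = next(r for r in recs if r.cell_type == "Pyr")
    peak_site = np.unravel_index(
        np.argmax(truth.amplitudes[pyr.cell_id]), (cfg.grid_rows, cfg.grid_cols)
    )
    got = compute_pixel_response(pyr.sweeps[tuple(peak_site)])
    assert got == pytest.approx(23.7, abs=1e-9)


def test_pixel_response_window_exceeds_trace():
    with pytest.raises(ConfigError):
        compute_pixel_response(constant_sweeps(1.0), window_ms=1000.0)


# ---------------------------------------------------------------------------
# build_map


def _noiseless_recording(**kwargs):
    cfg = ScracmSimConfig(n_pairs=1, noise_sd=0.0, sampling_rate=FS, **kwargs)
    recs, truth = generate_scracm_dataset(cfg)
    return cfg, recs, truth


def test_build_map_noiseless_equals_ground_truth():
    _, recs, truth = _noiseless_recording()
    for rec in recs:
        built = build_map(rec)
        np.testing.assert_allclose(built.values, truth.amplitudes[rec.cell_id], atol=1e-9)


def test_build_map_threshold_zero_equals_unthresholded():
    _, recs, _ = _noiseless_recording()
    rec = recs[0]
    strict = build_map(rec, threshold_mult=4.0)
    loose = build_map(rec, threshold_mult=0.0)
    np.testing.assert_allclose(strict.values, loose.values, atol=1e-9)


def test_build_map_missing_sites_listed():
    _, recs, _ = _noiseless_recording()
    rec = recs[0]
    del rec.sweeps[(0, 0)], rec.sweeps[(5, 3)]
    with pytest.raises(MissingSitesError) as err:
        build_map(rec)
    assert (0, 0) in err.value.sites and (5, 3) in err.value.sites


# ---------------------------------------------------------------------------
# map summary statistics


def _map_from(values, **kwargs):
    return SCRACMMap(values=np.asarray(values, dtype=float), **kwargs)


def test_total_input_examples(rng):
    assert total_input(_map_from(np.zeros((16, 8)))) == 0.0
    two = np.zeros((16, 8))
    two[2, 3], two[10, 1] = 5.0, 7.0
    assert total_input(_map_from(two)) == pytest.approx(12.0)
    random_map = rng.uniform(0, 50, (16, 8))
    oracle = math.fsum(float(v) for v in random_map.ravel())
    assert total_input(_map_from(random_map)) == pytest.approx(oracle, abs=1e-9)


def test_mean_epsc_per_area_examples():
    one = np.zeros((16, 8))
    one[4, 4] = 56.25
    assert mean_epsc_per_area(_map_from(one)) == pytest.approx(0.01)
    two = np.zeros((16, 8))
    two[0, 0], two[1, 1] = 10.0, 20.0
    assert mean_epsc_per_area(_map_from(two)) == pytest.approx(15.0 / 5625.0)
    with pytest.raises(UndefinedResultError):
        mean_epsc_per_area(_map_from(np.zeros((16, 8))))


def test_responsive_area(rng):
    assert responsive_area(_map_from(np.zeros((16, 8)))) == 0.0
    four = np.zeros((16, 8))
    four[np.array([0, 3, 7, 9]), np.array([1, 2, 3, 4])] = 1.0
    assert responsive_area(_map_from(four)) == pytest.approx(22500.0)
    mask = (rng.uniform(size=(16, 8)) > 0.5).astype(float)
    assert responsive_area(_map_from(mask)) == pytest.approx(
        sum(1 for v in mask.ravel() if v > 0) * 5625.0
    )


# ---------------------------------------------------------------------------
# time to peak


def test_time_to_peak_closed_form():
    cfg, recs, _ = _noiseless_recording(tau_rise_pyr=3.0, tau_decay=20.0)
    pyr = next(r for r in recs if r.cell_type == "Pyr")
    expected = kernel_peak_time(3.0, 20.0)
    got = time_to_peak(pyr)
    assert abs(got - expected) <= 1000.0 / cfg.sampling_rate  # within one sample


def test_time_to_peak_pv_faster_than_pyr():
    _, recs, _ = _noiseless_recording(tau_rise_pv=1.0, tau_rise_pyr=3.0)
    pv = next(r for r in recs if r.cell_type == "PV")
    pyr = next(r for r in recs if r.cell_type == "Pyr")
    assert time_to_peak(pv) < time_to_peak(pyr)


def test_time_to_peak_impulse():
    onset_idx = int(ONSET * FS / 1000)
    lag = int(10.0 * FS / 1000)
    x = np.zeros(N)
    x[onset_idx + lag] = -50.0
    sweeps = {
        (r, c): [make_sweep(x if (r, c) == (0, 0) else np.zeros(N))] * 3
        for r in range(2)
        for c in range(2)
    }
    rec = CellRecording(
        cell_id="impulse", cell_type="Pyr", layer="L2/3", conductance=5.0,
        sweeps=sweeps, grid_shape=(2, 2),
    )
    assert time_to_peak(rec) == pytest.approx(10.0)


def test_time_to_peak_no_significant_pixels():
    sweeps = {(r, c): constant_sweeps(0.0) for r in range(2) for c in range(2)}
    rec = CellRecording(
        cell_id="silent", cell_type="Pyr", layer="L2/3", conductance=5.0,
        sweeps=sweeps, grid_shape=(2, 2),
    )
    with pytest.raises(UndefinedResultError):
        time_to_peak(rec)


# ---------------------------------------------------------------------------
# pairs


def _pair_recordings(pv_value, pyr_value, pv_g=10.0, pyr_g=5.0):
    def rec(cell_id, cell_type, value, g, lateral):
        x = np.zeros(N)
        onset_idx = int(ONSET * FS / 1000)
        x[onset_idx:] = value
        sweeps = {(r, c): [make_sweep(x)] * 3 for r in range(2) for c in range(2)}
        return CellRecording(
            cell_id=cell_id, cell_type=cell_type, layer="L2/3", conductance=g,
            sweeps=sweeps, grid_shape=(2, 2), soma_xy=(100.0, lateral),
        )

    return rec("pv", "PV", pv_value, pv_g, 0.0), rec("pyr", "Pyr", pyr_value, pyr_g, 50.0)


def test_pair_ratio_examples():
    pv, pyr = _pair_recordings(-10.0, -10.0)
    assert pair_ratio(pv, pyr).fold == pytest.approx(1.0)

    pv, pyr = _pair_recordings(-10.0, -2.5)  # totals 40 vs 10 over 4 sites
    pc = pair_ratio(pv, pyr)
    assert pc.fold == pytest.approx(4.0)
    # conductances 10 and 5 nS halve the normalized fold: (40/10)/(10/5)
    assert pc.fold_norm == pytest.approx(2.0)
    assert pc.distance == pytest.approx(50.0)


def test_pair_ratio_zero_pyr_total_excluded():
    pv, pyr = _pair_recordings(-10.0, 0.0)
    with pytest.raises(ExcludedPairError):
        pair_ratio(pv, pyr)


def test_pair_ratio_distance_limit():
    pv, pyr = _pair_recordings(-10.0, -10.0)
    pyr.soma_xy = (100.0, 200.0)
    with pytest.raises(ConfigError):
        pair_ratio(pv, pyr)


def test_fold_scales_linearly_with_pv_current():
    # noiseless: scaling all PV sweeps by c multiplies the fold by exactly c
    pv, pyr = _pair_recordings(-10.0, -5.0)
    base = pair_ratio(pv, pyr).fold
    for c in (2.0, 3.5):
        pv_scaled, _ = _pair_recordings(-10.0 * c, -5.0)
        assert pair_ratio(pv_scaled, pyr).fold == pytest.approx(c * base)


def _fake_pairs(folds):
    return [
        PairComparison(
            pv_id=f"pv{i}", pyr_id=f"pyr{i}", pv_total=f, pyr_total=1.0,
            fold=f, fold_norm=f, distance=50.0,
        )
        for i, f in enumerate(folds)
    ]


def test_cohort_slope_geometric_mean():
    assert cohort_slope(_fake_pairs([2.0, 8.0])) == pytest.approx(4.0)
    assert cohort_slope(_fake_pairs([1.0, 1.0, 1.0])) == pytest.approx(1.0)
    assert cohort_slope(_fake_pairs([4.0, 9.0])) == pytest.approx(6.0)


def test_cohort_slope_rejects_nonpositive():
    with pytest.raises(ConfigError):
        cohort_slope(_fake_pairs([2.0, 0.0]))


# ---------------------------------------------------------------------------
# laminar profile


BANDS = {"L1": (0.0, 100.0), "L2-4": (100.0, 400.0), "L5": (400.0, 600.0)}


def test_laminar_profile_all_l1():
    values = np.zeros((16, 8))
    values[0, :] = 3.0  # row 0 centre at 37.5 um -> L1 (pia_offset 37.5, pitch 75 -> only row 0)
    prof = laminar_profile(_map_from(values), BANDS)
    assert prof.layer_sums["L1"] == pytest.approx(100.0)
    assert prof.row_totals.sum() == pytest.approx(100.0)


def test_laminar_profile_uniform_map():
    # 16-row uniform map with pia_offset 25, pitch 25: rows 0-2 lie in L1
    prof = laminar_profile(
        _map_from(np.ones((16, 8)), pixel_pitch=25.0, pia_offset=25.0), BANDS
    )
    np.testing.assert_allclose(prof.row_totals, 6.25)
    assert prof.layer_fractions["L1"] == pytest.approx(6.25)


def test_laminar_profile_zero_total():
    with pytest.raises(UndefinedResultError):
        laminar_profile(_map_from(np.zeros((16, 8))), BANDS)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_laminar_profile_rows_sum_to_100(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 30, (16, 8)) * (rng.uniform(size=(16, 8)) > 0.4)
    if values.sum() == 0:
        values[0, 0] = 1.0
    prof = laminar_profile(_map_from(values), BANDS)
    assert prof.row_totals.sum() == pytest.approx(100.0, abs=1e-6)


# ---------------------------------------------------------------------------
# average maps


def test_average_map_single_panel_peak_one(rng):
    m = _map_from(rng.uniform(0, 40, (16, 8)))
    avg = average_map([m], mode="panel_max")
    assert avg.values.max() == pytest.approx(1.0)


def test_average_map_identical_maps(rng):
    m = _map_from(rng.uniform(0, 40, (16, 8)))
    one = average_map([m], mode="cell_total", upsample=1)
    two = average_map([m, _map_from(m.values.copy())], mode="cell_total", upsample=1)
    np.testing.assert_allclose(one.values, two.values, atol=1e-12)


def test_average_map_integral_preserved():
    # smooth unimodal map, the realistic shape after cohort averaging
    r, c = np.meshgrid(np.arange(16), np.arange(8), indexing="ij")
    m = _map_from(40.0 * np.exp(-((r - 7.0) ** 2 / 18.0 + (c - 3.5) ** 2 / 8.0)))
    coarse = average_map([m], mode="cell_total", upsample=1)
    fine = average_map([m], mode="cell_total", upsample=4)

    def integral(sm):
        rows, cols = sm.values.shape
        r = np.arange(rows) * sm.pixel_pitch
        c = np.arange(cols) * sm.pixel_pitch
        return np.trapezoid(np.trapezoid(sm.values, c, axis=1), r)

    assert integral(fine) == pytest.approx(integral(coarse), rel=0.02)


def test_average_map_shape_mismatch():
    with pytest.raises(ConfigError):
        average_map([_map_from(np.ones((16, 8))), _map_from(np.ones((8, 8)))])


def test_average_map_pair_max_peak():
    a = _map_from(np.arange(128, dtype=float).reshape(16, 8))
    b = _map_from(np.arange(128, dtype=float).reshape(16, 8) / 2)
    avg = average_map([a, b], mode="pair_max")
    assert avg.values.max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# pathway statistics


def test_compare_pathways_identical_groups():
    report = compare_pathways({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert report.statistic == pytest.approx(0.0, abs=1e-9)
    assert report.p_value > 0.95


def test_compare_pathways_separated_groups(rng):
    a = rng.lognormal(np.log(12.0), 0.4, 14)
    b = rng.lognormal(np.log(2.0), 0.4, 21)
    report = compare_pathways({"ff": a, "fb": b})
    assert report.p_value < 0.001
    assert report.pairwise[("ff", "fb")][1] < 0.001


def test_compare_pathways_requires_two_groups():
    with pytest.raises(ConfigError):
        compare_pathways({"only": [1.0, 2.0]})


def test_wilcoxon_identical_pairs():
    x = [3.0, 4.0, 5.0, 6.0, 7.0]
    stat, p = wilcoxon_signed_rank(x, x)
    assert p > 0.95


def test_paired_ttest_detects_shift(rng):
    x = rng.normal(5.0, 0.5, 14)
    y = x + 2.0 + rng.normal(0, 0.1, 14)
    stat, p = paired_ttest(x, y)
    assert p < 1e-6 and stat < 0
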