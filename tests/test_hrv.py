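"""HRV metrics vs independent naive oracles, plus slicing and invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_freq_domain, naive_stress_index, naive_time_domain

from hypnoscore.hrv import (
    FEATURE_COLUMNS,
    RRWindow,
    artifact_fraction,
    freq_domain,
    hrv_per_epoch,
    is_excluded,
    slice_rr,
    stress_index,
    time_domain,
    window_features,
)
from hypnoscore.records import RRSeries

from conftest import make_window


# ------------------------------------------------------------------- slicing


def test_uniform_grid_window_holds_expected_intervals():
    bt = np.arange(1.0, 61.0)  # beats every 1 s
    rr = RRSeries(bt, np.full(60, 1000.0))
    w = slice_rr(rr, t_end=30.0, window_len=30.0)
    assert len(w) == 30
    assert w.beat_times[0] == 1.0 and w.beat_times[-1] == 30.0


def test_long_window_on_short_record_truncates_with_flag():
    bt = np.arange(1.0, 31.0)
    rr = RRSeries(bt, np.full(30, 1000.0))
    w = slice_rr(rr, t_end=30.0, window_len=300.0)
    assert len(w) == 30 and w.truncated


def test_window_before_record_is_empty():
    rr = RRSeries(np.array([100.0, 101.0]), np.array([1000.0, 1000.0]))
    assert len(slice_rr(rr, t_end=30.0, window_len=30.0)) == 0


def test_irregular_series_membership_matches_exhaustive_scan():
    bt = np.array([0.4, 1.1, 2.9, 3.0, 3.05, 7.2, 9.9])
    rr_ms = np.array([400.0, 700.0, 1800.0, 100.0, 50.0, 4150.0, 2700.0])
    rr = RRSeries(bt, rr_ms)
    for t_end in (3.0, 5.0, 9.9, 10.5):
        for L in (2.0, 3.0, 8.0):
            w = slice_rr(rr, t_end, L)
            expected = [i for i in range(7) if t_end - L < bt[i] <= t_end]
            assert list(w.beat_times) == list(bt[expected])
            assert list(w.intervals) == list(rr_ms[expected])


# --------------------------------------------------------------- time domain


def test_constant_window_time_domain_values():
    td = time_domain(make_window([1000.0] * 11))
    assert td["MeanRR"] == 1000.0
    assert td["SDRR"] == 0.0
    assert td["MeanHR"] == pytest.approx(60.0)
    assert td["RMSSD"] == 0.0
    assert td["PNN50"] == 0.0


def test_alternating_intervals_rmssd_and_pnn50():
    rr = [800.0, 900.0] * 10
    td = time_domain(make_window(rr))
    assert td["RMSSD"] == pytest.approx(100.0)
    assert td["PNN50"] == pytest.approx(100.0 * 19 / 20)  # 19 diffs over 20 intervals


def test_singleton_window_yields_sentinels():
    td = time_domain(make_window([800.0]))
    assert all(np.isnan(v) for v in td.values())


def test_mean_hr_switch_uses_mean_rr():
    w = make_window([700.0, 900.0, 1100.0, 800.0, 1000.0, 900.0])
    assert time_domain(w, hr_from_mean_rr=True)["MeanHR"] == pytest.approx(60000.0 / 900.0)
    assert time_domain(w)["MeanHR"] == pytest.approx(np.mean(60000.0 / np.asarray(w.intervals)))


# ---------------------------------------------------------------- oracle sweep


def test_all_17_metrics_match_naive_oracles_on_random_windows(rng):
    worst = 0.0
    for _ in range(100):
        n = int(rng.integers(30, 320))
        rr = rng.uniform(650.0, 1150.0, size=n)
        w = make_window(rr)
        got = window_features(w)
        exp = naive_time_domain(rr)
        exp.update(naive_freq_domain(w.beat_times, rr, 300.0))
        exp["StressIndex"] = naive_stress_index(rr)
        for k in FEATURE_COLUMNS:
            a, b = got[k], exp[k]
            if np.isnan(b):
                assert np.isnan(a), k
                continue
            rel = abs(a - b) / max(1e-12, abs(b))
            worst = max(worst, rel)
            assert rel < 1e-6, (k, a, b)
    assert worst < 1e-6


# ------------------------------------------------------------ frequency domain


def test_constant_rr_has_negligible_band_power():
    fd = freq_domain(make_window([1000.0] * 300))
    for band in ("VLFPower", "LFPower", "HFPower"):
        assert fd[band] <= 1e-6


@pytest.mark.parametrize(
    "freq,peak_field,ratio_gt_one",
    [(0.25, "HFPeak", False), (0.10, "LFPeak", True)],
)
def test_planted_sinusoid_recovers_peak(freq, peak_field, ratio_gt_one):
    t, rr = [], []
    now = 0.0
    while now < 300.0:
        val = 1000.0 + 50.0 * np.sin(2 * np.pi * freq * now)
        now += val / 1000.0
        t.append(now)
        rr.append(val)
    w = RRWindow(np.array(rr), np.array(t), t[-1], 300.0)
    fd = freq_domain(w)
    assert fd[peak_field] == pytest.approx(freq, abs=0.01)
    if ratio_gt_one:
        assert fd["LF_HF"] > 1.0
    else:
        assert fd["HFPower"] > 10.0 * (fd["VLFPower"] + fd["LFPower"])


def test_band_powers_sum_to_total_psd_power(rng):
    rr = rng.uniform(700.0, 1100.0, size=300)
    w = make_window(rr)
    fd = freq_domain(w)
    from scipy import interpolate, signal

    spline = interpolate.CubicSpline(w.beat_times, rr)
    grid = np.arange(w.beat_times[0], w.beat_times[-1], 0.25)
    x = signal.detrend(spline(grid), type="linear")
    f, psd = signal.welch(x, fs=4.0, nperseg=600, noverlap=300, detrend=False)
    m = f <= 0.4
    total = np.trapezoid(psd[m], f[m])
    assert fd["VLFPower"] + fd["LFPower"] + fd["HFPower"] == pytest.approx(total, rel=0.05)


# ----------------------------------------------------------------- stress index


def test_stress_index_constant_window_is_undefined():
    assert np.isnan(stress_index(make_window([1000.0] * 20)))


def test_stress_index_matches_hand_arithmetic():
    # 5 of 10 intervals in the modal 50-ms bin [1000, 1050) whose center is
    # 1025 ms; range 1100 - 900 = 200 ms.  SI = 50 / (2 * 1.025 * 0.2)
    rr = [1010.0, 1020.0, 1030.0, 1040.0, 1045.0, 900.0, 940.0, 960.0, 1060.0, 1100.0]
    si = 50.0 / (2.0 * 1.025 * 0.2)
    assert stress_index(make_window(rr)) == pytest.approx(np.sqrt(si), rel=1e-12)


def test_stress_index_matches_oracle_on_random_windows(rng):
    for _ in range(20):
        rr = rng.uniform(700.0, 1100.0, size=int(rng.integers(10, 200)))
        assert stress_index(make_window(rr)) == pytest.approx(
            naive_stress_index(rr), rel=1e-9
        )


# ------------------------------------------------------------------ artifacts


def test_clean_series_has_zero_artifact_fraction():
    rr = RRSeries(np.cumsum(np.full(100, 1.0)), np.full(100, 1000.0))
    assert artifact_fraction(rr) == 0.0
    assert not is_excluded(rr)


def test_single_spike_in_100_intervals_is_one_percent():
    vals = np.full(100, 1000.0)
    vals[50] = 1600.0
    rr = RRSeries(np.cumsum(vals) / 1000.0, vals)
    assert artifact_fraction(rr) == pytest.approx(1.0)


def test_six_spikes_in_100_flags_record_excluded():
    vals = np.full(100, 1000.0)
    vals[[10, 25, 40, 55, 70, 85]] = 1600.0
    rr = RRSeries(np.cumsum(vals) / 1000.0, vals)
    assert artifact_fraction(rr) == pytest.approx(6.0)
    assert is_excluded(rr)


# ------------------------------------------------------------------- per epoch


def test_stationary_record_gives_stable_metrics_across_epochs():
    vals, t, now = [], [], 0.0
    while now < 600.0:
        v = 1000.0 + 40.0 * np.sin(2 * np.pi * 0.25 * now)
        now += v / 1000.0
        vals.append(v)
        t.append(now)
    rr = RRSeries(np.array(t), np.array(vals))
    df = hrv_per_epoch(rr, 20, 300.0)
    steady = df.loc[~df["truncated"]]
    assert len(steady) >= 5
    assert steady["MeanRR"].std() < 2.0
    assert steady["HFPeak"].std() < 0.01


def test_output_length_matches_epoch_grid(tiny_cohort):
    rec = tiny_cohort[0]
    df = hrv_per_epoch(rec.rr, 10, 30.0)
    assert len(df) == 10
    assert list(df.columns[:17]) == FEATURE_COLUMNS


def test_longer_windows_pool_more_variance(tiny_cohort):
    rec = tiny_cohort[0]
    n = rec.grid.n_epochs
    s30 = hrv_per_epoch(rec.rr, n, 30.0)["SDRR"]
    s300 = hrv_per_epoch(rec.rr, n, 300.0)["SDRR"]
    assert np.nanmean(s300) >= np.nanmean(s30)


def test_disjoint_time_bases_error():
    rr = RRSeries(np.array([5000.0, 5001.0]), np.array([1000.0, 1000.0]))
    with pytest.raises(ValueError, match="disjoint"):
        hrv_per_epoch(rr, 10, 30.0)


def test_rejects_unknown_window_length(tiny_cohort):
    with pytest.raises(ValueError, match="window_len"):
        hrv_per_epoch(tiny_cohort[0].rr, 10, 60.0)


# ------------------------------------------------------------------ properties


@given(st.lists(st.floats(min_value=400.0, max_value=1500.0), min_size=10, max_size=60),
       st.floats(min_value=0.5, max_value=2.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_scaling_rr_scales_time_metrics(rr, c):
    base = time_domain(make_window(rr))
    scaled = time_domain(make_window([v * c for v in rr]))
    for k in ("MeanRR", "SDRR", "RMSSD"):
        assert scaled[k] == pytest.approx(base[k] * c, rel=1e-9, abs=1e-9)
    assert scaled["MeanHR"] == pytest.approx(base["MeanHR"] / c, rel=1e-9)


def test_order_invariance_and_sensitivity(rng):
    rr = rng.uniform(700.0, 1100.0, size=80)
    rev = rr[::-1].copy()
    a, b = time_domain(make_window(rr)), time_domain(make_window(rev))
    for k in ("MeanRR", "SDRR", "MeanHR", "HRVti", "TINN"):
        assert a[k] == pytest.approx(b[k], rel=1e-12)
    assert stress_index(make_window(rr)) == pytest.approx(
        stress_index(make_window(rev)), rel=1e-12
    )
    # RMSSD/PNN50 depend on successive ordering: a shuffled copy differs
    shuf = rr.copy()
    rng.shuffle(shuf)
    c = time_domain(make_window(shuf))
    assert abs(a["RMSSD"] - c["RMSSD"]) > 1e-9
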