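"""Agreement metrics and Bland–Altman statistics against formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import naive_bland_altman, naive_kappa

from hypnoscore.evaluate import (
    bland_altman,
    bland_altman_plot,
    compare_bias,
    epoch_metrics,
    kappa_multiclass,
    mean_ci,
    summarize_subjects,
)
from hypnoscore.stages import Hypnogram


def _hyp(labels):
    return Hypnogram(np.array(labels, dtype=object))


def _mixed(n_sleep, n_wake):
    return _hyp(["NREM"] * n_sleep + ["W"] * n_wake)


# ------------------------------------------------------------------ EBE metrics


def test_identical_sequences_are_perfect():
    h = _mixed(30, 10)
    m = epoch_metrics(h, h)
    assert m == {"accuracy": 100.0, "sensitivity": 100.0, "specificity": 100.0,
                 "kappa": 100.0}


def test_constant_all_sleep_prediction():
    ref = _mixed(30, 10)
    pred = _mixed(40, 0)
    m = epoch_metrics(ref, pred)
    assert m["sensitivity"] == 100.0
    assert m["specificity"] == 0.0
    assert m["kappa"] == 0.0  # constant rater -> zero by convention


def test_printed_2x2_table_matches_brute_force():
    # TP=40 TN=30 FP=10 FN=20
    ref = _hyp(["NREM"] * 60 + ["W"] * 40)
    pred = _hyp(["NREM"] * 40 + ["W"] * 20 + ["NREM"] * 10 + ["W"] * 30)
    m = epoch_metrics(ref, pred)
    assert m["accuracy"] == pytest.approx(70.0)
    assert m["sensitivity"] == pytest.approx(100.0 * 40 / 60, abs=0.005)  # 66.67
    assert m["specificity"] == pytest.approx(75.0)
    assert m["kappa"] == pytest.approx(100.0 * naive_kappa(40, 30, 10, 20), rel=1e-12)


def test_rater_swap_and_class_flip_symmetries(rng):
    ref = _hyp(rng.choice(["W", "NREM"], size=200))
    pred = _hyp(rng.choice(["W", "NREM"], size=200))
    a, b = epoch_metrics(ref, pred), epoch_metrics(pred, ref)
    # swapping the raters leaves the symmetric metrics unchanged
    assert a["accuracy"] == b["accuracy"]
    assert a["kappa"] == pytest.approx(b["kappa"], rel=1e-12)
    # flipping the positive class (scoring wake instead of sleep) swaps
    # sensitivity with specificity
    flip = lambda h: _hyp(np.where(h.labels == "W", "NREM", "W"))
    c = epoch_metrics(flip(ref), flip(pred))
    assert c["sensitivity"] == pytest.approx(a["specificity"], rel=1e-12)
    assert c["specificity"] == pytest.approx(a["sensitivity"], rel=1e-12)


def test_one_vs_rest_stage_framing():
    ref = _hyp(["W", "NREM", "REM", "REM", "NREM", "W"])
    pred = _hyp(["W", "REM", "REM", "NREM", "NREM", "NREM"])
    m = epoch_metrics(ref, pred, positive_class="REM")
    # REM vs rest: TP=1 (pos 2), FN=1 (pos 3), FP=1 (pos 1), TN=3
    assert m["sensitivity"] == pytest.approx(50.0)
    assert m["specificity"] == pytest.approx(75.0)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        epoch_metrics(_mixed(5, 5), _mixed(5, 4))


def test_multiclass_kappa_agrees_with_binary_on_two_classes(rng):
    ref = rng.choice(["W", "NREM"], size=300)
    pred = rng.choice(["W", "NREM"], size=300)
    m = epoch_metrics(_hyp(ref), _hyp(pred))
    assert kappa_multiclass(ref, pred) * 100.0 == pytest.approx(m["kappa"], rel=1e-12)


# -------------------------------------------------------------- subject summary


def test_identical_subject_values_have_zero_ci_width():
    m, lo, hi, n = mean_ci(np.array([80.0, 80.0, 80.0]))
    assert (m, lo, hi, n) == (80.0, 80.0, 80.0, 3)


def test_three_subject_ci_matches_t_table():
    m, lo, hi, n = mean_ci(np.array([60.0, 70.0, 80.0]))
    sem = 10.0 / np.sqrt(3)
    q = stats.t.ppf(0.975, 2)  # 4.3027
    assert m == 70.0 and n == 3
    assert lo == pytest.approx(70.0 - q * sem, rel=1e-12)
    assert hi == pytest.approx(70.0 + q * sem, rel=1e-12)


def test_sentinels_are_excluded_and_counted():
    vals = pd.DataFrame({"kappa": [50.0] * 9 + [np.nan]})
    out = summarize_subjects(vals)
    row = out.iloc[0]
    assert row["n_used"] == 9 and row["n_excluded"] == 1


def test_single_subject_has_no_ci():
    m, lo, hi, n = mean_ci(np.array([42.0]))
    assert m == 42.0 and n == 1 and np.isnan(lo) and np.isnan(hi)


# --------------------------------------------------------------- Bland–Altman


def test_identical_methods_have_zero_bias_and_loa():
    r = bland_altman([400.0, 420.0, 380.0, 460.0], [400.0, 420.0, 380.0, 460.0], "TST")
    assert r.bias == 0.0 and r.loa_lower == 0.0 and r.loa_upper == 0.0
    assert r.mae == 0.0 and r.t_p == 1.0


def test_constant_underestimation_gives_positive_bias():
    psg = np.array([400.0, 420.0, 380.0, 460.0, 350.0])
    ia = psg - 10.0  # device reads 10 min short... -> PSG - IA = +10
    r = bland_altman(psg, ia)
    assert r.bias == pytest.approx(10.0)
    assert r.loa_lower == pytest.approx(10.0) and r.loa_upper == pytest.approx(10.0)
    assert r.mae == pytest.approx(10.0)
    assert r.trend_slope == 0.0


def test_sign_convention_overestimation_is_negative():
    psg = np.array([100.0, 120.0, 140.0, 110.0])
    ia = psg + 25.0  # device overestimates
    assert bland_altman(psg, ia).bias == pytest.approx(-25.0)


def test_six_pair_toy_matches_formula_oracle():
    psg = [55.0, 62.0, 48.0, 70.0, 66.0, 51.0]
    ia = [50.0, 60.0, 52.0, 61.0, 70.0, 45.0]
    r = bland_altman(psg, ia, "SOL")
    o = naive_bland_altman(psg, ia)
    assert r.bias == pytest.approx(o["bias"], rel=1e-9)
    assert r.loa_lower == pytest.approx(o["loa_lower"], rel=1e-9)
    assert r.loa_upper == pytest.approx(o["loa_upper"], rel=1e-9)
    assert r.t_p == pytest.approx(o["t_p"], rel=1e-9)
    assert r.trend_slope == pytest.approx(o["trend_slope"], rel=1e-9)
    assert r.trend_p == pytest.approx(o["trend_p"], rel=1e-9)
    assert r.mae == pytest.approx(o["mae"], rel=1e-9)
    assert r.mae >= abs(r.bias)


def test_unpaired_lengths_rejected():
    with pytest.raises(ValueError, match="equal length"):
        bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


def test_bland_altman_plot_writes_file(tmp_path):
    psg = np.array([400.0, 420.0, 380.0, 460.0, 350.0])
    ia = psg - np.array([5.0, -3.0, 8.0, 0.0, 2.0])
    r = bland_altman(psg, ia, "TST")
    out = tmp_path / "ba_tst.png"
    bland_altman_plot(r, psg, ia, out)
    assert out.stat().st_size > 0


# ----------------------------------------------------------------- bias deltas


def test_identical_difference_vectors():
    d, p = compare_bias([3.0, -1.0, 2.0], [3.0, -1.0, 2.0])
    assert d == 0.0 and p == 1.0


def test_constant_shift_between_ia_biases():
    d1 = np.array([3.0, -1.0, 2.0, 0.5])
    d, _ = compare_bias(d1, d1 - 4.0)
    assert d == pytest.approx(4.0)


def test_compare_bias_matches_paired_t(rng):
    d1 = rng.normal(2.0, 5.0, size=15)
    d2 = rng.normal(0.0, 5.0, size=15)
    d, p = compare_bias(d1, d2)
    ref = stats.ttest_rel(d1, d2)
    assert d == pytest.approx(abs(np.mean(d1) - np.mean(d2)), rel=1e-12)
    assert p == pytest.approx(float(ref.pvalue), rel=1e-9)
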