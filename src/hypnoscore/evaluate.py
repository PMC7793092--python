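"""Epoch-by-epoch agreement metrics and method-comparison statistics.

Two families of device-vs-PSG statistics:

* **Epoch-by-epoch (EBE)**: per-subject accuracy, sensitivity, specificity
  and Cohen's kappa for a stated positive class — sleep vs wake, or
  one-vs-rest REM / NREM detection — reported in percent and summarized
  across subjects as mean with a t-based 95% CI.

* **Bland–Altman method comparison** of derived sleep parameters: paired
  differences d_i = PSG_i − IA_i give the bias (so a *positive* bias means
  the IA underestimates the PSG value), 1.96·SD limits of agreement, a
  paired-t test of zero bias, an OLS proportional-trend test of d against
  the pair means, and the mean absolute error.  Biases of two IAs over the
  same subjects are compared by a paired t-test on the difference of their
  difference vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stages import Hypnogram

EBE_METRICS = ("accuracy", "sensitivity", "specificity", "kappa")


def _positive_mask(labels: np.ndarray, positive_class: str) -> np.ndarray:
    if positive_class == "sleep":
        return labels != "W"
    if positive_class in ("REM", "NREM"):
        return labels == positive_class
    raise ValueError("positive_class must be 'sleep', 'REM' or 'NREM'")


def confusion_2x2(ref: np.ndarray, pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) of two boolean vectors."""
    tp = int(np.sum(ref & pred))
    tn = int(np.sum(~ref & ~pred))
    fp = int(np.sum(~ref & pred))
    fn = int(np.sum(ref & ~pred))
    return tp, tn, fp, fn


def kappa_binary(tp: int, tn: int, fp: int, fn: int) -> float:
    """Cohen's kappa from a 2x2 table (marginal-product chance agreement).

    Zero by convention when chance agreement is 1 (either rater constant).
    """
    n = tp + tn + fp + fn
    if n == 0:
        return float("nan")
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    if pe >= 1.0 - 1e-15:
        return 0.0
    return (po - pe) / (1.0 - pe)


def kappa_multiclass(ref_labels, pred_labels) -> float:
    """Cohen's kappa over an arbitrary shared label alphabet (fraction, not %)."""
    ref = np.asarray(ref_labels, dtype=object)
    pred = np.asarray(pred_labels, dtype=object)
    if ref.shape != pred.shape:
        raise ValueError("label sequences must have equal length")
    classes = sorted(set(ref) | set(pred))
    n = ref.size
    po = float(np.mean(ref == pred))
    pe = sum(np.mean(ref == c) * np.mean(pred == c) for c in classes)
    if pe >= 1.0 - 1e-15:
        return 0.0
    return (po - pe) / (1.0 - pe)


def epoch_metrics(ref: Hypnogram, pred: Hypnogram, positive_class: str = "sleep") -> dict:
    """EBE accuracy/sensitivity/specificity/kappa, in percent.

    Undefined cells (e.g. no positive epochs in the reference) yield NaN
    sentinels rather than errors.
    """
    if len(ref) != len(pred):
        raise ValueError(f"length mismatch: ref {len(ref)} vs pred {len(pred)}")
    r = _positive_mask(ref.labels, positive_class)
    p = _positive_mask(pred.labels, positive_class)
    tp, tn, fp, fn = confusion_2x2(r, p)
    n = tp + tn + fp + fn
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "kappa": 100.0 * kappa_binary(tp, tn, fp, fn),
    }


def mean_ci(values: np.ndarray, level: float = 0.95, t_based: bool = True) -> tuple[float, float, float, int]:
    """Mean and CI of per-subject values; NaN sentinels excluded.

    Returns (mean, lo, hi, n_used).  t-based by default; a normal-quantile
    mode is available.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        return float("nan"), float("nan"), float("nan"), 0
    m = float(np.mean(v))
    if n < 2:
        return m, float("nan"), float("nan"), n
    sem = float(np.std(v, ddof=1) / np.sqrt(n))
    q = stats.t.ppf((1 + level) / 2, n - 1) if t_based else stats.norm.ppf((1 + level) / 2)
    return m, m - q * sem, m + q * sem, n


def summarize_subjects(per_subject: pd.DataFrame, level: float = 0.95, t_based: bool = True) -> pd.DataFrame:
    """Mean and 95% CI per metric across subjects (one row per metric)."""
    rows = []
    for col in per_subject.columns:
        m, lo, hi, n = mean_ci(per_subject[col].to_numpy(), level, t_based)
        rows.append({"metric": col, "mean": m, "ci_lo": lo, "ci_hi": hi,
                     "n_used": n, "n_excluded": len(per_subject) - n})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- Bland–Altman


@dataclass(frozen=True)
class BAResult:
    """Bland–Altman comparison of one sleep parameter (PSG − IA differences)."""

    parameter: str
    n: int
    bias: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    t_p: float  # paired-t p for bias = 0
    trend_slope: float  # OLS of d on (PSG + IA)/2
    trend_p: float
    mae: float


def bland_altman(ref_vals, ia_vals, parameter: str = "") -> BAResult:
    """Bland–Altman statistics for paired per-subject parameter estimates.

    Differences are reference minus device (PSG − IA): positive bias means
    the device underestimates.  Limits of agreement are bias ± 1.96·SD of
    the differences; the trend test regresses d on the pair means.
    """
    ref = np.asarray(ref_vals, dtype=float)
    ia = np.asarray(ia_vals, dtype=float)
    if ref.shape != ia.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(ref) & np.isfinite(ia)
    ref, ia = ref[ok], ia[ok]
    n = ref.size
    if n < 3:
        raise ValueError("Bland–Altman requires at least 3 pairs")
    d = ref - ia
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    sem = sd / np.sqrt(n)
    q = stats.t.ppf(0.975, n - 1)
    if sd > 0:
        t_p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        t_p = 1.0 if bias == 0 else 0.0
    mean_pair = (ref + ia) / 2.0
    if np.ptp(mean_pair) > 0 and sd > 0:
        lr = stats.linregress(mean_pair, d)
        slope, trend_p = float(lr.slope), float(lr.pvalue)
    else:
        slope, trend_p = 0.0, 1.0
    return BAResult(
        parameter=parameter,
        n=n,
        bias=bias,
        bias_ci=(bias - q * sem, bias + q * sem),
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        t_p=t_p,
        trend_slope=slope,
        trend_p=trend_p,
        mae=float(np.mean(np.abs(d))),
    )


def compare_bias(diffs_ia1, diffs_ia2) -> tuple[float, float]:
    """Absolute difference of two IAs' biases and its paired-t p value.

    Both difference vectors must cover the same subjects in the same order.
    """
    d1 = np.asarray(diffs_ia1, dtype=float)
    d2 = np.asarray(diffs_ia2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("difference vectors must cover the same subjects")
    d = float(abs(np.mean(d1) - np.mean(d2)))
    delta = d1 - d2
    if np.std(delta, ddof=1) == 0:
        p = 1.0 if np.mean(delta) == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(delta, 0.0).pvalue)
    return d, p


def bland_altman_plot(result: BAResult, ref_vals, ia_vals, path):
    """Write a Bland–Altman plot: pair means on x, PSG − IA on y, solid bias
    line, dashed limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(ref_vals, dtype=float)
    ia = np.asarray(ia_vals, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((ref + ia) / 2.0, ref - ia, s=18, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1.5)
    ax.axhline(result.loa_lower, color="k", lw=1.0, ls="--")
    ax.axhline(result.loa_upper, color="k", lw=1.0, ls="--")
    ax.set_xlabel(f"mean of PSG and IA {result.parameter}")
    ax.set_ylabel(f"PSG − IA {result.parameter}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
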