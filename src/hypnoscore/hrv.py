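"""Per-epoch heart-rate-variability metrics over configurable window lengths.

Seventeen metrics — nine time-domain (MeanRR, SDRR, MeanHR, MinHR, MaxHR,
RMSSD, PNN50, HRVti, TINN) and eight frequency-domain (VLF/LF/HF peak
frequencies and absolute powers, LF/HF ratio) plus the square root of
Baevsky's stress index — are evaluated for every 30-s epoch over a trailing
window of 30 s, 3 min or 5 min ending at the epoch's end (a centered
alignment is also available).

Conventions follow common HRV practice: interval membership in a window is
decided by the interval's *terminating* beat falling in the half-open span
``(t_end - L, t_end]``; MeanHR is the mean of per-beat instantaneous HR;
Min/Max HR use a 5-beat moving average; the geometric metrics (HRVti, TINN)
use a 1/128-s histogram bin; the Baevsky mode uses 50-ms bins; spectra come
from a 4-Hz cubic-spline-resampled, linearly detrended tachogram via Welch's
method.  Epochs whose window cannot support a metric carry NaN sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .records import RRSeries
from .stages import EPOCH_LEN_S

ALLOWED_WINDOWS_S = (30.0, 180.0, 300.0)

#: column order of a feature table; abbreviations match common HRV reports
FEATURE_COLUMNS = [
    "MeanRR", "SDRR", "MeanHR", "MinHR", "MaxHR", "RMSSD", "PNN50",
    "HRVti", "TINN",
    "VLFPeak", "LFPeak", "HFPeak", "VLFPower", "LFPower", "HFPower",
    "LF_HF", "StressIndex",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

GEOM_BIN_S = 1.0 / 128.0  # histogram bin for HRVti / TINN
BAEVSKY_BIN_MS = 50.0


@dataclass(frozen=True)
class RRWindow:
    """Intervals whose terminating beats fall in ``(t_end - window_len, t_end]``."""

    intervals: np.ndarray  # ms
    beat_times: np.ndarray  # s, terminating beat of each interval
    t_end: float
    window_len: float
    truncated: bool = False  # True when clipped at the record start

    def __len__(self) -> int:
        return len(self.intervals)


def slice_rr(rr: RRSeries, t_end: float, window_len: float) -> RRWindow:
    """Trailing window of ``rr`` ending at ``t_end``.

    Windows that extend before the first beat are computed on the available
    intervals and flagged ``truncated``; a window before the record entirely
    is returned empty.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    t0 = t_end - window_len
    mask = (rr.beat_times > t0) & (rr.beat_times <= t_end)
    truncated = t0 < rr.span[0]
    return RRWindow(rr.intervals[mask], rr.beat_times[mask], t_end, window_len, truncated)


def slice_rr_centered(rr: RRSeries, epoch_end: float, window_len: float) -> RRWindow:
    """Window centered on the epoch (ends ``(L - 30)/2`` after the epoch end)."""
    center = epoch_end - EPOCH_LEN_S / 2.0
    return slice_rr(rr, center + window_len / 2.0, window_len)


# ---------------------------------------------------------------- time domain


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    return np.convolve(x, np.ones(k) / k, mode="valid")


def time_domain(w: RRWindow, hr_from_mean_rr: bool = False) -> dict:
    """Nine time-domain metrics of one window.

    ``hr_from_mean_rr`` switches MeanHR from the mean of per-beat HR
    (the default) to 60000/MeanRR.
    """
    rr = np.asarray(w.intervals, dtype=float)
    if rr.size < 2:
        return {k: np.nan for k in FEATURE_COLUMNS[:9]}
    hr = 60000.0 / rr
    mean_rr = float(np.mean(rr))
    mean_hr = 60000.0 / mean_rr if hr_from_mean_rr else float(np.mean(hr))
    if rr.size >= 5:
        ma = _moving_average(hr, 5)
        min_hr, max_hr = float(np.min(ma)), float(np.max(ma))
    else:  # too few beats for the 5-beat moving average: fall back, flagged by equality
        min_hr = max_hr = mean_hr
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = 100.0 * float(np.sum(np.abs(d) > 50.0)) / rr.size
    counts, _ = np.histogram(rr, bins=_geom_bin_edges(rr))
    hrvti = rr.size / float(counts.max())
    return {
        "MeanRR": mean_rr,
        "SDRR": float(np.std(rr, ddof=1)),
        "MeanHR": mean_hr,
        "MinHR": min_hr,
        "MaxHR": max_hr,
        "RMSSD": rmssd,
        "PNN50": pnn50,
        "HRVti": hrvti,
        "TINN": _tinn(rr),
    }


def _geom_bin_edges(rr_ms: np.ndarray) -> np.ndarray:
    """1/128-s bin edges aligned to the absolute time axis, covering the data."""
    bin_ms = GEOM_BIN_S * 1000.0
    lo = np.floor(rr_ms.min() / bin_ms) * bin_ms
    hi = np.ceil(rr_ms.max() / bin_ms) * bin_ms
    if hi <= lo:
        hi = lo + bin_ms
    return np.arange(lo, hi + bin_ms / 2, bin_ms)


def _tinn(rr_ms: np.ndarray) -> float:
    """Baseline width (ms) of the least-squares triangular fit to the RR histogram.

    The triangle is zero outside [N, M], rises linearly to the histogram
    peak Y at the mode bin X, and falls back to zero; N and M are chosen on
    the bin grid to minimize the squared error.  When the fit is degenerate
    (fewer than 3 occupied bins) the fallback is the occupied-bin span.
    """
    edges = _geom_bin_edges(rr_ms)
    counts, _ = np.histogram(rr_ms, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    occupied = np.nonzero(counts)[0]
    if occupied.size < 3:
        return float(centers[occupied[-1]] - centers[occupied[0]]) if occupied.size else 0.0
    x_i = int(np.argmax(counts))
    y = float(counts[x_i])
    x = centers[x_i]
    # The squared error splits at the mode: bins at or left of the mode
    # depend only on N, bins right of it only on M -> minimize separately.
    left = counts[: x_i + 1].astype(float)
    cl = centers[: x_i + 1]
    best_left = (np.inf, centers[0])
    for n_i in range(0, x_i + 1):
        n_v = cl[n_i]
        if x > n_v:
            tri = np.where(cl <= n_v, 0.0, y * (cl - n_v) / (x - n_v))
        else:  # N at the mode: triangle degenerates to the peak itself
            tri = np.where(cl < n_v, 0.0, y)
        err = float(np.sum((left - tri) ** 2))
        if err < best_left[0] - 1e-12:
            best_left = (err, n_v)
    right = counts[x_i + 1 :].astype(float)
    cr = centers[x_i + 1 :]
    best_right = (np.inf, centers[-1])
    for m_i in range(x_i, len(centers)):
        m_v = centers[m_i]
        if m_v > x:
            tri = np.where(cr >= m_v, 0.0, y * (m_v - cr) / (m_v - x))
        else:
            tri = np.zeros_like(cr)
        err = float(np.sum((right - tri) ** 2))
        if err < best_right[0] - 1e-12:
            best_right = (err, m_v)
    return float(best_right[1] - best_left[1])


# ----------------------------------------------------------- frequency domain


def freq_domain(
    w: RRWindow,
    bands: dict | None = None,
    resample_hz: float = 4.0,
) -> dict:
    """Seven frequency-domain metrics of one window.

    The tachogram (RR vs terminating-beat time) is cubic-spline resampled to
    an even ``resample_hz`` grid, linearly detrended, and fed to Welch's
    method (150-s segments with 50% overlap for 300-s windows, one segment
    otherwise).  Band power is the integral of the PSD over the band; the
    peak is the frequency of the PSD maximum inside the band.  VLF fields
    are NaN when the window is too short (< 50 s) to resolve the band.
    """
    bands = bands or {"VLF": VLF_BAND, "LF": LF_BAND, "HF": HF_BAND}
    out = {k: np.nan for k in FEATURE_COLUMNS[9:16]}
    rr = np.asarray(w.intervals, dtype=float)
    if rr.size < 4:
        return out
    t = np.asarray(w.beat_times, dtype=float)
    span = t[-1] - t[0]
    if span <= 0:
        return out
    spline = interpolate.CubicSpline(t, rr)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if grid.size < 8:
        return out
    x = signal.detrend(spline(grid), type="linear")
    if w.window_len >= 300.0 and grid.size >= int(150 * resample_hz):
        nperseg = int(150 * resample_hz)
    else:
        nperseg = grid.size
    f, psd = signal.welch(x, fs=resample_hz, nperseg=nperseg, noverlap=nperseg // 2,
                          detrend=False)
    vlf_resolvable = span >= 2.0 / max(bands["VLF"][1], 1e-9)
    for name, (lo, hi) in bands.items():
        m = (f >= lo) & (f <= hi)
        if name == "VLF" and not vlf_resolvable:
            continue
        if not np.any(m):
            continue
        out[f"{name}Power"] = float(np.trapezoid(psd[m], f[m])) if m.sum() > 1 else 0.0
        out[f"{name}Peak"] = float(f[m][np.argmax(psd[m])])
    lf, hf = out["LFPower"], out["HFPower"]
    if np.isfinite(lf) and np.isfinite(hf) and hf > 0:
        out["LF_HF"] = lf / hf
    return out


# ----------------------------------------------------------------- stress index


def stress_index(w: RRWindow) -> float:
    """Square root of Baevsky's stress index.

    SI = AMo / (2 * Mo * MxDMn) with the RR histogram on 50-ms bins: Mo the
    modal-bin center in seconds, AMo the modal bin's share of intervals in
    percent, MxDMn the RR range in seconds.  Constant windows (MxDMn = 0)
    return NaN: the index is undefined.
    """
    rr = np.asarray(w.intervals, dtype=float)
    if rr.size < 2:
        return np.nan
    mxdmn = (rr.max() - rr.min()) / 1000.0
    if mxdmn <= 0:
        return np.nan
    lo = np.floor(rr.min() / BAEVSKY_BIN_MS) * BAEVSKY_BIN_MS
    hi = np.ceil(rr.max() / BAEVSKY_BIN_MS) * BAEVSKY_BIN_MS
    if hi <= lo:
        hi = lo + BAEVSKY_BIN_MS
    edges = np.arange(lo, hi + BAEVSKY_BIN_MS / 2, BAEVSKY_BIN_MS)
    counts, _ = np.histogram(rr, bins=edges)
    mode_i = int(np.argmax(counts))
    mo_s = (edges[mode_i] + edges[mode_i + 1]) / 2.0 / 1000.0
    amo_pct = 100.0 * counts[mode_i] / rr.size
    si = amo_pct / (2.0 * mo_s * mxdmn)
    return float(np.sqrt(si))


# -------------------------------------------------------------- artifact rule


def artifact_fraction(rr: RRSeries, threshold: float = 0.20, kernel: int = 11) -> float:
    """Percentage of intervals deviating more than ``threshold`` (relative)
    from an 11-beat running median.

    A simple, documented artifact detector: records with >= 5% artifacts are
    excluded from training and evaluation (see :func:`is_excluded`).
    Returns NaN for series too short to median-filter meaningfully.
    """
    x = np.asarray(rr.intervals, dtype=float)
    if x.size < 3:
        return np.nan
    k = min(kernel, x.size if x.size % 2 == 1 else x.size - 1)
    med = signal.medfilt(x, kernel_size=k)
    bad = np.abs(x - med) > threshold * med
    return 100.0 * float(np.sum(bad)) / x.size


ARTIFACT_EXCLUSION_PCT = 5.0


def is_excluded(rr: RRSeries) -> bool:
    """Record-level exclusion rule: artifact fraction of 5% or more."""
    frac = artifact_fraction(rr)
    return bool(np.isnan(frac)) or frac >= ARTIFACT_EXCLUSION_PCT


# ------------------------------------------------------------------ per epoch


def window_features(w: RRWindow, hr_from_mean_rr: bool = False) -> dict:
    """All 17 metrics of one window (NaN sentinels where undefined)."""
    out = time_domain(w, hr_from_mean_rr=hr_from_mean_rr)
    out.update(freq_domain(w))
    out["StressIndex"] = stress_index(w)
    return out


def hrv_per_epoch(
    rr: RRSeries,
    n_epochs: int,
    window_len: float,
    align: str = "trailing",
    epoch_len: float = EPOCH_LEN_S,
    hr_from_mean_rr: bool = False,
) -> pd.DataFrame:
    """Evaluate the 17 metrics for every epoch of a record.

    Returns a DataFrame indexed by epoch with the 17 named columns plus a
    boolean ``truncated`` flag for windows clipped at the record start.
    """
    if window_len not in ALLOWED_WINDOWS_S:
        raise ValueError(f"window_len must be one of {ALLOWED_WINDOWS_S}")
    if align not in ("trailing", "centered"):
        raise ValueError("align must be 'trailing' or 'centered'")
    record_end = n_epochs * epoch_len
    if rr.beat_times[0] > record_end:
        raise ValueError("RR series and epoch grid have disjoint time bases")
    rows = []
    flags = []
    for i in range(n_epochs):
        t_end = (i + 1) * epoch_len
        if align == "trailing":
            w = slice_rr(rr, t_end, window_len)
        else:
            w = slice_rr_centered(rr, t_end, window_len)
        rows.append(window_features(w, hr_from_mean_rr=hr_from_mean_rr))
        flags.append(w.truncated)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.index.name = "epoch"
    df["truncated"] = flags
    return df
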