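"""Independent naive-loop oracles used to verify the HRV and statistics code.

Everything here is written from the metric definitions directly — plain
Python loops, hand-rolled Welch periodograms via np.fft, exhaustive searches
— and deliberately shares no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import interpolate

GEOM_BIN_MS = 1000.0 / 128.0
BAEVSKY_BIN_MS = 50.0


def naive_time_domain(rr_ms) -> dict:
    rr = [float(v) for v in rr_ms]
    n = len(rr)
    mean_rr = sum(rr) / n
    var = sum((v - mean_rr) ** 2 for v in rr) / (n - 1)
    hr = [60000.0 / v for v in rr]
    mean_hr = sum(hr) / n
    if n >= 5:
        ma = [sum(hr[i : i + 5]) / 5.0 for i in range(n - 4)]
        min_hr, max_hr = min(ma), max(ma)
    else:
        min_hr = max_hr = mean_hr
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / n
    counts, centers = _hist(rr, GEOM_BIN_MS)
    hrvti = n / max(counts)
    return {
        "MeanRR": mean_rr,
        "SDRR": math.sqrt(var),
        "MeanHR": mean_hr,
        "MinHR": min_hr,
        "MaxHR": max_hr,
        "RMSSD": rmssd,
        "PNN50": pnn50,
        "HRVti": hrvti,
        "TINN": naive_tinn(rr),
    }


def _hist(rr, bin_ms):
    lo = math.floor(min(rr) / bin_ms) * bin_ms
    hi = math.ceil(max(rr) / bin_ms) * bin_ms
    if hi <= lo:
        hi = lo + bin_ms
    nbins = int(round((hi - lo) / bin_ms))
    counts = [0] * nbins
    for v in rr:
        idx = int((v - lo) / bin_ms)
        if idx >= nbins:
            idx = nbins - 1
        counts[idx] += 1
    centers = [lo + (i + 0.5) * bin_ms for i in range(nbins)]
    return counts, centers


def naive_tinn(rr) -> float:
    """Exhaustive O(B^2) search over all (N, M) triangular-fit pairs."""
    counts, centers = _hist(rr, GEOM_BIN_MS)
    occupied = [i for i, c in enumerate(counts) if c > 0]
    if len(occupied) < 3:
        return centers[occupied[-1]] - centers[occupied[0]] if occupied else 0.0
    x_i = max(range(len(counts)), key=lambda i: counts[i])
    x, y = centers[x_i], float(counts[x_i])
    best_err, best_n, best_m = float("inf"), centers[0], centers[-1]
    for n_i in range(0, x_i + 1):
        for m_i in range(x_i, len(centers)):
            n_v, m_v = centers[n_i], centers[m_i]
            err = 0.0
            for j, c in enumerate(counts):
                t = centers[j]
                tri = 0.0
                if n_v <= t <= m_v:
                    if t == x:
                        tri = y
                    elif t < x and x > n_v:
                        tri = y * (t - n_v) / (x - n_v)
                    elif t > x and m_v > x:
                        tri = y * (m_v - t) / (m_v - x)
                err += (c - tri) ** 2
            if err < best_err - 1e-12:
                best_err, best_n, best_m = err, n_v, m_v
    return best_m - best_n


def naive_stress_index(rr_ms) -> float:
    rr = [float(v) for v in rr_ms]
    mxdmn = (max(rr) - min(rr)) / 1000.0
    if mxdmn <= 0 or len(rr) < 2:
        return float("nan")
    counts, centers = _hist(rr, BAEVSKY_BIN_MS)
    mode_i = max(range(len(counts)), key=lambda i: counts[i])
    mo_s = centers[mode_i] / 1000.0
    amo = 100.0 * counts[mode_i] / len(rr)
    return math.sqrt(amo / (2.0 * mo_s * mxdmn))


def naive_welch(x, fs, nperseg, noverlap):
    """Hand-rolled Welch PSD (periodic Hann, density scaling, one-sided)."""
    x = np.asarray(x, dtype=float)
    step = nperseg - noverlap
    w = np.array([0.5 - 0.5 * math.cos(2 * math.pi * i / nperseg) for i in range(nperseg)])
    norm = fs * float(np.sum(w * w))
    segs = []
    start = 0
    while start + nperseg <= x.size:
        seg = x[start : start + nperseg] * w
        spec = np.fft.rfft(seg)
        p = (np.abs(spec) ** 2) / norm
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        segs.append(p)
        start += step
    f = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return f, np.mean(segs, axis=0)


def naive_freq_domain(beat_times, rr_ms, window_len, fs=4.0) -> dict:
    """Frequency metrics recomputed step by step from the stated pipeline."""
    t = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    spline = interpolate.CubicSpline(t, rr)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    xg = spline(grid)
    # linear detrend by least squares, written out
    tt = np.arange(grid.size, dtype=float)
    a, b = np.polyfit(tt, xg, 1)
    x = xg - (a * tt + b)
    if window_len >= 300.0 and grid.size >= int(150 * fs):
        nperseg = int(150 * fs)
    else:
        nperseg = grid.size
    f, psd = naive_welch(x, fs, nperseg, nperseg // 2)
    out = {}
    span = t[-1] - t[0]
    bands = {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.40)}
    for name, (lo, hi) in bands.items():
        if name == "VLF" and span < 2.0 / 0.04:
            out["VLFPower"] = float("nan")
            out["VLFPeak"] = float("nan")
            continue
        idx = [i for i in range(f.size) if lo <= f[i] <= hi]
        power = 0.0
        for i, j in zip(idx[:-1], idx[1:]):
            power += 0.5 * (psd[i] + psd[j]) * (f[j] - f[i])
        out[f"{name}Power"] = power
        out[f"{name}Peak"] = float(f[max(idx, key=lambda i: psd[i])])
    out["LF_HF"] = (
        out["LFPower"] / out["HFPower"] if out.get("HFPower", 0) > 0 else float("nan")
    )
    return out


def naive_kappa(tp, tn, fp, fn) -> float:
    n = tp + tn + fp + fn
    po = (tp + tn) / n
    pe = ((tp + fn) / n) * ((tp + fp) / n) + ((tn + fp) / n) * ((tn + fn) / n)
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def naive_bland_altman(ref, ia):
    """Formula-by-formula Bland–Altman recomputation (loops + closed forms)."""
    from scipy import stats

    d = [float(r) - float(v) for r, v in zip(ref, ia)]
    n = len(d)
    bias = sum(d) / n
    var = sum((v - bias) ** 2 for v in d) / (n - 1)
    sd = math.sqrt(var)
    mean_pair = [(float(r) + float(v)) / 2.0 for r, v in zip(ref, ia)]
    mx = sum(mean_pair) / n
    sxx = sum((m - mx) ** 2 for m in mean_pair)
    sxy = sum((m - mx) * (dd - bias) for m, dd in zip(mean_pair, d))
    slope = sxy / sxx
    resid = [dd - bias - slope * (m - mx) for m, dd in zip(mean_pair, d)]
    s2 = sum(r * r for r in resid) / (n - 2)
    se_slope = math.sqrt(s2 / sxx)
    t_slope = slope / se_slope
    p_slope = 2 * stats.t.sf(abs(t_slope), n - 2)
    t_bias = bias / (sd / math.sqrt(n))
    p_bias = 2 * stats.t.sf(abs(t_bias), n - 1)
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "t_p": p_bias,
        "trend_slope": slope,
        "trend_p": p_slope,
        "mae": sum(abs(v) for v in d) / n,
    }
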