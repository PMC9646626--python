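"""Independent naive reimplementations of the 51 window features.

These are deliberately slow, loop-level translations of the written
feature definitions, sharing no code path with the package: spectra come
from an explicit DFT matrix, autocorrelation from per-lag dot products,
the envelope spline from a hand-assembled not-a-knot linear system, and
approximate entropy from a direct per-template loop.  Pulse anchors are
taken as given (the detector is validated separately against generator
truth), so oracle agreement checks the feature arithmetic, not peak
detection.
"""

from __future__ import annotations

import numpy as np

from neckppg.features import (
    _BAND_EDGE_EPS,
    AVGPOWER_BANDS,
    CORRELOGRAM_MIN_LAG_S,
    DB_FLOOR,
    ENTROPY_BANDS,
    ENVELOPE_MIN_SEPARATION,
    ENVPOWER_BANDS,
    FEATURE_NAMES,
    RELPOWER_BANDS,
)


def skewness(seg):
    d = seg - np.mean(seg)
    m2 = np.mean(d**2)
    return 0.0 if m2 == 0 else np.mean(d**3) / m2**1.5


def kurtosis(seg):
    d = seg - np.mean(seg)
    m2 = np.mean(d**2)
    return 0.0 if m2 == 0 else np.mean(d**4) / m2**2


def sample_std(v):
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        return np.nan
    mu = np.mean(v)
    return np.sqrt(np.sum((v - mu) ** 2) / (v.size - 1))


def mean_abs_diff(v):
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        return np.nan
    return np.mean([abs(v[i + 1] - v[i]) for i in range(v.size - 1)])


def time_features(x, fs, pulses, start_s, W):
    """F1-F25 recomputed from the pulse anchors by direct loops."""
    i0, i1 = int(round(start_s * fs)), int(round((start_s + W) * fs))
    out = {name: np.nan for name in FEATURE_NAMES[:25]}
    # zero-crossing rate, zeros inheriting the previous sign
    signs = [np.sign(v) for v in x[i0:i1] if v != 0]
    crossings = sum(
        1 for a, b in zip(signs, signs[1:]) if a != b
    )
    out["ZeroCrossingRate"] = crossings / W if len(signs) >= 2 else 0.0

    keep = [
        k for k in range(pulses.n_pulses)
        if i0 <= pulses.peaks[k] < i1
    ]
    if len(keep) < 2:
        return out
    on = pulses.onsets[keep]
    pk = pulses.peaks[keep]
    off = pulses.offsets[keep]
    amp = [x[p] - x[o] for o, p in zip(on, pk)]
    width = [(f - o) / fs for o, f in zip(on, off)]
    rise = [(p - o) / fs for o, p in zip(on, pk)]
    skw = [skewness(x[o : f + 1]) for o, f in zip(on, off)]
    krt = [kurtosis(x[o : f + 1]) for o, f in zip(on, off)]
    phd = [x[pk[k + 1]] - x[pk[k]] for k in range(len(pk) - 1)]
    pdist = [(pk[k + 1] - pk[k]) / fs for k in range(len(pk) - 1)]
    trough = [x[on[k + 1]] - x[on[k]] for k in range(len(on) - 1)]

    out["Amplitude"] = np.mean(amp)
    out["Width"] = np.mean(width)
    out["RiseTime"] = np.mean(rise)
    out["Skewness"] = np.mean(skw)
    out["Kurtosis"] = np.mean(krt)
    out["PeakHeightDiff"] = np.mean(np.abs(phd)) if phd else np.nan
    out["PeakDistance"] = np.mean(pdist) if pdist else np.nan
    out["TroughDiff"] = np.mean(np.abs(trough)) if trough else np.nan
    series = {
        "Amplitude": amp, "Width": width, "RiseTime": rise,
        "Skewness": skw, "Kurtosis": krt,
        "PeakHeightDiff": phd, "PeakDistance": pdist, "TroughDiff": trough,
    }
    for name, v in series.items():
        out[f"Change{name}"] = mean_abs_diff(np.asarray(v))
        out[f"Std{name}"] = sample_std(np.asarray(v))
    return out


def local_maxima_min_distance(x, distance):
    """Strict local maxima thinned by keeping taller peaks first."""
    cand = [
        i for i in range(1, len(x) - 1) if x[i - 1] < x[i] and x[i] > x[i + 1]
    ]
    keep = set()
    for i in sorted(cand, key=lambda i: -x[i]):
        if all(abs(i - j) >= distance for j in keep):
            keep.add(i)
    return sorted(keep)


def correlogram(x, fs, W):
    """F26-F29 by per-lag dot products and a local-maximum scan."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    max_lag = int(round(min(4.0, W / 2.0) * fs))
    r = np.array(
        [np.sum(xc[: xc.size - k] * xc[k:]) / denom for k in range(max_lag + 1)]
    )
    min_lag = int(round(CORRELOGRAM_MIN_LAG_S * fs))
    maxima = [
        k for k in range(1, r.size - 1) if r[k - 1] < r[k] and r[k] > r[k + 1]
    ]
    maxima = [k for k in maxima if k >= min_lag]
    out = {
        "CorrelogramPeak1": np.nan, "CorrelogramPeak2": np.nan,
        "CorrelogramLag1": np.nan, "CorrelogramLag2": np.nan,
    }
    if len(maxima) >= 1:
        out["CorrelogramPeak1"], out["CorrelogramLag1"] = r[maxima[0]], maxima[0] / fs
    if len(maxima) >= 2:
        out["CorrelogramPeak2"], out["CorrelogramLag2"] = r[maxima[1]], maxima[1] / fs
    return out


def dft_matrix(n):
    k = np.arange(n // 2 + 1)[:, None]
    t = np.arange(n)[None, :]
    return np.exp(-2j * np.pi * k * t / n)


def spectrogram(x, fs, frame_s=10.0, hop_s=1.0):
    """Modified periodogram per frame via an explicit DFT matrix."""
    nper = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    N = nper
    w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(N) / N)  # periodic Hamming
    D = dft_matrix(N)
    starts = list(range(0, len(x) - nper + 1, hop))
    freqs = np.arange(N // 2 + 1) * fs / N
    psd = np.empty((freqs.size, len(starts)))
    stft_real = np.empty_like(psd)
    scale = 1.0 / (fs * np.sum(w * w))
    for j, s in enumerate(starts):
        X = D @ (x[s : s + nper] * w)
        p = scale * np.abs(X) ** 2
        p[1:] = p[1:] * 2
        if N % 2 == 0:
            p[-1] = p[-1] / 2
        psd[:, j] = p
        stft_real[:, j] = X.real
    psd = np.maximum(psd, 10.0 ** (DB_FLOOR / 10.0))
    times = np.array(starts) / fs + frame_s / 2.0
    return freqs, times, psd, stft_real


def psd_features(freqs, times, psd, stft_real, start_s, W, frame_s=10.0):
    """F30-F41 from the mean in-window PSD, by direct bin loops."""
    names = FEATURE_NAMES[29:41]
    centers = [j for j, t in enumerate(times) if start_s <= t < start_s + W]
    if not centers:
        return {name: np.nan for name in names}
    P = psd[:, centers].mean(axis=1)
    out = {}
    for (lo, hi), name in zip(
        ENTROPY_BANDS, ["SpectralEntropy (0-1.5Hz)", "SpectralEntropy (1-4Hz)"]
    ):
        bins = [P[i] for i, f in enumerate(freqs) if lo - _BAND_EDGE_EPS <= f <= hi + _BAND_EDGE_EPS]
        total = sum(bins)
        h = -sum(
            (b / total) * np.log(b / total) for b in bins if b > 0
        )
        out[name] = h / np.log(len(bins))
    sk_cols = centers
    if len(centers) < 4:
        sk_cols = [
            j for j, t in enumerate(times)
            if (t + frame_s / 2 > start_s) and (t - frame_s / 2 < start_s + W)
        ]
    R = stft_real[:, sk_cols]
    for (lo, hi), name in zip(
        ENTROPY_BANDS, ["SpectralKurtosis (0-1.5Hz)", "SpectralKurtosis (1-4Hz)"]
    ):
        vals = []
        for i, f in enumerate(freqs):
            if lo - _BAND_EDGE_EPS <= f <= hi + _BAND_EDGE_EPS:
                m2 = np.mean(R[i] ** 2)
                m4 = np.mean(R[i] ** 4)
                vals.append(m4 / m2**2 if m2 > 0 else np.nan)
        out[name] = np.nanmean(vals) if vals else np.nan
    total = P.sum()
    for (lo, hi) in RELPOWER_BANDS:
        band = [P[i] for i, f in enumerate(freqs) if lo - _BAND_EDGE_EPS <= f <= hi + _BAND_EDGE_EPS]
        out[f"RelativePower ({lo:g}-{hi:g}Hz)"] = sum(band) / total
    for (lo, hi) in AVGPOWER_BANDS:
        band = [P[i] for i, f in enumerate(freqs) if lo - _BAND_EDGE_EPS <= f <= hi + _BAND_EDGE_EPS]
        out[f"AvgPower ({lo:g}-{hi:g}Hz)"] = np.mean(band)
    return out


def not_a_knot_spline(xk, yk):
    """Piecewise-cubic coefficients of the not-a-knot interpolant.

    Returns a callable evaluating the spline; built from a dense linear
    system over per-interval cubic coefficients (k >= 4), a single
    parabola (k == 3) or a line (k == 2).
    """
    xk = np.asarray(xk, dtype=float)
    yk = np.asarray(yk, dtype=float)
    k = xk.size
    if k == 2:
        slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
        return lambda t: yk[0] + slope * (np.asarray(t) - xk[0])
    if k == 3:
        coef = np.polyfit(xk, yk, 2)
        return lambda t: np.polyval(coef, np.asarray(t))
    m = k - 1  # intervals; unknowns: a,b,c,d per interval
    A = np.zeros((4 * m, 4 * m))
    rhs = np.zeros(4 * m)
    row = 0

    def cols(i):
        return slice(4 * i, 4 * i + 4)

    for i in range(m):
        h = xk[i + 1] - xk[i]
        A[row, 4 * i] = 1.0
        rhs[row] = yk[i]
        row += 1
        A[row, cols(i)] = [1.0, h, h**2, h**3]
        rhs[row] = yk[i + 1]
        row += 1
    for i in range(m - 1):
        h = xk[i + 1] - xk[i]
        A[row, cols(i)] = [0.0, 1.0, 2 * h, 3 * h**2]
        A[row, 4 * (i + 1) + 1] = -1.0
        row += 1
        A[row, cols(i)] = [0.0, 0.0, 2.0, 6 * h]
        A[row, 4 * (i + 1) + 2] = -2.0
        row += 1
    A[row, 4 * 0 + 3] = 1.0
    A[row, 4 * 1 + 3] = -1.0
    row += 1
    A[row, 4 * (m - 2) + 3] = 1.0
    A[row, 4 * (m - 1) + 3] = -1.0
    row += 1
    assert row == 4 * m
    coef = np.linalg.solve(A, rhs)

    def evaluate(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        for j, tv in enumerate(t):
            i = int(np.searchsorted(xk, tv, side="right")) - 1
            i = min(max(i, 0), m - 1)
            dt = tv - xk[i]
            a, b, c, d = coef[cols(i)]
            out[j] = a + b * dt + c * dt**2 + d * dt**3
        return out

    return evaluate


def upper_envelope(x, fs):
    x = np.asarray(x, dtype=float)
    peaks = local_maxima_min_distance(x, ENVELOPE_MIN_SEPARATION)
    n = x.size
    if len(peaks) < 2:
        level = x[peaks[0]] if peaks else np.max(x)
        return np.full(n, level)
    spline = not_a_knot_spline(peaks, x[peaks])
    idx = np.clip(np.arange(n), peaks[0], peaks[-1])
    return spline(idx)


def approx_entropy(x, m=2, r=None):
    """Direct Pincus ApEn with a per-template loop (self-matches included)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if r <= 0 or x.size < m + 2:
        return 0.0

    def phi(mm):
        M = x.size - mm + 1
        templates = np.array([x[i : i + mm] for i in range(M)])
        logs = []
        for ti in templates:  # per-template loop; j-axis vectorized
            cheb = np.max(np.abs(templates - ti), axis=1)
            logs.append(np.log(np.count_nonzero(cheb <= r) / M))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def envelope_features(env, fs):
    """F42-F51 from a given envelope, by direct formulas."""
    e = np.asarray(env, dtype=float)
    out = {}
    out["EnvelopeStd"] = sample_std(e)
    out["EnvelopeMax"] = np.max(e)
    out["EnvelopeMin"] = np.min(e)
    out["EnvelopeRange"] = out["EnvelopeMax"] - out["EnvelopeMin"]
    out["EnvelopeApproxEntropy"] = approx_entropy(e)
    a = np.abs(e)
    out["EnvelopeArea"] = sum(
        (a[i] + a[i + 1]) / 2.0 / fs for i in range(a.size - 1)
    )
    d = e - e.mean()
    N = d.size
    D = dft_matrix(N)
    X = D @ d
    p = np.abs(X) ** 2 / (fs * N)
    p[1:] = p[1:] * 2
    if N % 2 == 0:
        p[-1] = p[-1] / 2
    freqs = np.arange(N // 2 + 1) * fs / N
    for (lo, hi) in ENVPOWER_BANDS:
        band = [p[i] for i, f in enumerate(freqs) if lo - _BAND_EDGE_EPS <= f <= hi + _BAND_EDGE_EPS]
        out[f"EnvelopeAvgPower ({lo:g}-{hi:g}Hz)"] = np.mean(band)
    return out


def full_feature_vector(rec, pulses, start_s, W, spec_cache=None):
    """All 51 features for one window, via the naive paths only."""
    x = rec.samples
    fs = rec.fs
    if spec_cache is None:
        spec_cache = spectrogram(x, fs)
    freqs, times, psd, stft_real = spec_cache
    i0, i1 = int(round(start_s * fs)), int(round((start_s + W) * fs))
    xw = x[i0:i1]
    values = {}
    values.update(time_features(x, fs, pulses, start_s, W))
    values.update(correlogram(xw, fs, W))
    values.update(psd_features(freqs, times, psd, stft_real, start_s, W))
    env = upper_envelope(xw, fs)
    values.update(envelope_features(env, fs))
    return np.array([values[name] for name in FEATURE_NAMES])
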