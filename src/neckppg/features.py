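"""The 51-feature catalog for windowed neck-PPG classification.

Features fall into four blocks:

* time-domain pulse morphology (F1-F25): per-pulse amplitude, width,
  rise time, shape statistics, their pulse-to-pulse changes and
  window-level standard deviations, plus the zero-crossing rate;
* correlogram (F26-F29): value and lag of the first two autocorrelation
  peaks — periodic pulse trains correlate strongly, artifacts do not;
* frequency domain (F30-F41): band-restricted Shannon spectral entropy,
  spectral kurtosis, relative and average band powers from a 10 s / 90%
  overlap modified-periodogram spectrogram;
* upper envelope (F42-F51): statistics, approximate entropy, area and
  band powers of the spline upper envelope, which tracks respiratory
  amplitude modulation and hence collapses during apnea.

Numerical conventions (documented because the window-level oracle must
match them): series standard deviations use the sample (n-1) estimator;
"change" features are means of absolute consecutive differences;
spectral entropy uses natural logs normalized by log(#bins); band powers
are computed in the linear power domain (dB is storage/presentation
only); pulse kurtosis is the non-excess (normal == 3) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, get_window, periodogram

from .io import Recording
from .pulses import PulseSet

_BASE_NAMES = [
    "Amplitude",
    "Width",
    "PeakHeightDiff",
    "PeakDistance",
    "TroughDiff",
    "RiseTime",
    "Skewness",
    "Kurtosis",
]

#: Canonical feature names F1..F51 (CSV column glossary).
FEATURE_NAMES: list[str] = (
    _BASE_NAMES
    + [f"Change{b}" for b in _BASE_NAMES]
    + [f"Std{b}" for b in _BASE_NAMES]
    + ["ZeroCrossingRate"]
    + ["CorrelogramPeak1", "CorrelogramPeak2", "CorrelogramLag1", "CorrelogramLag2"]
    + [
        "SpectralEntropy (0-1.5Hz)",
        "SpectralEntropy (1-4Hz)",
        "SpectralKurtosis (0-1.5Hz)",
        "SpectralKurtosis (1-4Hz)",
        "RelativePower (0-0.8Hz)",
        "RelativePower (0.8-1.3Hz)",
        "RelativePower (1.3-1.8Hz)",
        "AvgPower (0-0.8Hz)",
        "AvgPower (0.8-1.3Hz)",
        "AvgPower (1.3-1.8Hz)",
        "AvgPower (2.2-2.8Hz)",
        "AvgPower (3.2-3.8Hz)",
    ]
    + [
        "EnvelopeStd",
        "EnvelopeMax",
        "EnvelopeMin",
        "EnvelopeRange",
        "EnvelopeApproxEntropy",
        "EnvelopeArea",
        "EnvelopeAvgPower (0-0.15Hz)",
        "EnvelopeAvgPower (0.2-0.5Hz)",
        "EnvelopeAvgPower (0-0.5Hz)",
        "EnvelopeAvgPower (0.5-1Hz)",
    ]
)

#: The ten envelope feature names (F42-F51).
ENVELOPE_FEATURES = FEATURE_NAMES[41:]

RELPOWER_BANDS = [(0.0, 0.8), (0.8, 1.3), (1.3, 1.8)]
AVGPOWER_BANDS = [(0.0, 0.8), (0.8, 1.3), (1.3, 1.8), (2.2, 2.8), (3.2, 3.8)]
ENTROPY_BANDS = [(0.0, 1.5), (1.0, 4.0)]
ENVPOWER_BANDS = [(0.0, 0.15), (0.2, 0.5), (0.0, 0.5), (0.5, 1.0)]

#: Minimum local-maximum separation for the upper envelope, in samples.
ENVELOPE_MIN_SEPARATION = 50

#: First correlogram peak is searched from this lag (guards the lag-0 max).
CORRELOGRAM_MIN_LAG_S = 0.25

SPECTROGRAM_FRAME_S = 10.0
SPECTROGRAM_HOP_S = 1.0
DB_FLOOR = -120.0


# ---------------------------------------------------------------------------
# time-domain block
# ---------------------------------------------------------------------------

def _pulse_skewness(seg: np.ndarray) -> float:
    """Biased sample skewness g1 = m3 / m2^(3/2)."""
    d = seg - seg.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0
    return float(np.mean(d**3) / m2**1.5)


def _pulse_kurtosis(seg: np.ndarray) -> float:
    """Non-excess kurtosis m4 / m2^2 (normal == 3)."""
    d = seg - seg.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0
    return float(np.mean(d**4) / m2**2)


def per_pulse_features(rec: Recording, pulses: PulseSet) -> pd.DataFrame:
    """Per-pulse morphology table (anchors plus F1, F2, F6, F7, F8).

    One row per detected pulse with columns ``onset, peak, offset``
    (sample indices), ``onset_val, peak_val`` (raw amplitudes) and the
    single-pulse features.  Pairwise features (F3-F5) are derived from
    consecutive rows by :func:`aggregate_time_features` so that window
    restriction stays exact.
    """
    x = rec.samples
    fs = rec.fs
    rows = []
    for o, p, f in zip(pulses.onsets, pulses.peaks, pulses.offsets):
        seg = x[o : f + 1]
        rows.append(
            {
                "onset": o,
                "peak": p,
                "offset": f,
                "onset_val": x[o],
                "peak_val": x[p],
                "Amplitude": x[p] - x[o],
                "Width": (f - o) / fs,
                "RiseTime": (p - o) / fs,
                "Skewness": _pulse_skewness(seg),
                "Kurtosis": _pulse_kurtosis(seg),
            }
        )
    cols = [
        "onset", "peak", "offset", "onset_val", "peak_val",
        "Amplitude", "Width", "RiseTime", "Skewness", "Kurtosis",
    ]
    return pd.DataFrame(rows, columns=cols)


def zero_crossing_rate(x: np.ndarray, duration_s: float) -> float:
    """Sign changes of the signal per second (zeros inherit the prior sign)."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0.0
    crossings = int(np.count_nonzero(s[:-1] != s[1:]))
    return crossings / duration_s


def _mean_abs_diff(series: np.ndarray) -> float:
    if series.size < 2:
        return np.nan
    return float(np.mean(np.abs(np.diff(series))))


def _sample_std(series: np.ndarray) -> float:
    if series.size < 2:
        return np.nan
    return float(np.std(series, ddof=1))


def aggregate_time_features(
    ppdf: pd.DataFrame, start_s: float, W: float, rec: Recording
) -> dict[str, float]:
    """Window-level time features F1-F25.

    F1-F8 are means over in-window pulses (pairwise F3-F5 are aggregated
    as means of absolute pair differences); F9-F16 ("Change") are means
    of absolute consecutive differences of the per-pulse series; F17-F24
    are sample standard deviations over the window; F25 is the
    zero-crossing rate of the windowed signal.  Windows holding fewer
    than 2 pulses yield NaN for all pulse-based features.
    """
    fs = rec.fs
    i0, i1 = int(round(start_s * fs)), int(round((start_s + W) * fs))
    out = {name: np.nan for name in FEATURE_NAMES[:25]}
    out["ZeroCrossingRate"] = zero_crossing_rate(rec.samples[i0:i1], W)

    if len(ppdf) == 0:
        return out
    sel = ppdf[(ppdf["peak"] >= i0) & (ppdf["peak"] < i1)]
    if len(sel) < 2:
        return out

    series: dict[str, np.ndarray] = {
        "Amplitude": sel["Amplitude"].to_numpy(),
        "Width": sel["Width"].to_numpy(),
        "RiseTime": sel["RiseTime"].to_numpy(),
        "Skewness": sel["Skewness"].to_numpy(),
        "Kurtosis": sel["Kurtosis"].to_numpy(),
        # pairwise series over consecutive in-window pulses
        "PeakHeightDiff": np.diff(sel["peak_val"].to_numpy()),
        "PeakDistance": np.diff(sel["peak"].to_numpy()) / fs,
        "TroughDiff": np.diff(sel["onset_val"].to_numpy()),
    }
    # window means: signed series averaged as absolute magnitude for the
    # vertical pair differences (they are fluctuation magnitudes)
    for name in ("Amplitude", "Width", "RiseTime", "Skewness", "Kurtosis"):
        out[name] = float(np.mean(series[name]))
    out["PeakDistance"] = float(np.mean(series["PeakDistance"])) if series[
        "PeakDistance"
    ].size else np.nan
    for name in ("PeakHeightDiff", "TroughDiff"):
        out[name] = (
            float(np.mean(np.abs(series[name]))) if series[name].size else np.nan
        )
    for name in _BASE_NAMES:
        out[f"Change{name}"] = _mean_abs_diff(series[name])
        out[f"Std{name}"] = _sample_std(series[name])
    return out


# ---------------------------------------------------------------------------
# correlogram block
# ---------------------------------------------------------------------------

def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation of the mean-removed signal, normalized at lag 0."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return np.zeros(max_lag + 1)
    full = np.correlate(x, x, mode="full")
    r = full[x.size - 1 : x.size + max_lag]
    return r / denom


def correlogram_features(x_win: np.ndarray, fs: float, W: float) -> dict[str, float]:
    """F26-F29: value and lag (s) of the first two correlogram peaks.

    Lags run to min(4 s, W/2); the search starts at 0.25 s so the trivial
    lag-0 maximum (and sub-250 ms ripple above a 240 bpm ceiling) is
    skipped.  Missing peaks yield NaN.
    """
    max_lag = int(round(min(4.0, W / 2.0) * fs))
    r = autocorrelation(x_win, max_lag)
    min_lag = int(round(CORRELOGRAM_MIN_LAG_S * fs))
    peaks, _ = find_peaks(r)
    peaks = peaks[peaks >= min_lag]
    out = {
        "CorrelogramPeak1": np.nan,
        "CorrelogramPeak2": np.nan,
        "CorrelogramLag1": np.nan,
        "CorrelogramLag2": np.nan,
    }
    if peaks.size >= 1:
        out["CorrelogramPeak1"] = float(r[peaks[0]])
        out["CorrelogramLag1"] = peaks[0] / fs
    if peaks.size >= 2:
        out["CorrelogramPeak2"] = float(r[peaks[1]])
        out["CorrelogramLag2"] = peaks[1] / fs
    return out


# ---------------------------------------------------------------------------
# frequency-domain block
# ---------------------------------------------------------------------------

@dataclass
class Spectrogram:
    """Modified-periodogram spectrogram (10 s Hamming frames, 1 s hop).

    ``psd_db`` stores one-sided density-scaled power in dB/Hz floored at
    -120 dB; ``stft_real`` keeps the real part of each frame's spectrum
    for the spectral-kurtosis features.  ``times`` are frame centers.
    """

    freqs: np.ndarray
    times: np.ndarray
    psd_db: np.ndarray       # (freq, time)
    stft_real: np.ndarray    # (freq, time)
    frame_s: float = SPECTROGRAM_FRAME_S

    def psd_linear(self) -> np.ndarray:
        return 10.0 ** (self.psd_db / 10.0)


class TooShortError(ValueError):
    pass


def compute_spectrogram(rec: Recording) -> Spectrogram:
    """STFT spectrogram with 10 s Hamming frames hopped by 1 s (90% overlap)."""
    fs = rec.fs
    nper = int(round(SPECTROGRAM_FRAME_S * fs))
    hop = int(round(SPECTROGRAM_HOP_S * fs))
    x = rec.samples
    if x.size < nper:
        raise TooShortError("recording shorter than one 10 s spectrogram frame")
    win = get_window("hamming", nper)
    scale = 1.0 / (fs * float(np.dot(win, win)))
    starts = np.arange(0, x.size - nper + 1, hop)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    psd = np.empty((freqs.size, starts.size))
    stft_real = np.empty_like(psd)
    for j, s in enumerate(starts):
        frame = x[s : s + nper] * win
        X = np.fft.rfft(frame)
        p = scale * np.abs(X) ** 2
        p[1:] *= 2.0
        if nper % 2 == 0:
            p[-1] /= 2.0  # Nyquist bin is not doubled
        psd[:, j] = p
        stft_real[:, j] = X.real
    psd_db = 10.0 * np.log10(np.maximum(psd, 10.0 ** (DB_FLOOR / 10.0)))
    times = starts / fs + SPECTROGRAM_FRAME_S / 2.0
    return Spectrogram(freqs=freqs, times=times, psd_db=psd_db, stft_real=stft_real)


#: Edge tolerance for band masks: band limits fall exactly on grid bins
#: (0.1 Hz spacing at 75 Hz / 10 s frames), so raw comparisons would make
#: edge-bin inclusion an accident of floating-point rounding.
_BAND_EDGE_EPS = 1e-9


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo - _BAND_EDGE_EPS) & (freqs <= hi + _BAND_EDGE_EPS)


def band_entropy(P: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> float:
    """Normalized Shannon entropy of the band-restricted PSD distribution."""
    band = P[_band_mask(freqs, lo, hi)]
    total = band.sum()
    if band.size < 2 or total <= 0:
        return np.nan
    p = band / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(band.size))


def window_psd_features(
    spec: Spectrogram, start_s: float, W: float
) -> dict[str, float]:
    """F30-F41 from the mean in-window PSD (linear power domain).

    The window PSD is the mean over spectrogram frames whose centers fall
    inside ``[start, start+W)``.  Spectral kurtosis is the per-bin
    normalized fourth moment of the real STFT over those frames (falling
    back to all frames overlapping the window when fewer than 4 centers
    are inside), averaged over the band.
    """
    names = FEATURE_NAMES[29:41]
    centers_in = (spec.times >= start_s) & (spec.times < start_s + W)
    if not centers_in.any():
        warnings.warn(
            f"no spectrogram frame center inside window [{start_s}, {start_s + W})",
            stacklevel=2,
        )
        return {name: np.nan for name in names}
    P = spec.psd_linear()[:, centers_in].mean(axis=1)
    freqs = spec.freqs
    out: dict[str, float] = {}
    out["SpectralEntropy (0-1.5Hz)"] = band_entropy(P, freqs, *ENTROPY_BANDS[0])
    out["SpectralEntropy (1-4Hz)"] = band_entropy(P, freqs, *ENTROPY_BANDS[1])

    sk_frames = centers_in
    if int(centers_in.sum()) < 4:
        frame_start = spec.times - spec.frame_s / 2.0
        frame_end = spec.times + spec.frame_s / 2.0
        sk_frames = (frame_end > start_s) & (frame_start < start_s + W)
    R = spec.stft_real[:, sk_frames]
    m2 = np.mean(R**2, axis=1)
    m4 = np.mean(R**4, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sk = np.where(m2 > 0, m4 / m2**2, np.nan)
    for (lo, hi), name in zip(
        ENTROPY_BANDS, ["SpectralKurtosis (0-1.5Hz)", "SpectralKurtosis (1-4Hz)"]
    ):
        band = sk[_band_mask(freqs, lo, hi)]
        out[name] = float(np.nanmean(band)) if band.size else np.nan

    total = float(P.sum())
    for (lo, hi), name in zip(
        RELPOWER_BANDS, [f"RelativePower ({lo:g}-{hi:g}Hz)" for lo, hi in RELPOWER_BANDS]
    ):
        band = P[_band_mask(freqs, lo, hi)]
        out[name] = float(band.sum() / total) if total > 0 else np.nan
    for (lo, hi), name in zip(
        AVGPOWER_BANDS, [f"AvgPower ({lo:g}-{hi:g}Hz)" for lo, hi in AVGPOWER_BANDS]
    ):
        band = P[_band_mask(freqs, lo, hi)]
        out[name] = float(band.mean()) if band.size else np.nan
    return out


# ---------------------------------------------------------------------------
# envelope block
# ---------------------------------------------------------------------------

@dataclass
class Envelope:
    """Upper envelope of a windowed signal, one value per sample."""

    samples: np.ndarray
    knots: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flagged: bool = False  # True when < 2 local maxima were available


def extract_envelope(x_win: np.ndarray, fs: float) -> Envelope:
    """Cubic-spline upper envelope through local maxima >= 50 samples apart.

    Beyond the first/last knot the envelope extends as a constant; with
    fewer than two local maxima it degrades to a flagged constant at the
    single maximum (or the signal maximum).
    """
    x = np.asarray(x_win, dtype=float)
    peaks, _ = find_peaks(x, distance=ENVELOPE_MIN_SEPARATION)
    n = x.size
    if peaks.size < 2:
        level = float(x[peaks[0]]) if peaks.size == 1 else float(x.max())
        return Envelope(np.full(n, level), knots=peaks, flagged=True)
    spline = CubicSpline(peaks, x[peaks])
    idx = np.arange(n)
    env = spline(np.clip(idx, peaks[0], peaks[-1]))
    return Envelope(env, knots=peaks, flagged=False)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = Phi_m(r) - Phi_{m+1}(r), Chebyshev distance,
    self-matches included (Pincus convention).

    Default radius is ``0.2 * std(x)``; a constant input (r == 0)
    returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0 or x.size < m + 2:
        return 0.0

    def phi(mm: int) -> float:
        emb = sliding_window_view(x, mm)
        M = emb.shape[0]
        dist = np.abs(emb[:, None, 0] - emb[None, :, 0])
        for k in range(1, mm):
            np.maximum(dist, np.abs(emb[:, None, k] - emb[None, :, k]), out=dist)
        counts = (dist <= r).mean(axis=1)
        return float(np.mean(np.log(counts)))

    return phi(m) - phi(m + 1)


def envelope_features(env: Envelope, fs: float) -> dict[str, float]:
    """F42-F51 from the upper envelope.

    Band powers use the one-sided periodogram of the mean-removed
    envelope; the area is the trapezoidal integral of ``|env|`` over time
    (amplitude * s).
    """
    e = env.samples
    out: dict[str, float] = {}
    out["EnvelopeStd"] = _sample_std(e)
    out["EnvelopeMax"] = float(e.max())
    out["EnvelopeMin"] = float(e.min())
    out["EnvelopeRange"] = out["EnvelopeMax"] - out["EnvelopeMin"]
    out["EnvelopeApproxEntropy"] = approximate_entropy(e)
    out["EnvelopeArea"] = float(np.trapezoid(np.abs(e), dx=1.0 / fs))
    f, Pxx = periodogram(e - e.mean(), fs=fs, window="boxcar", scaling="density")
    for (lo, hi), name in zip(
        ENVPOWER_BANDS, [f"EnvelopeAvgPower ({lo:g}-{hi:g}Hz)" for lo, hi in ENVPOWER_BANDS]
    ):
        band = Pxx[_band_mask(f, lo, hi)]
        out[name] = float(band.mean()) if band.size else np.nan
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_feature_vector(
    rec: Recording,
    ppdf: pd.DataFrame,
    start_s: float,
    W: float,
    spec: Spectrogram,
) -> pd.Series:
    """Assemble all 51 features for the window ``[start, start+W)``.

    ``ppdf`` is the recording-level per-pulse table from
    :func:`per_pulse_features`; ``spec`` the recording-level spectrogram.
    Deterministic: identical inputs give identical vectors.
    """
    fs = rec.fs
    i0, i1 = int(round(start_s * fs)), int(round((start_s + W) * fs))
    x_win = rec.samples[i0:i1]
    values: dict[str, float] = {}
    values.update(aggregate_time_features(ppdf, start_s, W, rec))
    values.update(correlogram_features(x_win, fs, W))
    values.update(window_psd_features(spec, start_s, W))
    env = extract_envelope(x_win, fs)
    values.update(envelope_features(env, fs))
    return pd.Series([values[name] for name in FEATURE_NAMES], index=FEATURE_NAMES)
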