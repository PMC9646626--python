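"""Pulse segmentation: systolic peaks, onsets and offsets.

Peaks are local maxima of a 0.5-8 Hz zero-phase band-passed copy of the
signal, gated by a minimum inter-peak distance (60/max_rate s) and an
adaptive prominence threshold.  Each onset is the minimum of the *raw*
signal between the previous peak (or the recording start) and the current
peak; the offset of pulse i is the onset of pulse i+1, and the last
offset is the last local minimum after the last peak.  All indices refer
to the raw signal.  Pulses truncated by the recording edges are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .io import Recording, ValidationError


class TooShortError(ValueError):
    """Recording shorter than two beats at the minimum heart rate."""


@dataclass
class PulseSet:
    """Detected pulse anchors (raw-signal sample indices).

    Invariants: ``onsets[i] < peaks[i] <= offsets[i]`` and
    ``offsets[i] <= onsets[i+1]``; each array strictly increasing.
    """

    onsets: np.ndarray
    peaks: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.peaks = np.asarray(self.peaks, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        n = self.n_pulses
        if not (self.peaks.size == n and self.offsets.size == n):
            raise ValidationError("onsets/peaks/offsets must have equal length")
        if n == 0:
            return
        if not (
            np.all(self.onsets < self.peaks)
            and np.all(self.peaks <= self.offsets)
        ):
            raise ValidationError("require onsets[i] < peaks[i] <= offsets[i]")
        if n > 1:
            if not (
                np.all(np.diff(self.onsets) > 0)
                and np.all(np.diff(self.peaks) > 0)
                and np.all(np.diff(self.offsets) > 0)
            ):
                raise ValidationError("pulse index arrays must be strictly increasing")
            if not np.all(self.offsets[:-1] <= self.onsets[1:]):
                raise ValidationError("offset of pulse i must not pass onset of i+1")

    @property
    def n_pulses(self) -> int:
        return self.onsets.size

    @classmethod
    def empty(cls) -> "PulseSet":
        z = np.array([], dtype=int)
        return cls(z.copy(), z.copy(), z.copy())


def bandpass_pulse_band(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.5-8 Hz band-pass (below resting HR, above pulse harmonics)."""
    sos = butter(2, [0.5, 8.0], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def detect_pulses(
    rec: Recording, min_rate: float = 40.0, max_rate: float = 180.0
) -> PulseSet:
    """Detect pulse onsets/peaks/offsets in a normalized recording.

    Raises
    ------
    TooShortError
        If the recording cannot contain two beats at ``min_rate``.

    Returns an empty :class:`PulseSet` when no peak passes the gates
    (downstream NaN policy applies); never extrapolates edge pulses.
    """
    if not rec.normalized:
        raise ValidationError("detect_pulses requires a normalized recording")
    x = rec.samples
    fs = rec.fs
    if rec.duration < 2 * 60.0 / min_rate:
        raise TooShortError(
            f"recording {rec.recording_id!r} shorter than 2 beats at {min_rate} bpm"
        )
    filt = bandpass_pulse_band(x, fs)
    min_dist = max(1, int(round(fs * 60.0 / max_rate)))
    # adaptive prominence: a fraction of the filtered signal's spread
    prom = 0.5 * float(np.std(filt))
    peak_idx, _ = find_peaks(filt, distance=min_dist, prominence=prom)
    if peak_idx.size == 0:
        return PulseSet.empty()

    onsets = np.empty(peak_idx.size, dtype=int)
    prev = 0
    for k, pk in enumerate(peak_idx):
        lo = prev if k == 0 else peak_idx[k - 1]
        if pk <= lo + 1:
            onsets[k] = lo  # degenerate; filtered out below
        else:
            onsets[k] = lo + int(np.argmin(x[lo:pk]))
    # last offset: last local minimum after the last peak
    tail_minima, _ = find_peaks(-x[peak_idx[-1]:])
    keep = np.ones(peak_idx.size, dtype=bool)
    if tail_minima.size == 0:
        keep[-1] = False  # truncated by the recording edge: drop
        last_offset = None
    else:
        last_offset = peak_idx[-1] + int(tail_minima[-1])

    peaks = peak_idx[keep]
    onsets = onsets[keep]
    if peaks.size == 0:
        return PulseSet.empty()
    if last_offset is None:
        offsets = onsets[1:].copy()
        onsets, peaks = onsets[:-1], peaks[:-1]
    else:
        offsets = np.concatenate([onsets[1:], [last_offset]])
    if peaks.size == 0:
        return PulseSet.empty()

    # enforce invariants strictly: drop pulses violating onset < peak <= offset
    good = (onsets < peaks) & (peaks <= offsets)
    onsets, peaks, offsets = onsets[good], peaks[good], offsets[good]
    if peaks.size == 0:
        return PulseSet.empty()
    # strict monotonicity after any drops
    order = np.argsort(peaks)
    onsets, peaks, offsets = onsets[order], peaks[order], offsets[order]
    keep2 = np.ones(peaks.size, dtype=bool)
    for i in range(1, peaks.size):
        j = np.flatnonzero(keep2[:i])[-1]
        if onsets[i] <= onsets[j] or peaks[i] <= peaks[j] or offsets[i] <= offsets[j] \
                or onsets[i] < offsets[j]:
            keep2[i] = False
    return PulseSet(onsets[keep2], peaks[keep2], offsets[keep2])


def pulses_to_csv(pulses: PulseSet, path) -> None:
    """Debug dump: one ``onset,peak,offset`` row per pulse."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset", "peak", "offset"])
        for o, p, f in zip(pulses.onsets, pulses.peaks, pulses.offsets):
            writer.writerow([int(o), int(p), int(f)])
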