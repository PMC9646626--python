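"""Sliding-window segmentation, corruption-threshold labelling and
balanced feature-table assembly.

Windows of length W in {4,5,6,7,8,10} s slide along each recording in
2 s steps.  A window is positive when the fraction of its span covered by
positive-class annotation (artifact subtypes for the artifacts task,
apnea for the apnea task) reaches the corruption threshold Thd in
{20,30,40,50}%.  Overlap is computed in continuous seconds on half-open
intervals.

For the apnea task the classification universe is clean PPG only:
windows overlapping any artifact annotation are excluded outright, and
the feature table is restricted to the breath-hold recordings, whose
normal-breathing gaps supply the negative class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (
    FEATURE_NAMES,
    compute_spectrogram,
    extract_feature_vector,
    per_pulse_features,
)
from .io import AnnotationSegment, Cohort, Recording, ValidationError, normalize_recording
from .pulses import detect_pulses

logger = logging.getLogger(__name__)

WINDOW_LENGTHS = (4, 5, 6, 7, 8, 10)
CORRUPTION_THRESHOLDS = (0.20, 0.30, 0.40, 0.50)
WINDOW_SHIFT_S = 2.0

TASKS = ("artifacts", "apnea")

#: Sentinel for apnea-task windows excluded for overlapping an artifact.
EXCLUDED = "excluded"


@dataclass(frozen=True)
class Window:
    """One analysis window ``[start, start + length)`` of a recording."""

    recording_id: str
    start: float
    length: float
    index: int


@dataclass(frozen=True)
class LabelledWindow:
    window: Window
    task: str
    label: int  # +1 positive, -1 negative
    corrupt_fraction: float


def segment_windows(rec: Recording, W: float, shift: float = WINDOW_SHIFT_S) -> list[Window]:
    """Windows starting at 0, shift, 2*shift, ... while start + W <= duration."""
    if W > rec.duration:
        raise ValidationError(
            f"window length {W} s exceeds recording duration {rec.duration} s"
        )
    n = int(np.floor((rec.duration - W) / shift)) + 1
    return [
        Window(rec.recording_id, start=i * shift, length=float(W), index=i)
        for i in range(n)
    ]


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    """Length of the intersection of half-open intervals [a0,a1) and [b0,b1)."""
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_window(
    w: Window,
    annotations: list[AnnotationSegment],
    task: str,
    thd: float,
) -> LabelledWindow | str:
    """Assign the window to the positive class iff its corrupt fraction
    reaches ``thd``.

    Positive sets: artifacts task -> any artifact subtype; apnea task ->
    apnea.  Apnea-task windows overlapping any artifact return the
    :data:`EXCLUDED` sentinel (clean-PPG-only universe).
    """
    if task not in TASKS:
        raise ValidationError(f"unknown task {task!r}")
    w0, w1 = w.start, w.start + w.length
    positive_overlap = 0.0
    for seg in annotations:
        ov = _overlap(w0, w1, seg.onset, seg.offset)
        if ov <= 0.0:
            continue
        if task == "apnea" and seg.is_artifact():
            return EXCLUDED
        if task == "artifacts" and seg.is_artifact():
            positive_overlap += ov
        elif task == "apnea" and seg.label == "apnea":
            positive_overlap += ov
    frac = positive_overlap / w.length
    label = 1 if frac >= thd else -1
    return LabelledWindow(window=w, task=task, label=label, corrupt_fraction=frac)


def extract_recording_features(rec: Recording, W: float) -> pd.DataFrame:
    """All window feature vectors for one recording at window length W.

    Normalizes the recording if needed, detects pulses, computes the
    spectrogram once, then assembles the 51-feature vector per window.
    Columns: subject, recording, window_start_s, W, F1..F51 glossary names.
    """
    if not rec.normalized:
        rec = normalize_recording(rec)
    pulses = detect_pulses(rec)
    ppdf = per_pulse_features(rec, pulses)
    spec = compute_spectrogram(rec)
    windows = segment_windows(rec, W)
    rows = []
    for w in windows:
        vec = extract_feature_vector(rec, ppdf, w.start, w.length, spec)
        row = {
            "subject": rec.subject_id,
            "recording": rec.recording_id,
            "window_start_s": w.start,
            "W": W,
        }
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort_features(
    cohort: Cohort, W: float, recordings: list[str] | None = None
) -> pd.DataFrame:
    """Stacked window-feature table for (a subset of) the cohort.

    Feature extraction is label-free, so one table per (cohort, W) is
    reused across tasks, thresholds and experiment repetitions.
    """
    frames = []
    for rec in cohort.recordings:
        if recordings is not None and rec.recording_id not in recordings:
            continue
        frames.append(extract_recording_features(rec, W))
    return pd.concat(frames, ignore_index=True)


def label_cohort_windows(
    cohort: Cohort, task: str, W: float, thd: float,
    recordings: list[str] | None = None,
) -> pd.DataFrame:
    """Labels and corrupt fractions for every (non-excluded) window."""
    rows = []
    n_excluded = 0
    for rec in cohort.recordings:
        if recordings is not None and rec.recording_id not in recordings:
            continue
        annotations = cohort.annotations[rec.recording_id]
        for w in segment_windows(rec, W):
            lw = label_window(w, annotations, task, thd)
            if lw == EXCLUDED:
                n_excluded += 1
                continue
            rows.append(
                {
                    "subject": rec.subject_id,
                    "recording": rec.recording_id,
                    "window_start_s": w.start,
                    "label": lw.label,
                    "corrupt_fraction": lw.corrupt_fraction,
                }
            )
    if n_excluded:
        logger.info(
            "excluded %d %s-task windows overlapping artifacts", n_excluded, task
        )
    return pd.DataFrame(rows)


def build_feature_table(
    cohort: Cohort,
    task: str,
    W: float,
    thd: float,
    seed: int,
    features: pd.DataFrame | None = None,
    max_per_class: int | None = None,
) -> pd.DataFrame:
    """Balanced labelled feature table for one task / W / Thd combination.

    Joins labels onto window features, drops NaN rows (logged),
    downsamples the majority class uniformly at random (seeded) to
    equality, optionally capping both classes at ``max_per_class``.
    Grouping keys (subject, recording, window_start_s) are preserved for
    subject-safe partitioning.

    For the apnea task only breath-hold recordings participate; their
    normal-breathing gaps supply the negatives.
    """
    if task == "apnea":
        rec_ids = [r.recording_id for r in cohort.by_scenario("breath_hold")]
    else:
        rec_ids = None
    if features is None:
        features = extract_cohort_features(cohort, W, recordings=rec_ids)
    labels = label_cohort_windows(cohort, task, W, thd, recordings=rec_ids)
    table = features.merge(
        labels, on=["subject", "recording", "window_start_s"], how="inner"
    )
    n_before = len(table)
    table = table.dropna(subset=FEATURE_NAMES).reset_index(drop=True)
    if len(table) < n_before:
        logger.info(
            "dropped %d windows with NaN features (task=%s W=%s Thd=%s)",
            n_before - len(table), task, W, thd,
        )
    pos = table[table["label"] == 1]
    neg = table[table["label"] == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError(
            f"empty class after labelling (task={task}, W={W}, Thd={thd}): "
            f"{len(pos)} positive, {len(neg)} negative windows"
        )
    n = min(len(pos), len(neg))
    if max_per_class is not None:
        n = min(n, max_per_class)
    rng = np.random.default_rng(seed)
    pos_idx = np.sort(rng.choice(pos.index.to_numpy(), size=n, replace=False))
    neg_idx = np.sort(rng.choice(neg.index.to_numpy(), size=n, replace=False))
    out = table.loc[np.concatenate([pos_idx, neg_idx])].reset_index(drop=True)
    out["task"] = task
    out["Thd"] = thd
    return out
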