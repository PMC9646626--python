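"""Domain types and file I/O for neck-PPG recordings and annotations.

A :class:`Recording` is one subject's single-channel PPG trace (default
75 Hz).  Ground truth comes as :class:`AnnotationSegment` intervals in
seconds; gaps between segments are implicitly ``normal``.  A
:class:`Cohort` bundles recordings with their annotation tables.

Interchange formats are deliberately plain: a sample CSV (``t,ppg`` or a
single ``ppg`` column) with a JSON metadata sidecar, and an annotation CSV
with header ``onset,offset,label``.  Floats are serialized with
``repr``-level precision so that save/load round-trips bit-for-bat.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Artifact subtypes characterized for the neck PPG site.
ARTIFACT_SUBTYPES = (
    "fast_breathing",
    "talking",
    "head_movement",
    "body_movement",
    "swallowing",
    "coughing",
    "yawning",
    "sensor_rubbing",
)

#: Non-artifact (clean PPG) labels.
CLEAN_LABELS = ("normal", "slow_breathing", "apnea")

SCENARIOS = ("control", "slow_breathing", "breath_hold") + tuple(
    f"artifact_{s}" for s in ARTIFACT_SUBTYPES
)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the offending row."""


class DegenerateSignalError(ValueError):
    """Raised for constant (zero-variance) signals."""


def _is_artifact_label(label: str) -> bool:
    return label.startswith("artifact_") or label in ARTIFACT_SUBTYPES


@dataclass
class Recording:
    """A single-channel PPG recording.

    Parameters
    ----------
    subject_id, recording_id : str
        Grouping keys; all recordings of a subject travel together in
        subject-safe partitions.
    scenario : str
        One of ``control``, ``slow_breathing``, ``breath_hold`` or
        ``artifact_<subtype>``.
    fs : float
        Sampling rate in Hz (protocol default 75).
    samples : ndarray
        Amplitude sequence, arbitrary units.
    normalized : bool
        Whether samples are per-recording z-scored.
    """

    subject_id: str
    recording_id: str
    scenario: str
    fs: float
    samples: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.samples.size < 2 * self.fs:
            raise ValidationError(
                f"recording {self.recording_id!r} must span at least 2 s "
                f"({int(2 * self.fs)} samples), got {self.samples.size}"
            )
        if self.normalized:
            if abs(float(np.mean(self.samples))) > 1e-9:
                raise ValidationError("normalized recording must have mean ~0")
            if abs(float(np.std(self.samples)) - 1.0) > 1e-9:
                raise ValidationError("normalized recording must have std ~1")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    def __eq__(self, other: object) -> bool:  # samples compared by value
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.recording_id == other.recording_id
            and self.scenario == other.scenario
            and self.fs == other.fs
            and self.normalized == other.normalized
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class AnnotationSegment:
    """Half-open ground-truth interval ``[onset, offset)`` in seconds."""

    onset: float
    offset: float
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValidationError(
                f"segment must satisfy 0 <= onset < offset, got "
                f"[{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def is_artifact(self) -> bool:
        return _is_artifact_label(self.label)


@dataclass
class Cohort:
    """A multi-subject collection of annotated recordings."""

    recordings: list[Recording]
    annotations: dict[str, list[AnnotationSegment]]
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subjects:
            seen: dict[str, None] = {}
            for rec in self.recordings:
                seen.setdefault(rec.subject_id, None)
            self.subjects = list(seen)
        for rec in self.recordings:
            if rec.recording_id not in self.annotations:
                raise ValidationError(
                    f"recording {rec.recording_id!r} has no annotation list"
                )
            if rec.subject_id not in self.subjects:
                raise ValidationError(
                    f"subject {rec.subject_id!r} missing from cohort subjects"
                )

    def recording(self, recording_id: str) -> Recording:
        for rec in self.recordings:
            if rec.recording_id == recording_id:
                return rec
        raise KeyError(recording_id)

    def by_scenario(self, scenario: str) -> list[Recording]:
        return [r for r in self.recordings if r.scenario == scenario]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as ``<path>`` CSV plus a ``.json`` metadata sidecar.

    The CSV holds a single ``ppg`` column with repr-precision floats, so
    :func:`load_recording` inverts it bit-for-bit.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ppg"])
        for v in rec.samples:
            writer.writerow([repr(float(v))])
    meta = {
        "subject_id": rec.subject_id,
        "recording_id": rec.recording_id,
        "scenario": rec.scenario,
        "fs": rec.fs,
        "normalized": rec.normalized,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_recording(path: str | Path) -> Recording:
    """Read a recording CSV (``t,ppg`` or ``ppg``) and its JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        header = [h.strip() for h in header]
        if header == ["ppg"]:
            col = 0
        elif header == ["t", "ppg"]:
            col = 1
        else:
            raise ParseError(f"unrecognized header {header!r} in {path}")
        samples = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                samples.append(float(row[col]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"non-numeric sample in {path} row {i}") from exc
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    fs = meta.get("fs", 75.0)
    if fs <= 0:
        raise ValidationError(f"fs must be > 0, got {fs} in {sidecar}")
    return Recording(
        subject_id=meta.get("subject_id", path.stem),
        recording_id=meta.get("recording_id", path.stem),
        scenario=meta.get("scenario", "control"),
        fs=fs,
        samples=np.array(samples),
        normalized=meta.get("normalized", False),
    )


def save_annotations(segments: list[AnnotationSegment], path: str | Path) -> None:
    """Write an ``onset,offset,label`` CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset", "offset", "label"])
        for seg in segments:
            writer.writerow([repr(float(seg.onset)), repr(float(seg.offset)), seg.label])


def load_annotations(path: str | Path) -> list[AnnotationSegment]:
    """Read, validate and onset-sort an annotation CSV.

    Raises
    ------
    ValidationError
        If two segments overlap (the message names the pair) or a segment
        has ``offset <= onset``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = [h.strip() for h in next(reader)]
        if header != ["onset", "offset", "label"]:
            raise ParseError(f"unrecognized header {header!r} in {path}")
        segments = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                onset, offset = float(row[0]), float(row[1])
            except ValueError as exc:
                raise ParseError(f"non-numeric onset/offset in {path} row {i}") from exc
            segments.append(AnnotationSegment(onset, offset, row[2].strip()))
    return sort_and_validate_segments(segments)


def sort_and_validate_segments(
    segments: list[AnnotationSegment],
) -> list[AnnotationSegment]:
    """Sort segments by onset and reject overlaps between half-open intervals."""
    segments = sorted(segments, key=lambda s: s.onset)
    for a, b in zip(segments, segments[1:]):
        if b.onset < a.offset:
            raise ValidationError(
                f"overlapping segments [{a.onset}, {a.offset}) {a.label!r} and "
                f"[{b.onset}, {b.offset}) {b.label!r}"
            )
    return segments


def normalize_recording(rec: Recording) -> Recording:
    """Return a copy with per-recording z-scored samples.

    Each recording is normalized independently so that amplitude features
    are comparable across subjects and sensors, and zero-crossing counts
    are meaningful around 0.

    Raises
    ------
    ValidationError
        If the recording is already normalized (idempotence guard).
    DegenerateSignalError
        If the signal is constant (zero standard deviation).
    """
    if rec.normalized:
        raise ValidationError("recording is already normalized")
    std = float(np.std(rec.samples))
    if std == 0.0:
        raise DegenerateSignalError(
            f"recording {rec.recording_id!r} is constant; cannot normalize"
        )
    z = (rec.samples - np.mean(rec.samples)) / std
    return replace(rec, samples=z, normalized=True)
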