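"""Readers and writers for every external file the pipeline touches.

Annotation label tracks use the plain-text export dialect of common audio
editors: one record per line, ``start<TAB>end<TAB>label``, times in seconds
from the recording origin with 6-decimal fixed-point formatting.  Lines
beginning with a backslash (the frequency-range continuation of that
dialect) are skipped.  The label text encodes a 0-3 annotation tier as its
first integer token; annotators may append free text after the digit.

Detector logs are delimited text with a ``device_id,timestamp,score``
header, one row per detected explosive sound.  Session manifests are YAML.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "AnnotationLabel",
    "Detection",
    "SessionManifest",
    "read_label_track",
    "write_label_track",
    "read_detections",
    "write_detections",
    "read_manifest",
    "write_manifest",
]

_TIER_RE = re.compile(r"[-+]?\d+")


@dataclass(frozen=True)
class AnnotationLabel:
    """One annotator's tiered label (point or interval) on the session timeline.

    Tiers: 0 definitely not a cough, 1 disputable, 2 definite but
    distant/muffled, 3 definite cough.  Point labels have ``end == start``.
    """

    annotator_id: str
    start: float
    end: float
    tier: int
    raw_text: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"label start must be non-negative, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"label end {self.end} precedes start {self.start}")
        if self.tier not in (0, 1, 2, 3):
            raise ValueError(f"tier must be in 0..3, got {self.tier}")

    @property
    def is_point(self) -> bool:
        return self.end == self.start


@dataclass(frozen=True)
class Detection:
    """One detector event: device, timestamp (device clock), prediction score."""

    device_id: str
    timestamp: float
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass
class SessionManifest:
    """Links one recording session to its annotator and device files.

    The consensus rule assumes exactly three annotators per session.
    """

    session_id: str
    participant_id: str
    script_version: int
    duration: float
    label_paths: dict[str, str]  # annotator_id -> path
    detection_paths: dict[str, str] = field(default_factory=dict)  # device_id -> path

    def __post_init__(self) -> None:
        if len(self.label_paths) != 3:
            raise ValueError(
                f"session {self.session_id}: exactly three annotators required, "
                f"got {len(self.label_paths)}"
            )
        if len(self.detection_paths) < 1:
            raise ValueError(f"session {self.session_id}: at least one device required")
        if self.duration <= 0:
            raise ValueError(f"session {self.session_id}: duration must be positive")
        if not 1 <= int(self.script_version) <= 5:
            raise ValueError(
                f"session {self.session_id}: script_version must be 1..5, "
                f"got {self.script_version}"
            )


def _parse_tier(text: str, path: Path, lineno: int) -> int:
    m = _TIER_RE.search(text)
    if m is None:
        raise ValueError(f"{path}:{lineno}: no tier digit in label text {text!r}")
    tier = int(m.group())
    if tier not in (0, 1, 2, 3):
        raise ValueError(f"{path}:{lineno}: tier {tier} outside 0..3 in {text!r}")
    return tier


def read_label_track(path: str | Path, annotator_id: str | None = None) -> list[AnnotationLabel]:
    """Read one annotator's label track, sorted ascending by start time.

    Unparseable lines raise :class:`ValueError` naming the line number;
    they are never silently dropped.  An empty file is a valid empty track.
    """
    path = Path(path)
    if annotator_id is None:
        annotator_id = path.stem
    labels: list[AnnotationLabel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("\\"):
                continue  # frequency-range continuation line
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable time field: {exc}") from None
            raw_text = "\t".join(fields[2:])
            tier = _parse_tier(raw_text, path, lineno)
            try:
                labels.append(
                    AnnotationLabel(annotator_id, start, end, tier, raw_text)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    labels.sort(key=lambda lab: (lab.start, lab.end))
    return labels


def write_label_track(labels: Iterable[AnnotationLabel], path: str | Path) -> None:
    """Write labels in the tab-separated track format (6-decimal times)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for lab in labels:
            text = lab.raw_text if lab.raw_text else str(lab.tier)
            fh.write(f"{lab.start:.6f}\t{lab.end:.6f}\t{text}\n")


def read_detections(path: str | Path) -> list[Detection]:
    """Read a detector log, sorted ascending by timestamp.

    Expects a ``device_id,timestamp,score`` header.  Scores outside [0, 1]
    and malformed rows raise :class:`ValueError` naming the line number.
    """
    path = Path(path)
    detections: list[Detection] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return []
        expected = ["device_id", "timestamp", "score"]
        if [h.strip() for h in header] != expected:
            raise ValueError(f"{path}:1: expected header {','.join(expected)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            device_id = row[0].strip()
            try:
                timestamp, score = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable field: {exc}") from None
            try:
                detections.append(Detection(device_id, timestamp, score))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    detections.sort(key=lambda d: d.timestamp)
    return detections


def write_detections(detections: Iterable[Detection], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["device_id", "timestamp", "score"])
        for det in detections:
            writer.writerow([det.device_id, f"{det.timestamp:.6f}", f"{det.score:.6f}"])


def read_manifest(path: str | Path) -> list[SessionManifest]:
    """Read a YAML session manifest; relative file paths resolve against it."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "sessions" not in doc:
        raise ValueError(f"{path}: manifest must be a mapping with a 'sessions' list")
    base = path.parent
    manifests = []
    for entry in doc["sessions"]:
        manifests.append(
            SessionManifest(
                session_id=str(entry["session_id"]),
                participant_id=str(entry["participant_id"]),
                script_version=int(entry["script_version"]),
                duration=float(entry["duration"]),
                label_paths={
                    str(k): str(base / v) for k, v in entry["labels"].items()
                },
                detection_paths={
                    str(k): str(base / v) for k, v in entry["detections"].items()
                },
            )
        )
    return manifests


def write_manifest(
    manifests: Sequence[SessionManifest], path: str | Path
) -> None:
    """Write a session manifest; paths are stored relative to the manifest."""
    path = Path(path)
    base = path.parent

    def _rel(p: str) -> str:
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    doc = {
        "sessions": [
            {
                "session_id": m.session_id,
                "participant_id": m.participant_id,
                "script_version": int(m.script_version),
                "duration": float(m.duration),
                "labels": {k: _rel(v) for k, v in sorted(m.label_paths.items())},
                "detections": {k: _rel(v) for k, v in sorted(m.detection_paths.items())},
            }
            for m in manifests
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
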