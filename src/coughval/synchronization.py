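"""Clock alignment of detector event streams to the annotation timeline.

Detector clocks and the continuous recorder start independently, so each
device in each session carries an unknown offset (convention: detector
timestamp + offset = annotation time).  The offset is estimated by grid
search: for each candidate the cough-like labels (tier >= 1) are matched
one-to-one to shifted detections within a tolerance (default 2 s, safe
because scripted sounds are separated by >= 5 s of silence), and the
candidate minimizing a match-error is chosen.

The match-error is the unmatched fraction plus a residual term smaller
than one unmatched event, so that within the plateau of equal match counts
the candidate with the tightest alignment wins:

    error = (n_unmatched + mean|residual| / tolerance) / max(#labels, #detections)

The grid argmin is then refined below the grid step by shifting it by the
mean signed residual of the matched pairs.  Sessions whose best error
exceeds 0.5 (fewer than half the events matchable) are flagged
unsynchronizable and excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .gold_standard import DEFAULT_MERGE_GAP, cluster_events
from .io_formats import AnnotationLabel, Detection

__all__ = [
    "OffsetEstimate",
    "offset_error",
    "estimate_offset",
    "apply_offset",
    "cough_like_times",
    "DEFAULT_GRID",
    "DEFAULT_TOLERANCE",
]

DEFAULT_GRID = (-60.0, 60.0, 0.1)
DEFAULT_TOLERANCE = 2.0
MAX_SYNC_ERROR = 0.5


@dataclass(frozen=True)
class OffsetEstimate:
    """Per-device, per-session clock offset (detector time + offset = annotation time)."""

    session_id: str
    device_id: str
    offset: float
    error: float
    method: str = "automatic"  # or "manual_override"
    search_grid: tuple[float, float, float] = DEFAULT_GRID
    synchronizable: bool = True

    def __post_init__(self) -> None:
        lo, hi, _ = self.search_grid
        if self.synchronizable and not lo <= self.offset <= hi:
            raise ValueError(f"offset {self.offset} outside search grid [{lo}, {hi}]")
        if self.error < 0:
            raise ValueError("match error cannot be negative")

    @classmethod
    def manual(
        cls, session_id: str, device_id: str, offset: float,
        search_grid: tuple[float, float, float] = DEFAULT_GRID,
    ) -> "OffsetEstimate":
        """Record a manually reviewed/overridden offset."""
        return cls(session_id, device_id, offset, error=0.0,
                   method="manual_override", search_grid=search_grid)


def _reference_times(labels) -> list[float]:
    """Cough-like label start times, or the input itself if already times."""
    out = []
    for lab in labels:
        if isinstance(lab, AnnotationLabel):
            if lab.tier >= 1:
                out.append(lab.start)
        else:
            out.append(float(lab))
    out.sort()
    return out


def cough_like_times(
    labels_by_annotator: Mapping[str, Sequence[AnnotationLabel]],
    merge_gap: float = DEFAULT_MERGE_GAP,
) -> list[float]:
    """Representative times of cough-like sounds pooled across annotators.

    All annotators' tier>=1 labels are clustered (merge gap) so the same
    sound marked by all three contributes one reference time.
    """
    times: list[float] = []
    for labels in labels_by_annotator.values():
        times.extend(lab.start for lab in labels if lab.tier >= 1)
    return [c[0] for c in cluster_events(times, merge_gap)]


def _greedy_match(
    ref: Sequence[float], shifted: Sequence[float], tolerance: float
) -> list[tuple[float, float]]:
    """One-to-one greedy matching in time order between two sorted streams."""
    pairs = []
    i = j = 0
    while i < len(ref) and j < len(shifted):
        d = shifted[j] - ref[i]
        if abs(d) <= tolerance:
            pairs.append((ref[i], shifted[j]))
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    return pairs


def _detection_times(
    detections: Sequence[Detection], score_threshold: float | None
) -> list[float]:
    if score_threshold is None:
        return [d.timestamp for d in detections]
    return [d.timestamp for d in detections if d.score >= score_threshold]


def offset_error(
    labels,
    detections: Sequence[Detection],
    candidate_offset: float,
    tolerance: float = DEFAULT_TOLERANCE,
    score_threshold: float | None = None,
) -> float:
    """Match-error of one candidate offset; 0 is perfect, 1 is no matches.

    ``labels`` may be annotation labels (tier >= 1 used) or raw reference
    times.  With ``score_threshold`` only detections scoring at least that
    value take part (aligning classified coughs, not every logged sound).
    Raises if there is nothing on either side to match.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ref = _reference_times(labels)
    det = sorted(t + candidate_offset for t in _detection_times(detections, score_threshold))
    denom = max(len(ref), len(det))
    if denom == 0:
        raise ValueError("offset error undefined: no cough-like labels and no detections")
    pairs = _greedy_match(ref, det, tolerance)
    if pairs:
        mean_abs = sum(abs(b - a) for a, b in pairs) / len(pairs)
        residual = mean_abs / tolerance
    else:
        residual = 0.0
    return (denom - len(pairs) + residual) / denom


def estimate_offset(
    labels,
    detections: Sequence[Detection],
    grid: tuple[float, float, float] = DEFAULT_GRID,
    tolerance: float = DEFAULT_TOLERANCE,
    session_id: str = "",
    device_id: str = "",
    refine: bool = True,
    max_error: float = MAX_SYNC_ERROR,
    score_threshold: float | None = None,
) -> OffsetEstimate:
    """Grid-search the offset minimizing :func:`offset_error`.

    Ties break toward the smallest |offset|, then toward the negative side.
    With ``refine`` the grid argmin is shifted by the mean signed residual
    of its matched pairs (clamped to the grid), giving sub-grid accuracy.
    An empty stream or a best error above ``max_error`` flags the device as
    unsynchronizable.
    """
    lo, hi, step = grid
    if hi < lo or step <= 0:
        raise ValueError(f"invalid search grid {grid}")
    if device_id == "" and detections:
        device_id = detections[0].device_id
    ref = _reference_times(labels)
    det_times = sorted(_detection_times(detections, score_threshold))
    if not ref or not det_times:
        return OffsetEstimate(session_id, device_id, 0.0, 1.0,
                              search_grid=grid, synchronizable=False)
    n = int(round((hi - lo) / step)) + 1
    candidates = lo + step * np.arange(n)
    best_off, best_err = None, math.inf
    for off in candidates:
        err = offset_error(ref, detections, off, tolerance, score_threshold)
        if err < best_err or (
            err == best_err
            and (abs(off) < abs(best_off) or (abs(off) == abs(best_off) and off < best_off))
        ):
            best_off, best_err = float(off), err

    if refine:
        pairs = _greedy_match(ref, [t + best_off for t in det_times], tolerance)
        if pairs:
            shift = sum(a - b for a, b in pairs) / len(pairs)
            refined = min(max(best_off + shift, lo), hi)
            err = offset_error(ref, detections, refined, tolerance, score_threshold)
            if err <= best_err:
                best_off, best_err = refined, err

    return OffsetEstimate(
        session_id, device_id, best_off, best_err,
        search_grid=grid, synchronizable=best_err <= max_error,
    )


def apply_offset(
    detections: Sequence[Detection], estimate: OffsetEstimate
) -> list[Detection]:
    """Shift detector timestamps onto the annotation timeline."""
    if not estimate.synchronizable:
        raise ValueError(
            f"session {estimate.session_id} device {estimate.device_id}: "
            "cannot apply an unsynchronizable offset estimate"
        )
    return [replace(d, timestamp=d.timestamp + estimate.offset) for d in detections]
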