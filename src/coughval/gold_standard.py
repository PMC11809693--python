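"""Per-second gold standard from three annotators, plus detection pooling.

The evaluation treats every second of a session that contains at least one
annotation as an analysis unit.  A second is a true cough only when all
three annotators gave tier 3 ("definite cough"); a second where every label
is tier 0 is a non-cough second; anything else reflects annotator
disagreement and is excluded from contingency counting.

Labels closer than the merge gap (default 1 s) are treated as a single
sound: they are clustered greedily in time order and each cluster is
assigned the second containing its first member.  Detections are pooled
within one-second bins, keeping the maximum prediction score per bin.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import AnnotationLabel, Detection

__all__ = [
    "GoldClass",
    "DeviceSecond",
    "AnalysisSecond",
    "SessionQC",
    "ExclusionReason",
    "cluster_events",
    "merge_events_to_seconds",
    "pool_detections",
    "annotator_tier_map",
    "consensus_classify",
    "build_analysis_seconds",
    "session_qc",
]

DEFAULT_MERGE_GAP = 1.0
DEFAULT_SCORE_THRESHOLD = 0.85
DEFAULT_MIN_COUGHS = 10


class GoldClass(enum.Enum):
    TRUE_COUGH = "TRUE_COUGH"
    NON_COUGH = "NON_COUGH"
    DISPUTED = "DISPUTED"
    COUGH_LIKE_NONCONSENSUS = "COUGH_LIKE_NONCONSENSUS"

    @property
    def in_contingency(self) -> bool:
        """Disagreement seconds are excluded from contingency counting."""
        return self in (GoldClass.TRUE_COUGH, GoldClass.NON_COUGH)


class ExclusionReason(enum.Enum):
    NONE = "none"
    SYNC_FAILURE = "sync_failure"
    TOO_FEW_COUGHS = "too_few_coughs"


@dataclass(frozen=True)
class DeviceSecond:
    """One device's detection state within a single analysis second."""

    detected: bool
    max_score: Optional[float] = None


@dataclass
class AnalysisSecond:
    """A one-second analysis unit: gold class plus per-device detection state."""

    session_id: str
    second_index: int
    gold_class: GoldClass
    devices: dict[str, DeviceSecond] = field(default_factory=dict)


@dataclass
class SessionQC:
    """Session-level quality decision.

    A session enters the evaluation only if its device clocks could be
    synchronized and it holds at least ``min_coughs`` unanimous cough-seconds.
    """

    session_id: str
    n_unanimous_coughs: int
    n_disputed_seconds: int
    synchronizable: bool
    included: bool
    exclusion_reason: ExclusionReason


def cluster_events(times: Sequence[float], merge_gap: float = DEFAULT_MERGE_GAP) -> list[list[float]]:
    """Greedy time-order clustering: a new cluster starts when the gap from
    the previous event is >= ``merge_gap``.  Input need not be sorted."""
    ts = sorted(times)
    clusters: list[list[float]] = []
    for t in ts:
        if clusters and t - clusters[-1][-1] < merge_gap:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    return clusters


def merge_events_to_seconds(
    times: Sequence[float], merge_gap: float = DEFAULT_MERGE_GAP
) -> set[int]:
    """Cluster events and return the second index of each cluster's first member."""
    return {int(math.floor(c[0])) for c in cluster_events(times, merge_gap)}


def _overlap_seconds(start: float, end: float) -> range:
    """Seconds (half-open bins [s, s+1)) overlapped by [start, end]."""
    first = int(math.floor(start))
    if end <= start:
        return range(first, first + 1)
    last = int(math.floor(end))
    if end == last and last > first:
        last -= 1  # interval ends exactly on a bin boundary
    return range(first, last + 1)


def annotator_tier_map(
    labels: Iterable[AnnotationLabel], merge_gap: float = DEFAULT_MERGE_GAP
) -> dict[int, int]:
    """One annotator's effective tier per second.

    Point labels of tier >= 1 are merged (within ``merge_gap``) into single
    sounds assigned to the second of the cluster's first label; tier-0 point
    labels mark their own second; interval labels contribute to every second
    they overlap.  Multiple contributions to a second take the maximum tier.
    """
    tiers: dict[int, int] = {}

    def _bump(sec: int, tier: int) -> None:
        tiers[sec] = max(tiers.get(sec, 0), tier)

    coughlike_points: list[AnnotationLabel] = []
    for lab in labels:
        if lab.is_point and lab.tier >= 1:
            coughlike_points.append(lab)
        elif lab.is_point:
            _bump(int(math.floor(lab.start)), lab.tier)
        else:
            for sec in _overlap_seconds(lab.start, lab.end):
                _bump(sec, lab.tier)

    if coughlike_points:
        coughlike_points.sort(key=lambda lab: lab.start)
        times = [lab.start for lab in coughlike_points]
        by_time = {lab.start: lab.tier for lab in coughlike_points}
        for cluster in cluster_events(times, merge_gap):
            sec = int(math.floor(cluster[0]))
            _bump(sec, max(by_time[t] for t in cluster))
    return tiers


def _classify_tiers(tiers: Sequence[Optional[int]]) -> GoldClass:
    """Consensus rule over the three annotators' effective tiers for a second.

    ``None`` means the annotator placed no label there; in a cough-like
    second that counts as tier 0, i.e. disagreement.
    """
    present = [t for t in tiers if t is not None]
    if not present:
        raise ValueError("second outside the analysis universe (no labels)")
    effective = [0 if t is None else t for t in tiers]
    if len(effective) != 3:
        raise ValueError(f"consensus rule assumes three annotators, got {len(effective)}")
    if all(t == 3 for t in effective):
        return GoldClass.TRUE_COUGH
    if all(t == 0 for t in present):
        return GoldClass.NON_COUGH
    if effective[0] == effective[1] == effective[2]:
        return GoldClass.COUGH_LIKE_NONCONSENSUS
    return GoldClass.DISPUTED


def consensus_classify(
    labels_by_annotator: Mapping[str, Sequence[AnnotationLabel]],
    second_index: int,
    merge_gap: float = DEFAULT_MERGE_GAP,
) -> GoldClass:
    """Gold class of one second from three annotators' label tracks."""
    if len(labels_by_annotator) != 3:
        raise ValueError("consensus rule assumes exactly three annotators")
    tiers = [
        annotator_tier_map(labels, merge_gap).get(second_index)
        for labels in labels_by_annotator.values()
    ]
    return _classify_tiers(tiers)


def pool_detections(
    detections: Iterable[Detection],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> dict[int, DeviceSecond]:
    """Pool offset-corrected detections into per-second detection state.

    All detections within a one-second bin are treated as a single
    detection-second whose score is the maximum member score; the second
    counts as detected when that score reaches the threshold (inclusive).
    """
    out: dict[int, float] = {}
    for det in detections:
        sec = int(math.floor(det.timestamp))
        if sec not in out or det.score > out[sec]:
            out[sec] = det.score
    return {
        sec: DeviceSecond(detected=score >= threshold, max_score=score)
        for sec, score in out.items()
    }


def build_analysis_seconds(
    session_id: str,
    labels_by_annotator: Mapping[str, Sequence[AnnotationLabel]],
    detections_by_device: Mapping[str, Sequence[Detection]],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    merge_gap: float = DEFAULT_MERGE_GAP,
) -> tuple[list[AnalysisSecond], dict[str, int]]:
    """Assemble the evaluable per-second dataset for one session.

    Returns the analysis seconds (the universe: every second holding at
    least one annotation) and, per device, the count of detected seconds
    falling outside that universe (detections in unlabeled silence, reported
    separately and excluded from contingency counting).
    """
    if len(labels_by_annotator) != 3:
        raise ValueError("consensus rule assumes exactly three annotators")
    annotators = sorted(labels_by_annotator)
    tier_maps = {
        ann: annotator_tier_map(labels_by_annotator[ann], merge_gap) for ann in annotators
    }
    universe = sorted(set().union(*(m.keys() for m in tier_maps.values())))

    device_maps = {
        dev: pool_detections(dets, threshold)
        for dev, dets in detections_by_device.items()
    }

    seconds = []
    for sec in universe:
        gold = _classify_tiers([tier_maps[ann].get(sec) for ann in annotators])
        devices = {
            dev: device_maps[dev].get(sec, DeviceSecond(False, None))
            for dev in device_maps
        }
        seconds.append(AnalysisSecond(session_id, sec, gold, devices))

    universe_set = set(universe)
    out_of_universe = {
        dev: sum(1 for sec, ds in dmap.items() if ds.detected and sec not in universe_set)
        for dev, dmap in device_maps.items()
    }
    return seconds, out_of_universe


def session_qc(
    seconds: Sequence[AnalysisSecond],
    synchronizable: bool,
    min_coughs: int = DEFAULT_MIN_COUGHS,
    session_id: str | None = None,
) -> SessionQC:
    """Apply the session inclusion rule: synchronizable and at least
    ``min_coughs`` unanimous cough-seconds (boundary inclusive)."""
    if session_id is None:
        session_id = seconds[0].session_id if seconds else ""
    n_coughs = sum(1 for s in seconds if s.gold_class is GoldClass.TRUE_COUGH)
    n_disputed = sum(1 for s in seconds if not s.gold_class.in_contingency)
    if not synchronizable:
        reason = ExclusionReason.SYNC_FAILURE
    elif n_coughs < min_coughs:
        reason = ExclusionReason.TOO_FEW_COUGHS
    else:
        reason = ExclusionReason.NONE
    return SessionQC(
        session_id=session_id,
        n_unanimous_coughs=n_coughs,
        n_disputed_seconds=n_disputed,
        synchronizable=synchronizable,
        included=reason is ExclusionReason.NONE,
        exclusion_reason=reason,
    )
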