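"""Simulate complete solicited-sound sessions for end-to-end testing.

No recordings were deposited with the study this pipeline evaluates, so
every stage is exercised on simulated sessions: scripted true sound events
with >= 5 s gaps and uniform sub-second jitter, three annotators who assign
tiers through per-kind confusion rows, and one or more detectors with
imperfect sensitivity, false triggers on non-cough sounds, a Poisson
spurious stream in silence, Beta-distributed prediction scores by class,
and an unknown per-device clock offset.

``p_detect_cough`` is the detector's operating sensitivity at its score
threshold: detected coughs draw their score from the cough Beta conditioned
at or above the threshold; missed coughs are either absent from the log or
logged with a sub-threshold conditional score.  Label and detection
timestamps are exact (no marking noise); see the methods note for what that
means for interpreting results on real data.

All randomness flows from one seeded generator; with a fixed seed the
simulated cohort, including its on-disk files, is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    AnnotationLabel,
    Detection,
    SessionManifest,
    write_detections,
    write_label_track,
    write_manifest,
)
from .study_design import DEFAULT_EMBEDDED_COUGHS, TEXT_PASSAGE, canonical_script

__all__ = [
    "DetectorParams",
    "AnnotatorParams",
    "SimulatorParams",
    "TrueEvent",
    "SessionTruth",
    "SessionData",
    "Cohort",
    "simulate_session",
    "simulate_cohort",
    "degraded_annotator_params",
    "degrade_annotators",
    "PERFECT_ANNOTATOR",
]

# tier-confusion rows P(tier 0..3 | true sound kind); defaults chosen so that
# three independent annotators reach tier-3 unanimity on ~91% of coughs and
# a few percent of non-cough sounds draw disputable (tier 1-2) labels,
# matching the consensus behaviour reported for solicited-sound cohorts.
DEFAULT_CONFUSION: dict[str, tuple[float, float, float, float]] = {
    "cough": (0.005, 0.005, 0.02, 0.97),
    "sneeze": (0.96, 0.03, 0.01, 0.0),
    "throat_clear": (0.95, 0.04, 0.01, 0.0),
    "word": (0.995, 0.004, 0.001, 0.0),
}

# sub-events a read text passage expands to (2 embedded coughs among words)
_PASSAGE_KINDS = ("word", "cough", "word", "word", "cough", "word")


@dataclass(frozen=True)
class DetectorParams:
    """Detector behaviour; defaults emulate the evaluated monitor."""

    p_detect_cough: float = 0.92
    p_detect_other: float = 0.30
    spurious_rate: float = 0.5  # events per minute of silence
    score_given_cough: tuple[float, float] = (8.0, 1.0)  # Beta(a, b)
    score_given_noncough: tuple[float, float] = (1.0, 6.0)
    score_threshold: float = 0.85
    clock_offset_range: tuple[float, float] = (-30.0, 30.0)
    p_log_missed_cough: float = 0.5  # missed coughs still logged sub-threshold

    def __post_init__(self) -> None:
        for name in ("p_detect_cough", "p_detect_other", "p_log_missed_cough"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be non-negative")
        for name in ("score_given_cough", "score_given_noncough"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta parameters must be positive")
        if not 0 < self.score_threshold < 1:
            raise ValueError("score_threshold must be in (0, 1)")


@dataclass(frozen=True)
class AnnotatorParams:
    """Tier-confusion rows per true sound kind for one annotator."""

    confusion: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONFUSION)
    )

    def __post_init__(self) -> None:
        for kind, row in self.confusion.items():
            if len(row) != 4 or any(not 0 <= p <= 1 for p in row):
                raise ValueError(f"confusion row for {kind!r} must be 4 probabilities")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"confusion row for {kind!r} must sum to 1, got {sum(row)}")


PERFECT_ANNOTATOR = AnnotatorParams(
    confusion={
        "cough": (0.0, 0.0, 0.0, 1.0),
        "sneeze": (1.0, 0.0, 0.0, 0.0),
        "throat_clear": (1.0, 0.0, 0.0, 0.0),
        "word": (1.0, 0.0, 0.0, 0.0),
    }
)


@dataclass(frozen=True)
class SimulatorParams:
    """Cohort-level simulation settings; defaults are the study conditions
    (49 ten-minute sessions, two phones, three annotators, scripts 1-5)."""

    seed: int = 0
    n_sessions: int = 49
    session_duration: float = 600.0
    devices: tuple[str, ...] = ("phone1", "phone2")
    annotator_ids: tuple[str, ...] = ("ann1", "ann2", "ann3")
    detector: DetectorParams = field(default_factory=DetectorParams)
    annotators: tuple[AnnotatorParams, ...] = ()
    script_composition: Optional[dict[str, int]] = None
    embedded_coughs: int = DEFAULT_EMBEDDED_COUGHS
    margin: float = 10.0  # silence kept at both ends of the session
    min_event_gap: float = 5.0
    event_jitter: float = 1.0  # uniform jitter around scheduled prompt times

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("need at least one session")
        if len(self.annotator_ids) != 3:
            raise ValueError("the consensus rule assumes exactly three annotators")
        if self.annotators and len(self.annotators) != 3:
            raise ValueError("provide either zero or three annotator parameter sets")

    def annotator_params(self) -> tuple[AnnotatorParams, ...]:
        if self.annotators:
            return self.annotators
        return tuple(AnnotatorParams() for _ in range(3))


@dataclass(frozen=True)
class TrueEvent:
    time: float
    kind: str
    embedded: bool = False


@dataclass
class SessionTruth:
    """Everything the simulator knows that the pipeline must recover."""

    session_id: str
    events: list[TrueEvent]
    offsets: dict[str, float]  # device -> true clock offset (detector + offset = truth)
    detected_events: dict[str, list[int]]  # device -> indices of logged true events
    n_spurious: dict[str, int]

    @property
    def n_true_coughs(self) -> int:
        return sum(1 for e in self.events if e.kind == "cough")


@dataclass
class SessionData:
    manifest_entry: dict
    labels: dict[str, list[AnnotationLabel]]
    detections: dict[str, list[Detection]]
    truth: SessionTruth

    @property
    def session_id(self) -> str:
        return self.truth.session_id


@dataclass
class Cohort:
    params: SimulatorParams
    sessions: list[SessionData]


def _beta_conditional(
    rng: np.random.Generator, a: float, b: float,
    lower: float = 0.0, upper: float = 1.0,
) -> float:
    """Draw from Beta(a, b) conditioned on [lower, upper] via CDF inversion."""
    lo = stats.beta.cdf(lower, a, b)
    hi = stats.beta.cdf(upper, a, b)
    u = rng.uniform(lo, hi)
    return float(np.clip(stats.beta.ppf(u, a, b), lower, upper))


def _schedule_events(
    rng: np.random.Generator, params: SimulatorParams, version: int
) -> list[TrueEvent]:
    script = canonical_script(version) if params.script_composition is None else None
    if script is None:
        from .study_design import generate_script

        script = generate_script(
            version, params.script_composition, embedded_coughs=params.embedded_coughs
        )
    kinds: list[tuple[str, bool]] = []
    for ins in script.instructions:
        if ins.kind == TEXT_PASSAGE:
            passage = list(_PASSAGE_KINDS)
            # honour a non-default embedded-cough count by trimming/padding coughs
            want = script.embedded_coughs
            have = passage.count("cough")
            while have > want:
                passage.remove("cough")
                have -= 1
            while have < want:
                passage.append("cough")
                have += 1
            kinds.extend((k, True) for k in passage)
        else:
            kinds.append((ins.kind, False))
    n = len(kinds)
    usable = params.session_duration - 2 * params.margin
    spacing = usable / n if n else 0.0
    if n == 0 or spacing < params.min_event_gap + params.event_jitter:
        raise ValueError(
            f"session of {params.session_duration}s too short for a {n}-sound script"
        )
    times = params.margin + spacing * np.arange(n) + rng.uniform(0, params.event_jitter, n)
    return [TrueEvent(float(t), k, emb) for t, (k, emb) in zip(times, kinds)]


def simulate_session(
    rng: np.random.Generator,
    session_id: str,
    participant_id: str,
    params: SimulatorParams,
) -> SessionData:
    version = int(rng.integers(1, 6))
    events = _schedule_events(rng, params, version)
    det = params.detector

    labels: dict[str, list[AnnotationLabel]] = {}
    for ann_id, ann in zip(params.annotator_ids, params.annotator_params()):
        track = []
        for ev in events:
            row = ann.confusion.get(ev.kind)
            if row is None:
                raise ValueError(f"no confusion row for sound kind {ev.kind!r}")
            tier = int(rng.choice(4, p=row))
            track.append(AnnotationLabel(ann_id, ev.time, ev.time, tier, str(tier)))
        labels[ann_id] = track

    detections: dict[str, list[Detection]] = {}
    offsets: dict[str, float] = {}
    detected_events: dict[str, list[int]] = {}
    n_spurious: dict[str, int] = {}
    thr = det.score_threshold
    for device in params.devices:
        offset = float(rng.uniform(*det.clock_offset_range))
        offsets[device] = offset
        stream: list[Detection] = []
        hits: list[int] = []
        for idx, ev in enumerate(events):
            if ev.kind == "cough":
                if rng.random() < det.p_detect_cough:
                    score = _beta_conditional(rng, *det.score_given_cough, lower=thr)
                    hits.append(idx)
                elif rng.random() < det.p_log_missed_cough:
                    score = _beta_conditional(rng, *det.score_given_cough, upper=thr)
                else:
                    continue
            else:
                if rng.random() < det.p_detect_other:
                    score = _beta_conditional(rng, *det.score_given_noncough)
                else:
                    continue
            stream.append(Detection(device, ev.time - offset, score))
        k = int(rng.poisson(det.spurious_rate * params.session_duration / 60.0))
        n_spurious[device] = k
        for t in np.sort(rng.uniform(0, params.session_duration, k)):
            score = _beta_conditional(rng, *det.score_given_noncough)
            stream.append(Detection(device, float(t) - offset, score))
        stream.sort(key=lambda d: d.timestamp)
        detections[device] = stream
        detected_events[device] = hits

    truth = SessionTruth(session_id, events, offsets, detected_events, n_spurious)
    manifest_entry = {
        "session_id": session_id,
        "participant_id": participant_id,
        "script_version": version,
        "duration": params.session_duration,
    }
    return SessionData(manifest_entry, labels, detections, truth)


def simulate_cohort(
    params: SimulatorParams, outdir: str | Path | None = None
) -> Cohort:
    """Simulate a full cohort; optionally write it in the pipeline's file
    formats (label tracks, detector logs, YAML manifest) under ``outdir``."""
    rng = np.random.default_rng(params.seed)
    sessions = []
    width = max(2, len(str(params.n_sessions)))
    for i in range(1, params.n_sessions + 1):
        sid = f"s{i:0{width}d}"
        pid = f"p{i:0{width}d}"
        sessions.append(simulate_session(rng, sid, pid, params))
    cohort = Cohort(params, sessions)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write the cohort's files; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests = []
    for ses in cohort.sessions:
        sdir = outdir / ses.session_id
        sdir.mkdir(exist_ok=True)
        label_paths = {}
        for ann_id, track in ses.labels.items():
            p = sdir / f"{ann_id}_labels.txt"
            write_label_track(track, p)
            label_paths[ann_id] = str(p)
        det_paths = {}
        for device, stream in ses.detections.items():
            p = sdir / f"{device}_detections.csv"
            write_detections(stream, p)
            det_paths[device] = str(p)
        manifests.append(
            SessionManifest(
                session_id=ses.manifest_entry["session_id"],
                participant_id=ses.manifest_entry["participant_id"],
                script_version=ses.manifest_entry["script_version"],
                duration=ses.manifest_entry["duration"],
                label_paths=label_paths,
                detection_paths=det_paths,
            )
        )
    manifest_path = outdir / "manifest.yaml"
    write_manifest(manifests, manifest_path)
    return manifest_path


def degraded_annotator_params(
    disagreement_rate: float,
    base: Optional[AnnotatorParams] = None,
) -> AnnotatorParams:
    """Annotator whose cough row yields tier-3 unanimity with probability
    ``1 - disagreement_rate`` across three independent annotators."""
    if not 0 <= disagreement_rate <= 1:
        raise ValueError("disagreement rate must be in [0, 1]")
    p3 = (1.0 - disagreement_rate) ** (1.0 / 3.0)
    rest = 1.0 - p3
    confusion = dict((base or AnnotatorParams()).confusion)
    confusion["cough"] = (0.1 * rest, 0.3 * rest, 0.6 * rest, p3)
    return AnnotatorParams(confusion=confusion)


def degrade_annotators(
    params: SimulatorParams,
    disagreement_rate: float,
    outdir: str | Path | None = None,
) -> Cohort:
    """Simulate a cohort where the stated fraction of coughs fails unanimity."""
    ann = degraded_annotator_params(disagreement_rate)
    degraded = dataclasses.replace(params, annotators=(ann, ann, ann))
    return simulate_cohort(degraded, outdir)
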