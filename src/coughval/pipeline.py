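"""End-to-end orchestration: manifest -> sync -> gold standard -> QC ->
accuracy -> rate agreement, with a reproducibility record.

Every default in :class:`RunConfig` is the evaluation's operating value:
score threshold 0.85, matching tolerance 2 s, offset grid +/-60 s at 0.1 s,
QC minimum of 10 unanimous cough-seconds, 60 s rate segments, 95% CIs.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import detector_eval, gold_standard, rate_agreement, synchronization
from .gold_standard import AnalysisSecond, ExclusionReason, GoldClass, SessionQC
from .io_formats import read_detections, read_label_track, read_manifest, SessionManifest
from .synchronization import OffsetEstimate

__all__ = ["RunConfig", "SessionResult", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    grid: tuple[float, float, float] = synchronization.DEFAULT_GRID
    tolerance: float = synchronization.DEFAULT_TOLERANCE
    threshold: float = gold_standard.DEFAULT_SCORE_THRESHOLD
    min_coughs: int = gold_standard.DEFAULT_MIN_COUGHS
    segment_length: float = rate_agreement.DEFAULT_SEGMENT_LENGTH
    confidence: float = 0.95
    merge_gap: float = gold_standard.DEFAULT_MERGE_GAP
    seed: int = 0
    make_plots: bool = False
    manual_offsets: dict = field(default_factory=dict)  # "session/device" -> offset

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "grid" in doc:
        doc["grid"] = tuple(doc["grid"])
    base = Path(path).parent
    for key in ("manifest", "out_dir"):
        if key in doc and not Path(doc[key]).is_absolute():
            doc[key] = str(base / doc[key])
    return RunConfig(**doc)


@dataclass
class SessionResult:
    manifest: SessionManifest
    offsets: dict[str, OffsetEstimate]
    seconds: list[AnalysisSecond]
    out_of_universe: dict[str, int]
    qc: SessionQC
    gold_cough_seconds: set[int]
    device_cough_seconds: dict[str, set[int]]


def _process_session(m: SessionManifest, config: RunConfig) -> SessionResult:
    labels = {
        ann: read_label_track(path, annotator_id=ann)
        for ann, path in m.label_paths.items()
    }
    raw_detections = {dev: read_detections(path) for dev, path in m.detection_paths.items()}
    return process_streams(m, labels, raw_detections, config)


def process_streams(
    m: SessionManifest,
    labels: dict,
    raw_detections: dict,
    config: RunConfig,
) -> SessionResult:
    """Evaluate one session from in-memory label and detection streams."""
    ref_times = synchronization.cough_like_times(labels, config.merge_gap)
    offsets: dict[str, OffsetEstimate] = {}
    corrected = {}
    for dev, dets in raw_detections.items():
        key = f"{m.session_id}/{dev}"
        if key in config.manual_offsets:
            est = OffsetEstimate.manual(m.session_id, dev,
                                        float(config.manual_offsets[key]), config.grid)
        else:
            est = synchronization.estimate_offset(
                ref_times, dets, grid=config.grid, tolerance=config.tolerance,
                session_id=m.session_id, device_id=dev,
                score_threshold=config.threshold,
            )
        offsets[dev] = est
        corrected[dev] = (
            synchronization.apply_offset(dets, est) if est.synchronizable else []
        )

    synchronizable = all(est.synchronizable for est in offsets.values())
    seconds, out_of_universe = gold_standard.build_analysis_seconds(
        m.session_id, labels, corrected, config.threshold, config.merge_gap
    )
    qc = gold_standard.session_qc(seconds, synchronizable,
                                  config.min_coughs, m.session_id)
    gold_secs = {
        s.second_index for s in seconds if s.gold_class is GoldClass.TRUE_COUGH
    }
    device_secs = {
        dev: {
            sec
            for sec, ds in gold_standard.pool_detections(
                corrected[dev], config.threshold
            ).items()
            if ds.detected
        }
        for dev in corrected
    }
    return SessionResult(m, offsets, seconds, out_of_universe, qc, gold_secs, device_secs)


def evaluate_cohort(cohort, config: Optional[RunConfig] = None) -> list[SessionResult]:
    """Evaluate a simulated cohort in memory (no file round-trip)."""
    if config is None:
        config = RunConfig(manifest="", out_dir="")
    results = []
    for ses in cohort.sessions:
        m = SessionManifest(
            session_id=ses.manifest_entry["session_id"],
            participant_id=ses.manifest_entry["participant_id"],
            script_version=ses.manifest_entry["script_version"],
            duration=ses.manifest_entry["duration"],
            label_paths={a: f"<memory>/{a}" for a in ses.labels},
            detection_paths={d: f"<memory>/{d}" for d in ses.detections},
        )
        results.append(process_streams(m, ses.labels, ses.detections, config))
    return results


def _flowchart(results: Sequence[SessionResult]) -> dict:
    reasons = {r.value: 0 for r in ExclusionReason if r is not ExclusionReason.NONE}
    for res in results:
        if not res.qc.included:
            reasons[res.qc.exclusion_reason.value] += 1
    included = sum(res.qc.included for res in results)
    return {
        "total_sessions": len(results),
        "excluded": reasons,
        "included_sessions": included,
    }


def _write_offsets(results: Sequence[SessionResult], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["session_id", "device_id", "offset", "error", "method"])
        for res in results:
            for dev in sorted(res.offsets):
                est = res.offsets[dev]
                writer.writerow(
                    [est.session_id, est.device_id, f"{est.offset:.4f}",
                     f"{est.error:.6f}", est.method if est.synchronizable else "unsynchronizable"]
                )


def _write_evaluable(results: Sequence[SessionResult], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["session_id", "second_index", "gold_class", "device_id", "detected", "max_score"]
        )
        for res in results:
            if not res.qc.included:
                continue
            for sec in res.seconds:
                for dev in sorted(sec.devices):
                    ds = sec.devices[dev]
                    writer.writerow(
                        [sec.session_id, sec.second_index, sec.gold_class.value, dev,
                         int(ds.detected),
                         "" if ds.max_score is None else f"{ds.max_score:.6f}"]
                    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the metrics dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifests = read_manifest(config.manifest)
    logger.info("loaded %d sessions from %s", len(manifests), config.manifest)

    results = [_process_session(m, config) for m in manifests]
    flow = _flowchart(results)
    included = [r for r in results if r.qc.included]
    devices = sorted({dev for r in results for dev in r.offsets})

    _write_offsets(results, out / "offsets.csv")
    _write_evaluable(results, out / "evaluable.csv")

    with open(out / "session_qc.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["session_id", "n_unanimous_coughs", "n_disputed_seconds",
                         "synchronizable", "included", "exclusion_reason"])
        for res in results:
            qc = res.qc
            writer.writerow([qc.session_id, qc.n_unanimous_coughs, qc.n_disputed_seconds,
                             int(qc.synchronizable), int(qc.included),
                             qc.exclusion_reason.value])

    seconds_by_session = {r.manifest.session_id: r.seconds for r in included}

    pooled = {}
    for dev in devices:
        try:
            pooled[dev] = detector_eval.pooled_metrics(
                seconds_by_session, dev, config.confidence
            )
        except ValueError as exc:
            logger.warning("device %s: pooled metrics unavailable (%s)", dev, exc)

    per_session_frame, summaries = (
        detector_eval.per_session_metrics(seconds_by_session)
        if included else (None, {})
    )
    if per_session_frame is not None:
        per_session_frame.to_csv(out / "per_session_metrics.csv", index=False)

    series = None
    agreement: dict = {}
    if included:
        series = rate_agreement.concat_series(
            [
                rate_agreement.segment_counts(
                    r.gold_cough_seconds, r.device_cough_seconds,
                    r.manifest.duration, config.segment_length,
                    r.manifest.session_id,
                )
                for r in included
            ]
        )
        series.frame.to_csv(out / "rate_segments.csv", index=False)
        try:
            agreement = rate_agreement.evaluate_agreement(series)
        except ValueError as exc:
            logger.warning("rate agreement unavailable (%s)", exc)
        if config.make_plots and series is not None:
            rate_agreement.plot_rate_scatter(series, out / "rate_scatter.png",
                                             seed=config.seed)
            rate_agreement.plot_bland_altman(series, out / "bland_altman.png")

    # table-shaped delimited reports
    with open(out / "table1_session_summaries.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["device_id", "metric", "minimum", "q1", "median", "q3", "maximum"])
        for dev in sorted(summaries):
            for metric, s in sorted(summaries[dev].items()):
                writer.writerow([dev, metric] +
                                [f"{v:.3f}" for v in (s.minimum, s.q1, s.median, s.q3, s.maximum)])
    with open(out / "table2_pooled.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["device_id", "tp", "fp", "fn", "tn",
                         "sensitivity_pct", "sensitivity_ci_pct",
                         "specificity_pct", "specificity_ci_pct"])
        for dev in sorted(pooled):
            p = pooled[dev]
            se_ci, sp_ci = p["sensitivity_ci"], p["specificity_ci"]
            writer.writerow([
                dev, p["table"].tp, p["table"].fp, p["table"].fn, p["table"].tn,
                f"{100 * p['sensitivity']:.1f}",
                f"{100 * se_ci.lower:.1f}-{100 * se_ci.upper:.1f}",
                f"{100 * p['specificity']:.1f}",
                f"{100 * sp_ci.lower:.1f}-{100 * sp_ci.upper:.1f}",
            ])
    with open(out / "table3_agreement.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["device_id", "pearson_r", "intercept", "slope",
                         "ba_mean_pct", "ba_loa_lower_pct", "ba_loa_upper_pct",
                         "n_segments_used"])
        for name in sorted(agreement):
            res = agreement[name]
            ba = res.bland_altman
            writer.writerow([
                name, f"{res.pearson_r:.3f}", f"{res.intercept:.3f}", f"{res.slope:.3f}",
                f"{ba.mean_pct_error:.1f}", f"{ba.loa_lower:.1f}", f"{ba.loa_upper:.1f}",
                ba.n_segments_used,
            ])

    # text flowchart of exclusions at each step
    with open(out / "flowchart.txt", "w", encoding="utf-8") as fh:
        fh.write(f"sessions recorded            {flow['total_sessions']}\n")
        fh.write(f"  excluded: sync failure     {flow['excluded']['sync_failure']}\n")
        fh.write(f"  excluded: <{config.min_coughs} unanimous coughs  "
                 f"{flow['excluded']['too_few_coughs']}\n")
        fh.write(f"sessions evaluated           {flow['included_sessions']}\n")
        n_cough = sum(r.qc.n_unanimous_coughs for r in included)
        n_non = sum(
            sum(1 for s in r.seconds if s.gold_class is GoldClass.NON_COUGH)
            for r in included
        )
        fh.write(f"unanimous cough-seconds      {n_cough}\n")
        fh.write(f"non-cough seconds            {n_non}\n")

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "flowchart": flow,
        "out_of_universe_detections": {
            dev: sum(r.out_of_universe.get(dev, 0) for r in included) for dev in devices
        },
        "pooled": {
            dev: {
                "tp": p["table"].tp, "fp": p["table"].fp,
                "fn": p["table"].fn, "tn": p["table"].tn,
                "sensitivity": p["sensitivity"],
                "sensitivity_ci": [p["sensitivity_ci"].lower, p["sensitivity_ci"].upper],
                "specificity": p["specificity"],
                "specificity_ci": [p["specificity_ci"].lower, p["specificity_ci"].upper],
            }
            for dev, p in pooled.items()
        },
        "per_session_summary": {
            dev: {
                metric: dataclasses.asdict(summary)
                for metric, summary in per_dev.items()
            }
            for dev, per_dev in summaries.items()
        },
        "agreement": {
            name: {
                "pearson_r": res.pearson_r,
                "intercept": res.intercept,
                "slope": res.slope,
                "bland_altman": dataclasses.asdict(res.bland_altman)
                if res.bland_altman else None,
            }
            for name, res in agreement.items()
        },
    }
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
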