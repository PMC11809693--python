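"""Diagnostic accuracy of a detector over the per-second gold standard.

Sensitivity is TP/(TP+FN) over unanimous cough-seconds; specificity is
1 - FP/(FP+TN) over non-cough seconds.  Confidence intervals are exact
Clopper-Pearson intervals (inversion of binomial tail probabilities), which
reproduce the intervals printed for the study counts where common
approximate intervals do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .gold_standard import AnalysisSecond, GoldClass

__all__ = [
    "ContingencyTable",
    "BinomialCI",
    "MetricSummary",
    "contingency",
    "sensitivity",
    "specificity",
    "exact_binomial_ci",
    "per_session_metrics",
    "metric_summary",
    "pooled_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts for one device over a set of analysis seconds."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @property
    def n_cough_seconds(self) -> int:
        return self.tp + self.fn

    @property
    def n_noncough_seconds(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class BinomialCI:
    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.estimate <= self.upper <= 1:
            raise ValueError(
                f"interval must satisfy 0 <= {self.lower} <= {self.estimate} "
                f"<= {self.upper} <= 1"
            )

    def __contains__(self, p: float) -> bool:
        return self.lower <= p <= self.upper


@dataclass(frozen=True)
class MetricSummary:
    """Five-number summary of a per-session metric."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def contingency(
    seconds: Sequence[AnalysisSecond], device_id: str
) -> ContingencyTable:
    """Count TP/FP/FN/TN for one device; disagreement seconds are skipped."""
    tp = fp = fn = tn = 0
    for sec in seconds:
        if not sec.gold_class.in_contingency:
            continue
        state = sec.devices.get(device_id)
        detected = state.detected if state is not None else False
        if sec.gold_class is GoldClass.TRUE_COUGH:
            tp += detected
            fn += not detected
        else:
            fp += detected
            tn += not detected
    return ContingencyTable(tp, fp, fn, tn)


def sensitivity(ct: ContingencyTable) -> float:
    if ct.tp + ct.fn == 0:
        raise ValueError("sensitivity undefined: no gold cough-seconds")
    return ct.tp / (ct.tp + ct.fn)


def specificity(ct: ContingencyTable) -> float:
    if ct.fp + ct.tn == 0:
        raise ValueError("specificity undefined: no gold non-cough seconds")
    return 1.0 - ct.fp / (ct.fp + ct.tn)


def exact_binomial_ci(
    successes: int, n: int, confidence: float = 0.95
) -> BinomialCI:
    """Clopper-Pearson exact binomial interval."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    lower, upper = proportion_confint(successes, n, alpha=1 - confidence, method="beta")
    # statsmodels returns NaN at the boundary counts where the exact bound is closed
    lower = 0.0 if np.isnan(lower) else float(lower)
    upper = 1.0 if np.isnan(upper) else float(upper)
    return BinomialCI(successes / n, lower, upper, confidence)


def metric_summary(values: Sequence[float]) -> MetricSummary:
    """Five-number summary (linear interpolation between order statistics)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty metric series")
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return MetricSummary(*map(float, q))


def per_session_metrics(
    seconds_by_session: Mapping[str, Sequence[AnalysisSecond]],
) -> tuple[pd.DataFrame, dict[str, dict[str, MetricSummary]]]:
    """Per (session, device) sensitivity/specificity plus per-device summaries.

    Sessions with an undefined metric (e.g. no evaluable gold coughs for
    that device) get NaN there and are skipped in the summary, with a
    logged warning.
    """
    devices: list[str] = sorted(
        {dev for secs in seconds_by_session.values() for s in secs for dev in s.devices}
    )
    rows = []
    for session_id in sorted(seconds_by_session):
        secs = seconds_by_session[session_id]
        for dev in devices:
            ct = contingency(secs, dev)
            try:
                se = sensitivity(ct)
            except ValueError:
                logger.warning(
                    "session %s device %s: sensitivity not evaluated (no gold coughs)",
                    session_id, dev,
                )
                se = float("nan")
            try:
                sp = specificity(ct)
            except ValueError:
                logger.warning(
                    "session %s device %s: specificity not evaluated (no non-cough seconds)",
                    session_id, dev,
                )
                sp = float("nan")
            rows.append(
                {"session_id": session_id, "device_id": dev,
                 "sensitivity": se, "specificity": sp,
                 "tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn}
            )
    frame = pd.DataFrame(
        rows, columns=["session_id", "device_id", "sensitivity", "specificity",
                       "tp", "fp", "fn", "tn"]
    )
    summaries: dict[str, dict[str, MetricSummary]] = {}
    for dev in devices:
        sub = frame[frame.device_id == dev]
        summaries[dev] = {
            metric: metric_summary(sub[metric].dropna().to_numpy())
            for metric in ("sensitivity", "specificity")
            if sub[metric].notna().any()
        }
    return frame, summaries


def pooled_metrics(
    seconds_by_session: Mapping[str, Sequence[AnalysisSecond]],
    device_id: str,
    confidence: float = 0.95,
) -> dict:
    """Pooled contingency table, sensitivity/specificity and exact CIs."""
    pooled = ContingencyTable(0, 0, 0, 0)
    for secs in seconds_by_session.values():
        pooled = pooled + contingency(secs, device_id)
    se = sensitivity(pooled)
    sp = specificity(pooled)
    return {
        "device_id": device_id,
        "table": pooled,
        "sensitivity": se,
        "sensitivity_ci": exact_binomial_ci(pooled.tp, pooled.n_cough_seconds, confidence),
        "specificity": sp,
        "specificity_ci": exact_binomial_ci(pooled.tn, pooled.n_noncough_seconds, confidence),
    }
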