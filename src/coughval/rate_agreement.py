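"""Minute-level agreement between gold-standard and detector cough rates.

The observation period is cut into fixed-length segments (default 60 s);
per segment the unanimous gold cough-seconds are counted against the
device's detected cough-seconds.  Agreement is summarized by the Pearson
correlation, an ordinary-least-squares fit (device = intercept +
slope * gold), and Bland-Altman limits of agreement on percentage error
with the gold count as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MinuteRateSeries",
    "BlandAltman",
    "AgreementResult",
    "segment_counts",
    "concat_series",
    "correlate",
    "bland_altman_pct",
    "evaluate_agreement",
    "plot_rate_scatter",
    "plot_bland_altman",
]

DEFAULT_SEGMENT_LENGTH = 60.0

_COLUMNS = ["session_id", "device_id", "segment_index", "gold_count", "device_count"]


@dataclass
class MinuteRateSeries:
    """Paired per-segment gold vs detector cough counts."""

    frame: pd.DataFrame  # columns: session_id, device_id, segment_index, gold_count, device_count
    segment_length: float = DEFAULT_SEGMENT_LENGTH

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"rate series missing columns {missing}")
        if (self.frame[["gold_count", "device_count"]] < 0).any().any():
            raise ValueError("segment counts must be non-negative")

    @property
    def devices(self) -> list[str]:
        return sorted(self.frame.device_id.unique())


@dataclass(frozen=True)
class BlandAltman:
    """Mean percentage error and 1.96-SD limits of agreement."""

    mean_pct_error: float
    loa_lower: float
    loa_upper: float
    n_segments_used: int

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.mean_pct_error <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the mean error")


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    intercept: float
    slope: float
    bland_altman: Optional[BlandAltman] = None


def segment_counts(
    gold_seconds: Iterable[int],
    device_seconds_by_device: Mapping[str, Iterable[int]],
    duration: float,
    segment_length: float = DEFAULT_SEGMENT_LENGTH,
    session_id: str = "session",
) -> MinuteRateSeries:
    """Per-segment counts for one session, all segments present (zeros kept).

    A final partial segment is kept only if it is at least half a segment
    long; seconds beyond the kept segments are dropped.
    """
    if segment_length <= 0:
        raise ValueError("segment length must be positive")
    n_full = int(duration // segment_length)
    remainder = duration - n_full * segment_length
    n_segments = n_full + (1 if remainder >= segment_length / 2 else 0)
    if n_segments == 0:
        raise ValueError(f"session {session_id}: too short for any segment")

    def _counts(seconds: Iterable[int]) -> np.ndarray:
        counts = np.zeros(n_segments, dtype=int)
        for sec in seconds:
            idx = int(sec // segment_length)
            if 0 <= idx < n_segments and sec < duration:
                counts[idx] += 1
        return counts

    gold = _counts(gold_seconds)
    rows = []
    for dev in sorted(device_seconds_by_device):
        dev_counts = _counts(device_seconds_by_device[dev])
        for i in range(n_segments):
            rows.append((session_id, dev, i, int(gold[i]), int(dev_counts[i])))
    return MinuteRateSeries(pd.DataFrame(rows, columns=_COLUMNS), segment_length)


def concat_series(series: Sequence[MinuteRateSeries]) -> MinuteRateSeries:
    if not series:
        raise ValueError("no rate series to concatenate")
    lengths = {s.segment_length for s in series}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent segment lengths {lengths}")
    return MinuteRateSeries(
        pd.concat([s.frame for s in series], ignore_index=True), lengths.pop()
    )


def correlate(gold: Sequence[int], device: Sequence[int]) -> AgreementResult:
    """Pearson r and OLS fit device = intercept + slope * gold."""
    gold = np.asarray(gold, dtype=float)
    device = np.asarray(device, dtype=float)
    if gold.size < 3:
        raise ValueError("need at least 3 segments for correlation")
    if np.var(gold) == 0:
        raise ValueError("correlation undefined: gold counts have zero variance")
    fit = stats.linregress(gold, device)
    return AgreementResult(
        pearson_r=float(fit.rvalue), intercept=float(fit.intercept),
        slope=float(fit.slope),
    )


def bland_altman_pct(gold: Sequence[int], device: Sequence[int]) -> BlandAltman:
    """Bland-Altman on percentage error, gold count as denominator.

    Segments with zero gold coughs are excluded (percentage error
    undefined); ``n_segments_used`` reports how many remain.
    """
    gold = np.asarray(gold, dtype=float)
    device = np.asarray(device, dtype=float)
    mask = gold > 0
    if not mask.any():
        raise ValueError("Bland-Altman undefined: no segments with gold coughs")
    pct = 100.0 * (device[mask] - gold[mask]) / gold[mask]
    mean = float(np.mean(pct))
    sd = float(np.std(pct, ddof=1)) if pct.size > 1 else 0.0
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd, int(mask.sum()))


def evaluate_agreement(
    series: MinuteRateSeries, pooled: bool = True
) -> dict[str, AgreementResult]:
    """Agreement per device, plus a pooled result concatenating all
    device-session segments under the key ``"pooled"``."""
    results: dict[str, AgreementResult] = {}
    groups: list[tuple[str, pd.DataFrame]] = [
        (dev, sub) for dev, sub in series.frame.groupby("device_id")
    ]
    if pooled:
        groups.append(("pooled", series.frame))
    for name, sub in groups:
        fit = correlate(sub.gold_count.to_numpy(), sub.device_count.to_numpy())
        ba = bland_altman_pct(sub.gold_count.to_numpy(), sub.device_count.to_numpy())
        results[str(name)] = AgreementResult(
            fit.pearson_r, fit.intercept, fit.slope, ba
        )
    return results


def _jitter(rng: np.random.Generator, values: np.ndarray, amount: float) -> np.ndarray:
    return values + rng.uniform(-amount, amount, size=values.shape)


def plot_rate_scatter(
    series: MinuteRateSeries, path, jitter: float = 0.3, seed: int = 0
) -> None:
    """Scatter of device vs gold per-segment counts with the identity line.

    Points are jittered (up to ``jitter`` counts) for visibility only; the
    numbers in the tables are the contract.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(5, 5))
    for dev, sub in series.frame.groupby("device_id"):
        ax.scatter(
            _jitter(rng, sub.gold_count.to_numpy(dtype=float), jitter),
            _jitter(rng, sub.device_count.to_numpy(dtype=float), jitter),
            s=12, alpha=0.6, label=str(dev),
        )
    lim = max(series.frame.gold_count.max(), series.frame.device_count.max(), 1)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="perfect monitor")
    ax.set_xlabel("Gold-standard coughs per segment")
    ax.set_ylabel("Detector coughs per segment")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(series: MinuteRateSeries, path) -> None:
    """Percentage error vs gold count with mean bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = series.frame[series.frame.gold_count > 0]
    ba = bland_altman_pct(frame.gold_count.to_numpy(), frame.device_count.to_numpy())
    pct = 100.0 * (frame.device_count - frame.gold_count) / frame.gold_count
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(frame.gold_count, pct, s=12, alpha=0.6)
    for y, style in ((ba.mean_pct_error, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("Gold-standard coughs per segment")
    ax.set_ylabel("Percentage error in detections (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
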