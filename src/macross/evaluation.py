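"""Outcome classification, per-participant metrics, cohort aggregates, and
the per-participant parameter-grid optimization.

A detection on a GO trial is a **true positive** when it falls inside the
target window around the IMU-derived movement onset — from 400 ms before
to 100 ms after onset, the span in which afferent feedback triggered by
the detection can still coincide with the motor cortical activity
(Hebbian plasticity window). A detection outside that window is a false
positive; a trial with no detection is a false negative. Only GO trials
are scored (movement is confirmed on each), so true negatives are not
defined.

Rate convention: TPR and FPR share the GO-trial denominator, with false
negatives counted separately, so TPR + FPR + FN-rate = 100% exactly for
every participant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detector import (
    DEFAULT_FAST_GRID,
    DEFAULT_SLOW_GRID,
    DetectionResult,
    DetectionWindow,
    MAConfig,
    STRATEGY_ORDER,
    Strategy,
    detect_trial,
)
from .errors import ConfigurationError, EvaluationError
from .preprocess import Epoch

__all__ = [
    "TargetWindow",
    "TrialOutcome",
    "ParticipantMetrics",
    "AggregateSummary",
    "GridEntry",
    "GridResult",
    "classify_detection",
    "participant_metrics",
    "aggregate_summary",
    "optimize_grid",
]

log = logging.getLogger(__name__)


def round1(x: float) -> float:
    """Round to one decimal, halves away from zero (printing convention)."""
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


@dataclass(frozen=True)
class TargetWindow:
    """Latency interval (closed) around movement onset that counts as a TP."""

    pre_ms: float = 400.0
    post_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.pre_ms < 0 or self.post_ms < 0:
            raise ConfigurationError("target window extents must be >= 0")


@dataclass(frozen=True)
class TrialOutcome:
    """Classification of one GO trial: TP, FP, or FN, with its latency."""

    trial_index: int
    outcome: str  # "TP" | "FP" | "FN"
    detection_time: Optional[float]
    onset_time: Optional[float]
    latency_ms: Optional[float]


@dataclass(frozen=True)
class ParticipantMetrics:
    """Per-participant rates and timing summaries.

    Onset/detection means are on whatever timebase the caller supplied
    (conventionally seconds from the GO cue). Rates are exact fractions of
    the GO-trial count, in percent.
    """

    n_trials: int
    tpr_percent: float
    fpr_percent: float
    fn_count: int
    mean_onset_s: float = math.nan
    sd_onset_s: float = math.nan
    mean_detection_s: float = math.nan
    sd_detection_s: float = math.nan
    mean_latency_ms: float = math.nan


@dataclass(frozen=True)
class AggregateSummary:
    """Unweighted cross-participant aggregates.

    Percentages carry one decimal; ``mean_lead_ms`` is the signed mean over
    participants of (mean detection - mean onset), truncated toward zero to
    integer milliseconds (negative = detection precedes movement).
    """

    n_participants: int
    mean_tpr_percent: float
    mean_fpr_percent: float
    min_tpr_percent: float
    max_tpr_percent: float
    mean_lead_ms: int


def classify_detection(
    result: DetectionResult,
    onset_time: Optional[float],
    target: TargetWindow = TargetWindow(),
) -> TrialOutcome:
    """Score one GO trial's detection against its movement onset.

    ``onset_time`` must be on the same timebase as the detection time
    (classification is invariant to a common shift of both). Boundary
    latencies of exactly -pre_ms or +post_ms count as true positives.
    """
    if onset_time is None:
        raise EvaluationError(
            f"trial {result.trial_index}: GO trial without a movement onset "
            "cannot be scored"
        )
    if result.cross is None:
        return TrialOutcome(result.trial_index, "FN", None, float(onset_time), None)
    det = float(result.cross.time)
    latency_ms = (det - float(onset_time)) * 1000.0
    # closed interval with a float-noise epsilon: latencies on the sample
    # grid that are mathematically exactly -pre/+post must classify as TP
    eps = 1e-6
    in_window = -target.pre_ms - eps <= latency_ms <= target.post_ms + eps
    return TrialOutcome(result.trial_index, "TP" if in_window else "FP",
                        det, float(onset_time), latency_ms)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)])
    if arr.size == 0:
        return math.nan, math.nan
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def participant_metrics(
    outcomes: Sequence[TrialOutcome],
    onsets: Optional[Sequence[float]] = None,
    detections: Optional[Sequence[float]] = None,
) -> ParticipantMetrics:
    """Aggregate per-trial outcomes into one participant's metrics.

    ``onsets`` / ``detections`` override the times recorded on the
    outcomes, letting the caller report on a different timebase (e.g.
    seconds from the GO cue) than the one used for classification.
    """
    if len(outcomes) == 0:
        raise EvaluationError("no trial outcomes to aggregate")
    n = len(outcomes)
    tp = sum(o.outcome == "TP" for o in outcomes)
    fp = sum(o.outcome == "FP" for o in outcomes)
    fn = sum(o.outcome == "FN" for o in outcomes)
    if tp + fp + fn != n:
        raise EvaluationError("outcomes contain an unknown class label")
    if onsets is None:
        onsets = [o.onset_time for o in outcomes]
    if detections is None:
        detections = [o.detection_time for o in outcomes]
    mean_on, sd_on = _mean_sd(onsets)
    mean_det, sd_det = _mean_sd(detections)
    mean_lat, _ = _mean_sd([o.latency_ms for o in outcomes])
    return ParticipantMetrics(
        n_trials=n,
        tpr_percent=100.0 * tp / n,
        fpr_percent=100.0 * fp / n,
        fn_count=fn,
        mean_onset_s=mean_on,
        sd_onset_s=sd_on,
        mean_detection_s=mean_det,
        sd_detection_s=sd_det,
        mean_latency_ms=mean_lat,
    )


def aggregate_summary(per_participant: Sequence[ParticipantMetrics]) -> AggregateSummary:
    """Unweighted means across participants.

    Percentages are reported to one decimal; the signed detection lead is
    the mean over participants of (mean detection - mean onset) in ms,
    truncated toward zero.
    """
    if len(per_participant) == 0:
        raise EvaluationError("no participants to aggregate")
    tprs = [m.tpr_percent for m in per_participant]
    fprs = [m.fpr_percent for m in per_participant]
    leads = [
        (m.mean_detection_s - m.mean_onset_s) * 1000.0
        for m in per_participant
        if np.isfinite(m.mean_detection_s) and np.isfinite(m.mean_onset_s)
    ]
    mean_lead = math.trunc(float(np.mean(leads))) if leads else 0
    return AggregateSummary(
        n_participants=len(per_participant),
        mean_tpr_percent=round1(float(np.mean(tprs))),
        mean_fpr_percent=round1(float(np.mean(fprs))),
        min_tpr_percent=round1(min(tprs)),
        max_tpr_percent=round1(max(tprs)),
        mean_lead_ms=mean_lead,
    )


@dataclass(frozen=True)
class GridEntry:
    """Performance of one (MA window pair, strategy) configuration."""

    config: MAConfig
    strategy: Strategy
    tpr_percent: float
    fpr_percent: float
    fn_count: int
    mean_latency_ms: float


@dataclass(frozen=True)
class GridResult:
    """Exhaustive grid evaluation plus the selected best configuration.

    Ties on TPR are broken deterministically: lower FPR, then smaller slow
    window, then smaller fast window, then strategy order blue < red < gold.
    """

    entries: tuple = field(default_factory=tuple)
    best: GridEntry = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fast_len": [e.config.fast_len for e in self.entries],
                "slow_len": [e.config.slow_len for e in self.entries],
                "strategy": [e.strategy.value for e in self.entries],
                "tpr_percent": [e.tpr_percent for e in self.entries],
                "fpr_percent": [e.fpr_percent for e in self.entries],
                "fn_count": [e.fn_count for e in self.entries],
                "mean_latency_ms": [e.mean_latency_ms for e in self.entries],
            }
        )


def _entry_sort_key(e: GridEntry):
    return (-e.tpr_percent, e.fpr_percent, e.config.slow_len, e.config.fast_len,
            STRATEGY_ORDER[e.strategy])


def optimize_grid(
    epochs: Sequence[Epoch],
    onsets: Sequence[Optional[float]],
    fast_grid: Sequence[int] = DEFAULT_FAST_GRID,
    slow_grid: Sequence[int] = DEFAULT_SLOW_GRID,
    strategies: Sequence = (Strategy.BLUE, Strategy.RED, Strategy.GOLD),
    window: DetectionWindow = DetectionWindow(),
    target: TargetWindow = TargetWindow(),
) -> GridResult:
    """Exhaustively evaluate every (fast, slow, strategy) combination.

    ``onsets`` are per-epoch movement-onset times on the epoch-relative
    timebase (seconds from preparation onset); epochs whose onset is absent
    are excluded from scoring with a logged warning. Pairs with
    ``fast >= slow`` are skipped. Deterministic given its inputs.
    """
    pairs = [
        MAConfig(f, s) for f in fast_grid for s in slow_grid if f < s
    ]
    if not pairs:
        raise ConfigurationError("no valid fast < slow window pair in the grids")
    scored: list[tuple[Epoch, float]] = []
    for epoch, onset in zip(epochs, onsets):
        if onset is None:
            log.warning("trial %d: no movement onset; excluded from grid scoring",
                        epoch.trial.index)
            continue
        scored.append((epoch, float(onset)))
    if not scored:
        raise EvaluationError("no scorable trials (all onsets absent)")
    strategies = [Strategy.coerce(s) for s in strategies]
    entries: list[GridEntry] = []
    for cfg in pairs:
        for strat in strategies:
            outs = [
                classify_detection(detect_trial(ep, cfg, window, strat), on, target)
                for ep, on in scored
            ]
            m = participant_metrics(outs)
            entries.append(GridEntry(cfg, strat, m.tpr_percent, m.fpr_percent,
                                     m.fn_count, m.mean_latency_ms))
    best = min(entries, key=_entry_sort_key)
    return GridResult(entries=tuple(entries), best=best)
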