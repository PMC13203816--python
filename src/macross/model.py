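"""Model/Results interface over the full detection pipeline.

:class:`MovingAverageCrossoverModel` is built from per-trial epochs and
movement onsets (or directly from session streams with
:meth:`~MovingAverageCrossoverModel.from_session`); ``fit()`` runs the
per-participant parameter-grid optimization — or evaluates one fixed
configuration — and returns a :class:`CrossoverResults` carrying the grid
table, the selected configuration, per-trial outcomes, the participant
metrics, and a printable ``summary()``.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detector import (
    DEFAULT_FAST_GRID,
    DEFAULT_SLOW_GRID,
    DetectionResult,
    DetectionWindow,
    MAConfig,
    Strategy,
    detect_trial,
)
from .errors import EvaluationError
from .evaluation import (
    GridResult,
    ParticipantMetrics,
    TargetWindow,
    TrialOutcome,
    classify_detection,
    optimize_grid,
    participant_metrics,
)
from .io import AngleTrace, EventLog, Recording, segment_trials
from .preprocess import (
    DEFAULT_EPOCH_WINDOW,
    Epoch,
    detect_movement_onset,
    detrend_epoch,
    epoch_trials,
    fit_baseline,
)

__all__ = ["MovingAverageCrossoverModel", "CrossoverResults"]

log = logging.getLogger(__name__)


class MovingAverageCrossoverModel:
    """Fast/slow moving-average crossover detector fitted per participant.

    Parameters
    ----------
    epochs : sequence of Epoch
        Raw (not yet detrended) GO-trial epochs anchored at preparation
        onset. Each epoch's baseline is fitted and removed internally
        before detection.
    onsets : sequence of float or None
        Movement-onset time per epoch, seconds relative to preparation
        onset. ``None`` excludes the trial from scoring.
    window : DetectionWindow
        Detection gate (default [2, 5] s, i.e. the cue period).
    target : TargetWindow
        Latency interval around onset scored as a true positive
        (default -400 ms to +100 ms).
    fast_grid, slow_grid : sequence of int
        Candidate window lengths in samples for ``fit()`` without a fixed
        configuration.
    cue_rel_s : float
        Cue time on the epoch-relative timebase; reported onset/detection
        means are re-expressed as seconds from the cue.
    """

    def __init__(
        self,
        epochs: Sequence[Epoch],
        onsets: Sequence[Optional[float]],
        window: DetectionWindow = DetectionWindow(),
        target: TargetWindow = TargetWindow(),
        fast_grid: Sequence[int] = DEFAULT_FAST_GRID,
        slow_grid: Sequence[int] = DEFAULT_SLOW_GRID,
        strategies: Sequence = (Strategy.BLUE, Strategy.RED, Strategy.GOLD),
        cue_rel_s: float = 2.0,
    ) -> None:
        if len(epochs) != len(onsets):
            raise EvaluationError("epochs and onsets differ in length")
        if len(epochs) == 0:
            raise EvaluationError("need at least one epoch")
        self.window = window
        self.target = target
        self.fast_grid = tuple(fast_grid)
        self.slow_grid = tuple(slow_grid)
        self.strategies = tuple(Strategy.coerce(s) for s in strategies)
        self.cue_rel_s = float(cue_rel_s)
        self.onsets = list(onsets)
        self.epochs = [detrend_epoch(e, fit_baseline(e)) for e in epochs]

    @classmethod
    def from_session(
        cls,
        recording: Recording,
        events: EventLog,
        angle: AngleTrace,
        epoch_window: tuple = DEFAULT_EPOCH_WINDOW,
        max_reaction_s: float = 1.5,
        velocity_threshold: float = 5.0,
        hold_ms: float = 100.0,
        **kwargs,
    ) -> "MovingAverageCrossoverModel":
        """Build the model from raw session streams.

        Segments trials from the event log, epochs the GO trials, and
        derives per-trial movement onsets from the angle trace (first
        sustained angular velocity above ``velocity_threshold`` deg/s
        within ``max_reaction_s`` of the cue).
        """
        trials = segment_trials(events)
        epochs = epoch_trials(recording, trials, window=epoch_window)
        onsets: list[Optional[float]] = []
        for ep in epochs:
            trial = ep.trial
            mo = detect_movement_onset(
                angle, trial.cue_onset, trial.cue_onset + max_reaction_s,
                velocity_threshold=velocity_threshold, hold_ms=hold_ms,
            )
            onsets.append(None if mo.time is None else mo.time - trial.prep_onset)
        return cls(epochs, onsets, **kwargs)

    def detect(self, config: MAConfig, strategy=Strategy.GOLD) -> list[DetectionResult]:
        """Streaming detection of every epoch under one configuration."""
        strategy = Strategy.coerce(strategy)
        return [detect_trial(e, config, self.window, strategy) for e in self.epochs]

    def fit(self, config: Optional[MAConfig] = None,
            strategy=None) -> "CrossoverResults":
        """Grid-optimize (default) or evaluate one fixed configuration."""
        grid: Optional[GridResult] = None
        if config is None:
            grid = optimize_grid(
                self.epochs, self.onsets,
                fast_grid=self.fast_grid, slow_grid=self.slow_grid,
                strategies=self.strategies, window=self.window,
                target=self.target,
            )
            config = grid.best.config
            strategy = grid.best.strategy
        else:
            strategy = Strategy.coerce(strategy if strategy is not None
                                       else Strategy.GOLD)
        detections = self.detect(config, strategy)
        outcomes: list[TrialOutcome] = []
        for det, onset in zip(detections, self.onsets):
            if onset is None:
                log.warning("trial %d: no movement onset; excluded",
                            det.trial_index)
                continue
            outcomes.append(classify_detection(det, onset, self.target))
        # report timing as seconds from the GO cue
        from_cue = lambda t: None if t is None else t - self.cue_rel_s
        metrics = participant_metrics(
            outcomes,
            onsets=[from_cue(o.onset_time) for o in outcomes],
            detections=[from_cue(o.detection_time) for o in outcomes],
        )
        return CrossoverResults(self, config, strategy, detections,
                                outcomes, metrics, grid)


class CrossoverResults:
    """Fitted detector: selected configuration, outcomes, and metrics."""

    def __init__(self, model, config, strategy, detections, outcomes,
                 metrics: ParticipantMetrics, grid: Optional[GridResult]) -> None:
        self.model = model
        self.config = config
        self.strategy = strategy
        self.detections = detections
        self.outcomes = outcomes
        self.metrics = metrics
        self.grid = grid

    @property
    def tpr_percent(self) -> float:
        return self.metrics.tpr_percent

    @property
    def fpr_percent(self) -> float:
        return self.metrics.fpr_percent

    def outcomes_frame(self) -> pd.DataFrame:
        """Per-trial outcomes as a table (``trial,class,latency_ms``...)."""
        return pd.DataFrame(
            {
                "trial": [o.trial_index for o in self.outcomes],
                "class": [o.outcome for o in self.outcomes],
                "detection_rel_s": [o.detection_time for o in self.outcomes],
                "onset_rel_s": [o.onset_time for o in self.outcomes],
                "latency_ms": [o.latency_ms for o in self.outcomes],
            }
        )

    def grid_frame(self) -> Optional[pd.DataFrame]:
        return None if self.grid is None else self.grid.to_dataframe()

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.metrics
        lines = [
            "Moving-average crossover detection".center(58),
            "=" * 58,
            f"{'GO trials scored:':<30}{m.n_trials}",
            f"{'Fast/Slow MA (samples):':<30}{self.config.fast_len}/{self.config.slow_len}",
            f"{'Strategy:':<30}{self.strategy.value}",
            f"{'Detection window (s):':<30}"
            f"[{self.model.window.effective_open_s:g}, {self.model.window.close_s:g}]",
            "-" * 58,
            f"{'True positive rate (%):':<30}{m.tpr_percent:.1f}",
            f"{'False positive rate (%):':<30}{m.fpr_percent:.1f}",
            f"{'False negatives (#):':<30}{m.fn_count}",
            f"{'Mean movement onset (s):':<30}{m.mean_onset_s:.2f} "
            f"+/- {m.sd_onset_s:.2f}",
            f"{'Mean detection time (s):':<30}{m.mean_detection_s:.2f} "
            f"+/- {m.sd_detection_s:.2f}",
            f"{'Mean latency vs onset (ms):':<30}{m.mean_latency_ms:.0f}",
            "=" * 58,
            "Times in seconds from the GO cue; negative latency means the",
            "detection preceded movement onset.",
        ]
        if self.grid is not None:
            lines.insert(6, f"{'Grid entries evaluated:':<30}{len(self.grid.entries)}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CrossoverResults fast={self.config.fast_len} "
                f"slow={self.config.slow_len} strategy={self.strategy.value} "
                f"TPR={self.metrics.tpr_percent:.1f}%>")
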