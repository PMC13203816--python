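"""Causal fast/slow moving-average crossover detection.

The method borrows the classic trend-following signal from time-series
forecasting: a short (Fast) and a long (Slow) moving average are updated
sample by sample; the Fast MA crossing *under* the Slow MA marks the start
of a downward trend (the steep pre-movement negativity of an MRCP, or ERD
onset), while a cross *over* marks the reversal after the negative trough.
Following the marker colors used for these events, ``blue`` accepts only
cross-unders, ``red`` only cross-overs, and ``gold`` the first cross of
either kind after the detection window opens.

Both windows are strictly causal ring buffers with maintained running
sums, so once filled they add no latency: each streamed sample costs two
additions, two subtractions and one comparison.

Tie semantics (the difference being exactly zero) are deterministic: an
exact tie contributes no event and the previous non-zero sign is carried
forward, so flat signals never fire. The sign state is tracked
continuously from the moment the buffers fill — i.e. during the
preparation period, before the detection window opens — which is what
makes the *kind* of the first in-window cross depend on the relative
position of the two averages at window opening.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .preprocess import Epoch

__all__ = [
    "MAConfig",
    "DetectionWindow",
    "CrossEvent",
    "Strategy",
    "DetectorState",
    "DetectionResult",
    "detect_trial",
    "crosses_batch",
    "emit_trigger",
    "DEFAULT_FAST_GRID",
    "DEFAULT_SLOW_GRID",
]

#: Per-participant optimization grids (window lengths in samples at 300 Hz).
DEFAULT_FAST_GRID = (50, 100, 150)
DEFAULT_SLOW_GRID = (100, 150, 200)

#: Re-anchor the maintained running sums by full recomputation this often,
#: bounding floating-point drift on arbitrarily long streams.
REANCHOR_INTERVAL = 100_000


@dataclass(frozen=True)
class MAConfig:
    """Fast and Slow moving-average window lengths, in samples."""

    fast_len: int
    slow_len: int

    def __post_init__(self) -> None:
        if self.fast_len < 1 or self.slow_len < 1:
            raise ConfigurationError("window lengths must be positive")
        if self.fast_len >= self.slow_len:
            raise ConfigurationError(
                f"fast window ({self.fast_len}) must be shorter than slow "
                f"window ({self.slow_len})"
            )


@dataclass(frozen=True)
class DetectionWindow:
    """Detection gate in seconds relative to preparation onset.

    Defaults to ``[2, 5]``: the gate opens at the GO/NO-GO cue (after the
    2 s preparation) and stays open for the 3 s cue period. ``delay_s``
    shifts the opening later for participants with consistently delayed
    reactions (0.25 s was used for one such participant).
    """

    open_s: float = 2.0
    close_s: float = 5.0
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ConfigurationError("window delay must be non-negative")
        if not self.open_s + self.delay_s < self.close_s:
            raise ConfigurationError(
                f"window opens at {self.open_s + self.delay_s} s, at or after "
                f"it closes ({self.close_s} s)"
            )

    @property
    def effective_open_s(self) -> float:
        return self.open_s + self.delay_s


@dataclass(frozen=True)
class CrossEvent:
    """A fast/slow crossing: ``under`` (blue) or ``over`` (red)."""

    kind: str
    sample_index: int
    time: float


class Strategy(str, Enum):
    """Which cross kinds count as a detection."""

    BLUE = "blue"   # cross-under only
    RED = "red"     # cross-over only
    GOLD = "gold"   # first cross of either kind

    def accepts(self, kind: str) -> bool:
        if self is Strategy.BLUE:
            return kind == "under"
        if self is Strategy.RED:
            return kind == "over"
        return True

    @classmethod
    def coerce(cls, value) -> "Strategy":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ConfigurationError(f"unknown strategy {value!r}") from None


#: Deterministic order used to break exact performance ties in grid search.
STRATEGY_ORDER = {Strategy.BLUE: 0, Strategy.RED: 1, Strategy.GOLD: 2}


class DetectorState:
    """Streaming state: two ring buffers with running sums and a sign memory.

    Feed samples in time order through :meth:`update`; a
    :class:`CrossEvent` is returned on the sample at which the sign of
    ``fastMA - slowMA`` changes (relative to the last *non-zero* sign).
    No event can be emitted before both buffers are full.

    ``rate`` and ``start_time`` only decorate emitted events with a time
    stamp (``start_time + index / rate``); they do not affect detection.
    """

    def __init__(self, config: MAConfig, rate: float = 1.0,
                 start_time: float = 0.0) -> None:
        self.config = config
        self.rate = float(rate)
        self.start_time = float(start_time)
        self._fast: deque = deque()
        self._slow: deque = deque()
        self._fast_sum = 0.0
        self._slow_sum = 0.0
        self.prev_diff_sign = 0
        self.n_seen = 0

    @property
    def buffers_full(self) -> bool:
        return len(self._slow) == self.config.slow_len

    def update(self, value: float) -> Optional[CrossEvent]:
        """Push one sample; return a CrossEvent if this sample crosses."""
        value = float(value)
        index = self.n_seen
        self.n_seen = index + 1

        fast, slow = self._fast, self._slow
        cfg = self.config
        if len(fast) == cfg.fast_len:
            self._fast_sum -= fast.popleft()
        fast.append(value)
        self._fast_sum += value
        if len(slow) == cfg.slow_len:
            self._slow_sum -= slow.popleft()
        slow.append(value)
        self._slow_sum += value

        if self.n_seen % REANCHOR_INTERVAL == 0:
            self._fast_sum = math.fsum(fast)
            self._slow_sum = math.fsum(slow)

        if len(slow) < cfg.slow_len:
            return None
        d = self._fast_sum / cfg.fast_len - self._slow_sum / cfg.slow_len
        if d == 0.0:
            return None  # exact tie: carry the previous sign, no event
        sign = 1 if d > 0.0 else -1
        if sign == self.prev_diff_sign:
            return None
        self.prev_diff_sign = sign
        return CrossEvent(
            kind="over" if sign > 0 else "under",
            sample_index=index,
            time=self.start_time + index / self.rate,
        )

    def run(self, values: Sequence[float]) -> list[CrossEvent]:
        """Stream a whole sequence; collect every emitted event."""
        out = []
        up = self.update
        for v in values:
            ev = up(v)
            if ev is not None:
                out.append(ev)
        return out


@dataclass(frozen=True)
class DetectionResult:
    """The per-trial first qualifying detection (or absence thereof)."""

    trial_index: int
    cross: Optional[CrossEvent]
    strategy: Strategy
    config: MAConfig
    window: DetectionWindow

    @property
    def detected(self) -> bool:
        return self.cross is not None


def detect_trial(
    epoch: Epoch,
    config: MAConfig,
    window: DetectionWindow = DetectionWindow(),
    strategy: Strategy = Strategy.GOLD,
) -> DetectionResult:
    """Run the streaming detector over one (detrended) epoch.

    Samples are streamed from relative time 0 (preparation onset) onward,
    so the buffers fill during the preparation period; crossings before the
    window opens update the sign state but are ignored, and the first
    in-window cross accepted by the strategy is returned. A cross exactly
    at the window close is accepted (closed interval).
    """
    strategy = Strategy.coerce(strategy)
    rate = epoch.rate
    if config.slow_len / rate >= window.open_s:
        raise ConfigurationError(
            f"slow window of {config.slow_len} samples ({config.slow_len / rate:.3f} s) "
            f"cannot fill before the detection window opens at {window.open_s} s"
        )
    if epoch.epoch_start > 0 or epoch.epoch_end < window.close_s:
        raise ConfigurationError(
            f"epoch [{epoch.epoch_start}, {epoch.epoch_end}] s does not cover "
            f"[0, {window.close_s}] s"
        )
    j0 = int(round(-epoch.epoch_start * rate))
    rel = epoch.rel_times
    state = DetectorState(config, rate=rate, start_time=float(rel[j0]))
    open_t = window.effective_open_s
    for value in epoch.samples[j0:]:
        ev = state.update(value)
        if ev is None:
            continue
        if ev.time > window.close_s:
            break
        if ev.time >= open_t and strategy.accepts(ev.kind):
            return DetectionResult(epoch.trial.index, ev, strategy, config, window)
    return DetectionResult(epoch.trial.index, None, strategy, config, window)


def crosses_batch(
    values: Sequence[float],
    config: MAConfig,
    rate: float = 1.0,
    start_time: float = 0.0,
) -> list[CrossEvent]:
    """Brute-force oracle: compute full MA arrays and list every crossing.

    Computes the moving averages directly from cumulative sums (no
    incremental state) with tie semantics identical to
    :meth:`DetectorState.update`; used to cross-check the streaming path.
    """
    arr = np.asarray(values, dtype=float)
    f, s = config.fast_len, config.slow_len
    if len(arr) < s:
        raise DataError(f"need at least slow_len={s} samples, got {len(arr)}")
    c = np.concatenate(([0.0], np.cumsum(arr)))
    idx = np.arange(s - 1, len(arr))
    fast_ma = (c[idx + 1] - c[idx + 1 - f]) / f
    slow_ma = (c[idx + 1] - c[idx + 1 - s]) / s
    signs = np.sign(fast_ma - slow_ma).astype(int)
    events: list[CrossEvent] = []
    nz = np.flatnonzero(signs)
    prev = 0
    for k in nz:
        sgn = signs[k]
        if sgn != prev:
            i = int(idx[k])
            events.append(CrossEvent(kind="over" if sgn > 0 else "under",
                                     sample_index=i,
                                     time=start_time + i / rate))
            prev = sgn
    return events


def emit_trigger(result: DetectionResult) -> Optional[tuple[str, float]]:
    """Stimulation trigger marker for a detection, or absent.

    Hardware control is out of scope; the trigger is reduced to a
    timestamped ``stim_trigger`` marker mergeable with an event log.
    """
    if result.cross is None:
        return None
    return ("stim_trigger", result.cross.time)
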