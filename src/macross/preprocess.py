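"""Trial epoching, baseline detrending, offline band filters, ERD courses,
and IMU movement-onset detection.

The streaming detector consumes *detrended raw* samples only; the band-pass
and band-power operations here exist for offline review (slow 0.5-5 Hz MRCP
morphology, alpha/low-beta desynchronization) and are never part of the
simulated real-time path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .errors import ConfigurationError, DataError
from .io import AngleTrace, Recording, TrialRecord

__all__ = [
    "Epoch",
    "BaselineFit",
    "MovementOnset",
    "BandPowerCourse",
    "epoch_trials",
    "fit_baseline",
    "detrend_epoch",
    "bandpass",
    "band_power_course",
    "detect_movement_onset",
]

log = logging.getLogger(__name__)

#: Trial epoch span relative to preparation onset, seconds.
DEFAULT_EPOCH_WINDOW = (-6.0, 5.0)


@dataclass(frozen=True)
class Epoch:
    """A per-trial signal slice on a trial-relative timebase.

    Relative time 0 is anchored at the preparation onset (nearest sample);
    the baseline is the sub-span ``[epoch_start, 0)`` — by default the last
    6 s of the 8 s rest period preceding preparation.
    """

    trial: TrialRecord
    samples: np.ndarray
    rate: float
    epoch_start: float = DEFAULT_EPOCH_WINDOW[0]
    epoch_end: float = DEFAULT_EPOCH_WINDOW[1]

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        expected = (self.epoch_end - self.epoch_start) * self.rate
        if abs(len(arr) - expected) > 1:
            raise DataError(
                f"epoch length {len(arr)} inconsistent with window "
                f"[{self.epoch_start}, {self.epoch_end}] at {self.rate} Hz"
            )
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def rel_times(self) -> np.ndarray:
        """Times relative to preparation onset, seconds."""
        return self.epoch_start + np.arange(len(self.samples)) / self.rate

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.rel_times < 0.0


@dataclass(frozen=True)
class BaselineFit:
    """Ordinary least-squares line through the baseline samples.

    ``intercept`` is the fitted value at relative time 0 (preparation
    onset); ``slope`` is in microvolts per second.
    """

    slope: float
    intercept: float
    residual_sd: float


@dataclass(frozen=True)
class MovementOnset:
    """Detected ankle movement onset (session timebase), or absent."""

    time: float | None
    velocity_threshold: float = 5.0
    hold_ms: float = 100.0
    search_start: float = 0.0
    search_end: float = 0.0

    @property
    def present(self) -> bool:
        return self.time is not None


@dataclass(frozen=True)
class BandPowerCourse:
    """Sliding-window band power as percent change vs. baseline power.

    ``erd_percent = 100 * (P(t) - P_base) / P_base``; negative values mean
    desynchronization.
    """

    times: np.ndarray
    erd_percent: np.ndarray
    band: tuple


def epoch_trials(
    recording: Recording,
    trials: Sequence[TrialRecord],
    window: tuple = DEFAULT_EPOCH_WINDOW,
    include_nogo: bool = False,
) -> list[Epoch]:
    """Slice the recording into per-trial epochs anchored at preparation onset.

    One epoch per GO trial (NO-GO trials are included only on request).
    Trials whose window falls outside the recording are dropped with a
    logged warning rather than raising.
    """
    start_s, end_s = float(window[0]), float(window[1])
    if not (start_s < 0.0 < end_s):
        raise ConfigurationError(f"epoch window must straddle 0, got {window}")
    rate = recording.rate
    n = int(round((end_s - start_s) * rate))
    epochs: list[Epoch] = []
    for trial in trials:
        if not trial.is_go and not include_nogo:
            continue
        i0 = int(round((trial.prep_onset - recording.start_time) * rate))
        a = i0 + int(round(start_s * rate))
        if a < 0 or a + n > len(recording.samples):
            log.warning(
                "trial %d: window [%g, %g] s around prep onset %g s exceeds "
                "recording bounds; trial dropped",
                trial.index, start_s, end_s, trial.prep_onset,
            )
            continue
        epochs.append(
            Epoch(trial=trial, samples=recording.samples[a:a + n],
                  rate=rate, epoch_start=start_s, epoch_end=end_s)
        )
    return epochs


def fit_baseline(epoch: Epoch) -> BaselineFit:
    """Fit an OLS line to the baseline span of an epoch.

    The line is parameterized on relative time, so ``intercept`` is the
    predicted value at preparation onset.
    """
    mask = epoch.baseline_mask
    t = epoch.rel_times[mask]
    y = epoch.samples[mask]
    if len(t) < 10:
        raise DataError(f"baseline has only {len(t)} samples; need at least 10")
    if np.ptp(t) == 0:
        raise DataError("degenerate baseline: constant time axis")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    dof = max(len(t) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return BaselineFit(slope=float(slope), intercept=float(intercept),
                       residual_sd=residual_sd)


def detrend_epoch(epoch: Epoch, fit: BaselineFit) -> Epoch:
    """Subtract the extrapolated baseline line from every sample.

    The line is extended over the whole epoch (baseline included), so the
    detrended baseline has mean ~0 and the trial-period samples are freed
    of the slow drift present during rest.
    """
    line = fit.intercept + fit.slope * epoch.rel_times
    return replace(epoch, samples=epoch.samples - line)


def _band_sos(low_hz: float, high_hz: float, rate: float, order: int = 4):
    if not (0.0 < low_hz < high_hz < rate / 2.0):
        raise ConfigurationError(
            f"invalid band ({low_hz}, {high_hz}) Hz at rate {rate} Hz"
        )
    return sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=rate, output="sos")


def bandpass(epoch: Epoch, low_hz: float, high_hz: float) -> Epoch:
    """Zero-phase Butterworth band-pass (offline review only).

    The streaming detector never sees filtered data; this exists to inspect
    the slow 0.5-5 Hz MRCP morphology and narrow-band oscillations after
    the fact.
    """
    sos = _band_sos(low_hz, high_hz, epoch.rate)
    return replace(epoch, samples=sp_signal.sosfiltfilt(sos, epoch.samples))


def band_power_course(
    epoch: Epoch,
    band: tuple = (8.0, 13.0),
    baseline_span: tuple = (-6.0, 0.0),
    window_s: float = 0.5,
    overlap: float = 0.5,
    edge_guard_s: float = 0.25,
) -> BandPowerCourse:
    """Sliding-window band power expressed as % change vs. baseline power.

    Band-pass the epoch, average the squared amplitude in rectangular
    windows (default 0.5 s, 50% overlap), and normalize by the mean power
    of the windows fully inside ``baseline_span``. Windows overlapping the
    outermost ``edge_guard_s`` of the epoch are dropped (zero-phase filter
    edge transients corrupt them).
    """
    low, high = float(band[0]), float(band[1])
    if window_s * low < 3.0:
        raise ConfigurationError(
            f"window of {window_s} s holds fewer than 3 cycles at {low} Hz"
        )
    b0, b1 = float(baseline_span[0]), float(baseline_span[1])
    if b0 < epoch.epoch_start or b1 > epoch.epoch_end:
        raise ConfigurationError("baseline span must lie inside the epoch")
    filtered = bandpass(epoch, low, high).samples
    rate = epoch.rate
    win = int(round(window_s * rate))
    hop = max(int(round(win * (1.0 - overlap))), 1)
    guard = int(round(edge_guard_s * rate))
    starts = np.arange(guard, len(filtered) - win - guard + 1, hop)
    if len(starts) == 0:
        raise ConfigurationError("epoch too short for the requested windows")
    power = np.array([np.mean(filtered[s:s + win] ** 2) for s in starts])
    centers = epoch.epoch_start + (starts + win / 2.0) / rate
    base = (centers - window_s / 2.0 >= b0) & (centers + window_s / 2.0 <= b1)
    if not np.any(base):
        raise ConfigurationError("baseline span holds no complete window")
    p_base = float(np.mean(power[base]))
    if p_base <= 0:
        raise DataError("baseline band power is zero; cannot normalize")
    erd = 100.0 * (power - p_base) / p_base
    return BandPowerCourse(times=centers, erd_percent=erd, band=(low, high))


def detect_movement_onset(
    angle: AngleTrace,
    cue_onset: float,
    search_end: float,
    velocity_threshold: float = 5.0,
    hold_ms: float = 100.0,
) -> MovementOnset:
    """First sustained supra-threshold angular velocity after the cue.

    Onset is the first time ``t >= cue_onset`` at which the
    centered-difference angular velocity exceeds ``velocity_threshold``
    (deg/s) continuously for ``hold_ms``. Movement before the cue is never
    reported (the search starts at the cue). Returns an absent onset when
    the criterion is never met.
    """
    if search_end <= cue_onset:
        raise ConfigurationError("search window is empty")
    times = angle.times
    in_search = (times >= cue_onset) & (times <= search_end)
    if not np.any(in_search):
        raise ConfigurationError("search window lies outside the angle trace")
    velocity = np.gradient(angle.samples, 1.0 / angle.rate)
    hold = max(int(round(hold_ms / 1000.0 * angle.rate)), 1)
    above = velocity > velocity_threshold
    candidates = np.flatnonzero(in_search & above)
    params = dict(velocity_threshold=velocity_threshold, hold_ms=hold_ms,
                  search_start=cue_onset, search_end=search_end)
    for i in candidates:
        if i + hold <= len(above) and np.all(above[i:i + hold]):
            return MovementOnset(time=float(times[i]), **params)
    return MovementOnset(time=None, **params)
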