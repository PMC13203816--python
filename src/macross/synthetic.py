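"""Synthetic session generator.

Produces complete cued GO/NO-GO ankle-dorsiflexion sessions — single-channel
EEG, event log, ankle-angle trace, and ground-truth movement onsets — with
the statistical structure the detector assumes:

* trial layout 8 s rest -> 2 s preparation -> 3 s cue -> 1.2 s feedback,
  with a NO-GO cue on ~25% of trials;
* an MRCP template per GO trial: a shallow negative ramp starting ~1.5 s
  before movement, steepening ~450 ms before movement to a negative trough
  at movement onset, then a positive rebound;
* a band-limited alpha-range oscillation running through the whole session
  whose envelope dips (ERD) before each GO movement and recovers after it;
* 1/f ("pink") background noise;
* reaction times drawn from a truncated normal (all movements within 1.5 s
  of the GO cue).

Everything is fully determined by ``ParadigmConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy import signal as sp_signal

from .errors import ConfigurationError
from .io import AngleTrace, EventLog, Recording

__all__ = [
    "ParadigmConfig",
    "MRCPModel",
    "ERDModel",
    "NoiseModel",
    "ReactionModel",
    "GroundTruthTrial",
    "GroundTruth",
    "SessionData",
    "make_pink_noise",
    "make_mrcp_waveform",
    "make_erd_oscillation",
    "make_angle_trace",
    "simulate_session",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial structure and session bookkeeping."""

    rest_s: float = 8.0
    prep_s: float = 2.0
    cue_s: float = 3.0
    feedback_s: float = 1.2
    nogo_prob: float = 0.25
    n_go_trials: int = 15
    rate: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rest_s", "prep_s", "cue_s", "feedback_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.nogo_prob < 1.0:
            raise ConfigurationError("nogo_prob must lie in [0, 1)")
        if self.n_go_trials < 1:
            raise ConfigurationError("need at least one GO trial")

    @property
    def trial_s(self) -> float:
        return self.rest_s + self.prep_s + self.cue_s + self.feedback_s


@dataclass(frozen=True)
class MRCPModel:
    """Piecewise-linear MRCP/CNV template anchored at movement onset.

    Zero until ``early_onset_s`` before movement; shallow ramp to
    ``early_amp_uv`` by ``steep_onset_s`` before movement; steep ramp to
    ``trough_amp_uv`` at movement onset; rebound to ``rebound_amp_uv``
    over ``rebound_s``; then return to zero over ``decay_s``.
    """

    early_onset_s: float = 1.5
    steep_onset_s: float = 0.45
    early_amp_uv: float = -3.0
    trough_amp_uv: float = -8.0
    rebound_s: float = 0.4
    rebound_amp_uv: float = 2.0
    decay_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.trough_amp_uv < self.early_amp_uv < 0.0:
            raise ConfigurationError("need trough_amp < early_amp < 0")
        if self.steep_onset_s >= self.early_onset_s:
            raise ConfigurationError("steep onset must follow the early onset")
        if self.rebound_s <= 0:
            raise ConfigurationError("rebound span must be positive")


@dataclass(frozen=True)
class ERDModel:
    """Alpha-range oscillation with a pre-movement envelope dip.

    The envelope drops to ``1 - attenuation_frac`` of its resting value
    from ``erd_onset_s`` before movement until ``recovery_s`` after it.
    ``carrier_amp_uv`` plays the role of a sinusoid amplitude: the carrier's
    RMS is ``carrier_amp_uv / sqrt(2)``.
    """

    band_hz: tuple = (8.0, 13.0)
    carrier_amp_uv: float = 4.0
    attenuation_frac: float = 0.5
    erd_onset_s: float = 0.8
    recovery_s: float = 1.0
    ramp_s: float = 0.1  # cosine transition width of the envelope edges

    def __post_init__(self) -> None:
        if not 0.0 <= self.attenuation_frac <= 1.0:
            raise ConfigurationError("attenuation_frac must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """1/f^exponent background noise scaled to a target standard deviation."""

    pink_exponent: float = 1.0
    noise_sd_uv: float = 2.0

    def __post_init__(self) -> None:
        if self.pink_exponent < 0 or self.noise_sd_uv < 0:
            raise ConfigurationError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ReactionModel:
    """Truncated-normal reaction time from the GO cue to movement onset."""

    mean_s: float = 0.45
    sd_s: float = 0.10
    min_s: float = 0.15
    max_s: float = 1.5

    def __post_init__(self) -> None:
        if not self.min_s <= self.mean_s <= self.max_s:
            raise ConfigurationError("need min_s <= mean_s <= max_s")
        if self.sd_s < 0:
            raise ConfigurationError("sd_s must be non-negative")

    def draw(self, rng: np.random.Generator) -> float:
        """Rejection-sample one truncated-normal reaction time."""
        if self.sd_s == 0:
            return self.mean_s
        for _ in range(1000):
            rt = rng.normal(self.mean_s, self.sd_s)
            if self.min_s <= rt <= self.max_s:
                return float(rt)
        return float(np.clip(rng.normal(self.mean_s, self.sd_s),
                             self.min_s, self.max_s))


@dataclass(frozen=True)
class GroundTruthTrial:
    """Generator bookkeeping for one GO trial (session timebase)."""

    trial_index: int
    cue_onset_s: float
    movement_onset_s: float
    mrcp_trough_s: float
    erd_onset_s: float


@dataclass(frozen=True)
class GroundTruth:
    trials: tuple = field(default_factory=tuple)

    @property
    def onsets(self) -> list[float]:
        return [t.movement_onset_s for t in self.trials]


class SessionData(NamedTuple):
    recording: Recording
    events: EventLog
    angle: AngleTrace
    truth: GroundTruth


# ---------------------------------------------------------------------------
# component waveforms
# ---------------------------------------------------------------------------

def make_pink_noise(
    n: int,
    rate: float,
    model: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zero-mean noise with spectral density ~ 1/f^exponent, sd-scaled.

    Shaped in the frequency domain: white Gaussian noise is filtered by
    f^(-exponent/2) (DC removed), then rescaled to ``noise_sd_uv``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if model.noise_sd_uv == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-model.pink_exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = np.std(x)
    if sd > 0:
        x *= model.noise_sd_uv / sd
    return x


def _mrcp_template(t_rel_movement: np.ndarray, model: MRCPModel) -> np.ndarray:
    """Evaluate the piecewise-smooth MRCP template (t relative to movement).

    Linear segments for the early and steep descents; the post-trough
    recovery is an ease-out curve (steepest right at the trough, levelling
    off toward the rebound value) — the negative peak is a sharp reversal,
    not a plateau, which is what lets a cross-over mark it promptly.
    """
    t = np.asarray(t_rel_movement, dtype=float)
    out = np.zeros_like(t)
    # shallow linear ramp: 0 -> early_amp over [-early_onset, -steep_onset]
    m1 = (t >= -model.early_onset_s) & (t < -model.steep_onset_s)
    out[m1] = model.early_amp_uv * (
        (t[m1] + model.early_onset_s) / (model.early_onset_s - model.steep_onset_s)
    )
    # steep linear ramp: early_amp -> trough over [-steep_onset, 0]
    m2 = (t >= -model.steep_onset_s) & (t < 0.0)
    out[m2] = model.early_amp_uv + (model.trough_amp_uv - model.early_amp_uv) * (
        (t[m2] + model.steep_onset_s) / model.steep_onset_s
    )
    # sharp reversal: trough -> rebound_amp over [0, rebound_s] as a
    # saturating exponential (time constant rebound_s/4, normalized to
    # land exactly on rebound_amp at rebound_s)
    m3 = (t >= 0.0) & (t < model.rebound_s)
    x = t[m3] / model.rebound_s
    out[m3] = model.trough_amp_uv + (model.rebound_amp_uv - model.trough_amp_uv) * (
        (1.0 - np.exp(-4.0 * x)) / (1.0 - np.exp(-4.0))
    )
    # linear return to baseline over decay_s
    m4 = (t >= model.rebound_s) & (t < model.rebound_s + model.decay_s)
    out[m4] = model.rebound_amp_uv * (
        1.0 - (t[m4] - model.rebound_s) / model.decay_s
    )
    return out


def make_mrcp_waveform(
    rate: float,
    model: MRCPModel = MRCPModel(),
    movement_rel_s: float = 0.0,
    duration_s: Optional[float] = None,
    start_s: float = 0.0,
) -> np.ndarray:
    """Sample the MRCP template on a uniform grid.

    ``movement_rel_s`` places the trough relative to the grid origin
    ``start_s``. The default duration just covers the template support.
    """
    if duration_s is None:
        duration_s = movement_rel_s + model.rebound_s + model.decay_s - start_s
    n = int(round(duration_s * rate))
    t = start_s + np.arange(n) / rate
    return _mrcp_template(t - movement_rel_s, model)


def _erd_envelope(t_rel_movement: np.ndarray, model: ERDModel) -> np.ndarray:
    """Smooth envelope: 1 at rest, 1 - attenuation inside the ERD span."""
    depth = model.attenuation_frac
    if depth == 0:
        return np.ones_like(t_rel_movement)
    r = model.ramp_s
    a, b = -model.erd_onset_s, model.recovery_s

    def smooth_step(x):  # 0 -> 1 over [0, 1], cosine-shaped
        x = np.clip(x, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * x))

    down = smooth_step((t_rel_movement - (a - r)) / r)
    up = smooth_step((t_rel_movement - b) / r)
    return 1.0 - depth * (down - up)


def _band_carrier(n: int, rate: float, model: ERDModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Band-limited random-phase carrier with RMS = carrier_amp / sqrt(2)."""
    if model.carrier_amp_uv == 0 or n == 0:
        return np.zeros(n)
    low, high = model.band_hz
    pad = int(round(2.0 * rate))  # discard filter edge transients
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=rate,
                           output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    sd = np.std(x)
    if sd > 0:
        x = x * (model.carrier_amp_uv / np.sqrt(2.0)) / sd
    return x


def make_erd_oscillation(
    rate: float,
    model: ERDModel = ERDModel(),
    movement_rel_s: float = 0.0,
    duration_s: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Band-limited oscillation whose envelope dips around movement.

    Band power inside the suppressed span is ~(1 - attenuation_frac)^2 of
    the resting band power.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    carrier = _band_carrier(n, rate, model, rng)
    return carrier * _erd_envelope(t - movement_rel_s, model)


def _angle_noise(n: int, rate: float, sd: float, rng: np.random.Generator,
                 cutoff_hz: float = 4.0) -> np.ndarray:
    """Band-limited angle jitter (sensor-fusion output wobbles slowly).

    White per-sample noise would imply tens of deg/s of spurious angular
    velocity at 300 Hz, which no fused IMU angle exhibits; the jitter is
    low-passed and rescaled so its total SD is ``sd`` degrees.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    pad = int(round(2.0 * rate))  # discard filter edge transients
    sos = sp_signal.butter(4, cutoff_hz, btype="lowpass", fs=rate,
                           output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    x_sd = np.std(x)
    if x_sd > 0:
        x = x * (sd / x_sd)
    return x


def _angle_step(t_rel_onset: np.ndarray, amplitude_deg: float,
                rise_s: float) -> np.ndarray:
    """Smoothstep dorsiflexion: 0 before onset, plateau after the rise."""
    x = np.clip(t_rel_onset / rise_s, 0.0, 1.0)
    return amplitude_deg * x * x * (3.0 - 2.0 * x)


def make_angle_trace(
    rate: float,
    onset_s: float,
    amplitude_deg: float = 15.0,
    rise_s: float = 0.4,
    noise_sd_deg: float = 0.2,
    seed: Optional[int] = None,
    duration_s: Optional[float] = None,
    start_time: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> AngleTrace:
    """Flat baseline, smooth sigmoidal rise of ``amplitude_deg`` at
    ``onset_s``, plateau, plus additive measurement noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = onset_s - start_time + 3.0
    n = int(round(duration_s * rate))
    t = start_time + np.arange(n) / rate
    samples = _angle_step(t - onset_s, amplitude_deg, rise_s)
    samples = samples + _angle_noise(n, rate, noise_sd_deg, rng)
    return AngleTrace(samples=samples, rate=rate, start_time=start_time)


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------

def simulate_session(
    paradigm: ParadigmConfig = ParadigmConfig(),
    mrcp: MRCPModel = MRCPModel(),
    erd: ERDModel = ERDModel(),
    noise: NoiseModel = NoiseModel(),
    reaction: ReactionModel = ReactionModel(),
    angle_amplitude_deg: float = 15.0,
    angle_rise_s: float = 0.4,
    angle_noise_sd_deg: float = 0.2,
) -> SessionData:
    """Generate one complete session on a single shared timebase.

    Trials run back to back (rest -> preparation -> cue -> feedback); the
    NO-GO flag is drawn per trial and trials continue until
    ``paradigm.n_go_trials`` GO trials have been produced. Each GO trial
    draws a reaction time, places the movement onset at cue + reaction,
    and anchors the MRCP template, the ERD envelope dip, and the ankle
    rise to that onset. NO-GO trials carry only noise plus the stationary
    oscillation. Fully determined by ``paradigm.seed``.
    """
    rng = np.random.default_rng(paradigm.seed)
    rate = paradigm.rate

    # trial plan
    trial_starts: list[float] = []
    is_nogo: list[bool] = []
    n_go = 0
    t = 0.0
    while n_go < paradigm.n_go_trials:
        nogo = bool(rng.random() < paradigm.nogo_prob)
        trial_starts.append(t)
        is_nogo.append(nogo)
        if not nogo:
            n_go += 1
        t += paradigm.trial_s

    duration = t + 1.0  # 1 s tail after the last feedback period
    n = int(round(duration * rate))
    times = np.arange(n) / rate

    # events
    evs: list[tuple] = []
    truth_trials: list[GroundTruthTrial] = []
    onsets: list[tuple] = []  # (onset_s,) per GO trial for angle/waveforms
    for idx, (t0, nogo) in enumerate(zip(trial_starts, is_nogo)):
        prep = t0 + paradigm.rest_s
        cue = prep + paradigm.prep_s
        feedback = cue + paradigm.cue_s
        evs += [("rest_start", t0), ("prep_start", prep),
                ("cue_nogo" if nogo else "cue_go", cue),
                ("feedback_start", feedback)]
        if not nogo:
            rt = reaction.draw(rng)
            onset = cue + rt
            onsets.append(onset)
            truth_trials.append(GroundTruthTrial(
                trial_index=idx, cue_onset_s=cue, movement_onset_s=onset,
                mrcp_trough_s=onset, erd_onset_s=onset - erd.erd_onset_s,
            ))
    evs.append(("session_end", duration))

    # EEG: pink noise + enveloped carrier + MRCP templates
    eeg = make_pink_noise(n, rate, noise, rng=rng)
    carrier = _band_carrier(n, rate, erd, rng)
    envelope = np.ones(n)
    for onset in onsets:
        envelope *= _erd_envelope(times - onset, erd)
        eeg += _mrcp_template(times - onset, mrcp)
    eeg = eeg + carrier * envelope

    # ankle angle: one smoothstep rise per GO onset; each plateau relaxes
    # back to baseline before the next trial's rest period ends
    angle = np.zeros(n)
    relax = 1.0  # seconds to return to neutral after the feedback period
    for onset, tt in zip(onsets, truth_trials):
        rise = _angle_step(times - onset, angle_amplitude_deg, angle_rise_s)
        trial_end = trial_starts[tt.trial_index] + paradigm.trial_s
        fall = _angle_step(times - trial_end, angle_amplitude_deg, relax)
        angle += rise - fall
    angle = angle + _angle_noise(n, rate, angle_noise_sd_deg, rng)

    return SessionData(
        recording=Recording(samples=eeg, rate=rate, start_time=0.0),
        events=EventLog(tuple(evs)),
        angle=AngleTrace(samples=angle, rate=rate, start_time=0.0),
        truth=GroundTruth(trials=tuple(truth_trials)),
    )
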