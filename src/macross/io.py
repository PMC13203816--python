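"""Recordings, event logs, angle traces: containers, delimited I/O, streaming replay.

All times are session-relative seconds on a single shared timebase whose
origin is the first EEG sample. The canonical on-disk representation is
comma-separated text with a header row and ``.`` decimals, so fixtures are
bit-stable across platforms:

* recording file: columns ``time_s,value_uv``
* event file:     columns ``label,time_s``
* angle file:     columns ``time_s,angle_deg``

EDF reading is provided as a convenience for single-channel exports and
requires :mod:`mne` (imported lazily).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import DataError, FormatError

__all__ = [
    "EVENT_LABELS",
    "Recording",
    "EventLog",
    "AngleTrace",
    "TrialRecord",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_angle_trace",
    "write_angle_trace",
    "stream_replay",
    "segment_trials",
]

#: Paradigm marker vocabulary. Anything else is rejected at read time.
EVENT_LABELS = frozenset(
    {"rest_start", "prep_start", "cue_go", "cue_nogo", "feedback_start", "session_end"}
)

_CUE_LABELS = ("cue_go", "cue_nogo")

#: Maximum tolerated deviation of any inter-sample interval from the median,
#: as a fraction of the median interval. Larger deviations are rejected as
#: non-uniform sampling rather than resampled.
UNIFORMITY_TOL = 0.10


@dataclass(frozen=True)
class Recording:
    """A uniformly sampled single-channel EEG recording.

    Parameters
    ----------
    samples : array-like
        Signal values in microvolts.
    rate : float
        Sampling rate in Hz (default 300, the dry-headset streaming rate).
    channel, reference : str
        Electrode labels; the method uses Cz referenced to Pz.
    start_time : float
        Session time of the first sample, seconds. Sample ``i`` sits at
        ``start_time + i / rate``.
    """

    samples: np.ndarray
    rate: float = 300.0
    channel: str = "Cz"
    reference: str = "Pz"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise DataError("recording must hold at least one sample")
        if not self.rate > 0:
            raise DataError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        """Session times of all samples, seconds."""
        return self.start_time + np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class AngleTrace:
    """Ankle dorsiflexion angle (degrees) on the shared session timebase."""

    samples: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise DataError("angle trace must hold at least one sample")
        if not self.rate > 0:
            raise DataError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.rate


@dataclass(frozen=True)
class EventLog:
    """Ordered paradigm markers ``(label, time_s)``.

    Invariants enforced at construction: labels belong to
    :data:`EVENT_LABELS`, times are non-decreasing, and every
    ``prep_start`` is followed by exactly one GO/NO-GO cue before the next
    ``prep_start`` (the final preparation may still be awaiting its cue;
    :func:`segment_trials` rejects that case).
    """

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        evs = tuple((str(lbl), float(t)) for lbl, t in self.events)
        for lbl, _ in evs:
            if lbl not in EVENT_LABELS:
                raise FormatError(f"unknown event label {lbl!r}")
        times = [t for _, t in evs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DataError("event times must be non-decreasing")
        self._check_trial_structure(evs)
        object.__setattr__(self, "events", evs)

    @staticmethod
    def _check_trial_structure(evs: Sequence[tuple]) -> None:
        pending_cue = False  # a prep_start has been seen without its cue
        for lbl, t in evs:
            if lbl == "prep_start":
                if pending_cue:
                    raise DataError(
                        f"prep_start at {t} s follows a preparation with no cue"
                    )
                pending_cue = True
            elif lbl in _CUE_LABELS:
                if not pending_cue:
                    raise DataError(f"{lbl} at {t} s has no preceding prep_start")
                pending_cue = False

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def of_label(self, label: str) -> list[float]:
        """Times of all events carrying ``label``."""
        return [t for lbl, t in self.events if lbl == label]


@dataclass(frozen=True)
class TrialRecord:
    """One paradigm trial: a preparation onset and the cue that followed it."""

    index: int
    prep_onset: float
    cue_label: str
    cue_onset: float

    def __post_init__(self) -> None:
        if self.cue_label not in _CUE_LABELS:
            raise DataError(f"cue_label must be one of {_CUE_LABELS}")

    @property
    def is_go(self) -> bool:
        return self.cue_label == "cue_go"


# ---------------------------------------------------------------------------
# delimited readers / writers
# ---------------------------------------------------------------------------

def _read_table(path, required: Sequence[str]) -> dict[str, list[str]]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(c not in reader.fieldnames for c in required):
            raise FormatError(
                f"{path}: expected columns {list(required)}, got {reader.fieldnames}"
            )
        cols: dict[str, list[str]] = {c: [] for c in required}
        for row in reader:
            for c in required:
                if row[c] is None:
                    raise FormatError(f"{path}: short row {row}")
                cols[c].append(row[c])
    return cols


def _parse_floats(raw: Sequence[str], path, column: str) -> np.ndarray:
    try:
        return np.array([float(v) for v in raw])
    except ValueError as exc:
        raise FormatError(f"{path}: column {column!r} is not numeric: {exc}") from exc


def _uniform_rate(times: np.ndarray, path) -> float:
    if len(times) < 2:
        raise DataError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise DataError(f"{path}: sample times must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > UNIFORMITY_TOL * med:
        raise DataError(
            f"{path}: non-uniform sampling (interval deviates more than "
            f"{UNIFORMITY_TOL:.0%} from the median {med:.6g} s)"
        )
    return 1.0 / med


def read_recording(path, format: str = "delimited") -> Recording:
    """Read a single-channel recording from delimited text or EDF.

    The sampling rate is inferred from the median inter-sample interval;
    files whose sampling deviates from uniform by more than 10% of that
    interval are rejected (resampling is out of scope).
    """
    if format == "edf":
        return _read_edf(path)
    if format != "delimited":
        raise FormatError(f"unknown recording format {format!r}")
    cols = _read_table(path, ("time_s", "value_uv"))
    times = _parse_floats(cols["time_s"], path, "time_s")
    values = _parse_floats(cols["value_uv"], path, "value_uv")
    rate = _uniform_rate(times, path)
    return Recording(samples=values, rate=rate, start_time=float(times[0]))


def _read_edf(path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise FormatError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(picks=[0])[0] * 1e6  # volts -> microvolts
    return Recording(samples=data, rate=float(raw.info["sfreq"]),
                     channel=raw.ch_names[0], start_time=0.0)


def write_recording(recording: Recording, path) -> None:
    """Write the canonical ``time_s,value_uv`` file (lossless to repr precision)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value_uv"])
        t0, rate = recording.start_time, recording.rate
        for i, v in enumerate(recording.samples):
            writer.writerow([repr(t0 + i / rate), repr(float(v))])


def read_events(path) -> EventLog:
    """Read and validate an event-marker file (columns ``label,time_s``)."""
    cols = _read_table(path, ("label", "time_s"))
    times = _parse_floats(cols["time_s"], path, "time_s")
    return EventLog(tuple(zip(cols["label"], times)))


def write_events(events: EventLog, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "time_s"])
        for lbl, t in events:
            writer.writerow([lbl, repr(t)])


def read_angle_trace(path) -> AngleTrace:
    """Read an ankle-angle file (columns ``time_s,angle_deg``)."""
    cols = _read_table(path, ("time_s", "angle_deg"))
    times = _parse_floats(cols["time_s"], path, "time_s")
    values = _parse_floats(cols["angle_deg"], path, "angle_deg")
    rate = _uniform_rate(times, path)
    return AngleTrace(samples=values, rate=rate, start_time=float(times[0]))


def write_angle_trace(trace: AngleTrace, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "angle_deg"])
        t0, rate = trace.start_time, trace.rate
        for i, v in enumerate(trace.samples):
            writer.writerow([repr(t0 + i / rate), repr(float(v))])


# ---------------------------------------------------------------------------
# streaming replay and trial segmentation
# ---------------------------------------------------------------------------

def stream_replay(recording: Recording) -> Iterator[tuple[float, float]]:
    """Yield ``(time, value)`` pairs one sample at a time, in order.

    This is the faithful stand-in for a live acquisition stream: a consumer
    driven by this generator can only ever see current and past samples, so
    anything built on it is causal by construction.
    """
    t0, rate = recording.start_time, recording.rate
    for i, v in enumerate(recording.samples):
        yield t0 + i / rate, float(v)


def segment_trials(events: EventLog) -> list[TrialRecord]:
    """Pair each ``prep_start`` with its following cue into a TrialRecord.

    Trials are returned in time order, indexed from 0. A preparation with
    no following cue is a structural error.
    """
    trials: list[TrialRecord] = []
    evs = list(events)
    for i, (lbl, t) in enumerate(evs):
        if lbl != "prep_start":
            continue
        cue = next(
            ((l2, t2) for l2, t2 in evs[i + 1:] if l2 in _CUE_LABELS or l2 == "prep_start"),
            None,
        )
        if cue is None or cue[0] == "prep_start":
            raise DataError(f"prep_start at {t} s has no following GO/NO-GO cue")
        trials.append(
            TrialRecord(index=len(trials), prep_onset=t, cue_label=cue[0], cue_onset=cue[1])
        )
    return trials
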