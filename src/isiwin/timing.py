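"""Timing arithmetic and signal primitives for paired mechanical–cortical stimulation.

A trial of the paired protocol is driven by two command times referenced to the
trial start: ``t_valve`` (pneumatic valve open command that launches the tendon
hammer) and ``t_TMS`` (magnetic pulse to the motor cortex).  The hammer strikes
the tendon at ``t_hit = t_valve + t_delay`` where ``t_delay`` is the pneumatic
system latency; the physiologically meaningful timing variable is the
inter-stimulus interval ``ISI = t_TMS - t_hit``.  This module holds the event
bookkeeping, hammer-impact detection from accelerometer traces, peak-to-peak
motor-evoked-potential (MEP) extraction from EMG, and the trial/time budget of
the conventional incremental sweep protocol.

All times are in milliseconds from the trial start unless a field name says
otherwise; EMG amplitudes are in millivolts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "StimulationTiming",
    "SampledTrace",
    "ProtocolConfig",
    "SignalError",
    "NoMotionError",
    "NoImpactError",
    "detect_impact_time",
    "compute_isi",
    "extract_mep_amplitude",
    "trial_budget",
    "read_trial_log",
    "write_trial_log",
    "read_trace_csv",
    "write_trace_csv",
    "TRIAL_LOG_COLUMNS",
]


class SignalError(ValueError):
    """Base class for signal-processing failures."""


class NoMotionError(SignalError):
    """No sample of the acceleration trace exceeded the onset threshold."""


class NoImpactError(SignalError):
    """Motion was detected but the trace never crossed zero afterwards."""


@dataclass(frozen=True)
class Window:
    """A closed interval of ISIs ``[lower, upper]`` in milliseconds."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("window bounds must be finite")
        if self.upper < self.lower:
            raise ValueError(f"upper ({self.upper}) < lower ({self.lower})")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, t: float) -> bool:
        return self.lower <= t <= self.upper

    def intersection_length(self, other: "Window") -> float:
        return max(0.0, min(self.upper, other.upper) - max(self.lower, other.lower))


@dataclass(frozen=True)
class StimulationTiming:
    """Event times of one paired-stimulation trial, referenced to trial start.

    ``t_hit`` is optional: it is only available when an accelerometer (or the
    simulator) provides the actual hammer-impact time.
    """

    t_valve: float
    t_tms: float
    t_hit: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("t_valve", "t_tms"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.t_hit is not None:
            if not math.isfinite(self.t_hit) or self.t_hit < 0:
                raise ValueError(f"t_hit must be finite and non-negative, got {self.t_hit}")
            if self.t_hit < self.t_valve:
                raise ValueError("t_hit precedes t_valve")

    @property
    def t_delay(self) -> Optional[float]:
        """Pneumatic latency t_hit - t_valve, or None without an impact time."""
        if self.t_hit is None:
            return None
        return self.t_hit - self.t_valve

    @property
    def isi(self) -> Optional[float]:
        if self.t_hit is None:
            return None
        return self.t_tms - self.t_hit


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled time series (acceleration or EMG).

    Sample ``k`` is taken at ``start_time + k * sampling_interval`` (ms).
    """

    sampling_interval: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.sampling_interval * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.sampling_interval * (self.values.size - 1)


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of the conventional incremental sweep protocol.

    Defaults reproduce the full sweep: 12 repetitions per ISI (first 2
    discarded against startle responses), 1 s per stimulation, 120 s rest per
    block, 50 intervals at 5 ms steps, and two 10-minute long breaks.
    """

    reps_per_isi: int = 12
    discard_first: int = 2
    trial_duration_s: float = 1.0
    rest_between_blocks_s: float = 120.0
    n_intervals: int = 50
    long_breaks_s: Tuple[float, ...] = (600.0, 600.0)
    grid_step_ms: float = 5.0
    search_range_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.discard_first >= self.reps_per_isi:
            raise ValueError("discard_first must be smaller than reps_per_isi")
        if self.discard_first < 0:
            raise ValueError("discard_first must be non-negative")
        if self.grid_step_ms <= 0:
            raise ValueError("grid_step_ms must be positive")
        if self.search_range_ms <= 0:
            raise ValueError("search_range_ms must be positive")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be at least 1")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def detect_impact_time(trace: SampledTrace, onset_threshold: Optional[float] = None) -> float:
    """Detect the hammer-impact time from an acceleration trace.

    The impact is the first zero crossing of the signed acceleration after the
    initiation of hammer motion.  Motion initiation is the first sample whose
    magnitude exceeds ``onset_threshold`` (default: 10% of the trace's maximum
    absolute value).  The crossing time is refined by linear interpolation
    between the bracketing samples.  The crossing is accepted in either
    direction, so the result does not depend on sensor polarity.

    Raises
    ------
    NoMotionError
        If no sample exceeds the onset threshold.
    NoImpactError
        If motion is detected but the signal never crosses zero afterwards.
    """
    v = trace.values
    if onset_threshold is None:
        onset_threshold = 0.1 * float(np.max(np.abs(v)))
    if onset_threshold <= 0:
        raise NoMotionError("no motion detected: trace has no signal")

    above = np.nonzero(np.abs(v) > onset_threshold)[0]
    if above.size == 0:
        raise NoMotionError("no motion detected: threshold never exceeded")
    onset = int(above[0])

    # first sign change strictly after the onset sample
    for k in range(onset + 1, v.size):
        a, b = v[k - 1], v[k]
        if b == 0.0:
            return float(trace.start_time + k * trace.sampling_interval)
        if a * b < 0.0:
            frac = a / (a - b)  # in (0, 1): linear interpolation to the root
            return float(trace.start_time + (k - 1 + frac) * trace.sampling_interval)
    raise NoImpactError("no impact detected: no zero crossing after motion onset")


def compute_isi(timing: StimulationTiming) -> float:
    """Inter-stimulus interval ``ISI = t_TMS - t_hit`` in milliseconds.

    Negative values mean the cortical pulse preceded the mechanical impact.
    """
    if timing.t_hit is None:
        raise ValueError("impact time unavailable; use valve-referenced timing")
    return timing.t_tms - timing.t_hit


def extract_mep_amplitude(emg: SampledTrace, response_window: Window) -> float:
    """Peak-to-peak EMG amplitude (mV) within a response window.

    The caller chooses ``response_window`` so that it excludes the stimulation
    artifacts; a typical choice is 10–60 ms after the TMS pulse.
    """
    t = emg.times
    mask = (t >= response_window.lower) & (t <= response_window.upper)
    if not mask.any():
        raise ValueError("response window contains no EMG samples")
    seg = emg.values[mask]
    return float(seg.max() - seg.min())


def trial_budget(protocol: ProtocolConfig) -> Tuple[int, float]:
    """Trial count and wall-clock seconds of the full incremental sweep.

    With the defaults this is 600 trials and 7,800 s (130 min):
    ``(1 s × 12 reps + 120 s rest) × 50 intervals + 2 × 600 s breaks``.
    """
    total_trials = protocol.reps_per_isi * protocol.n_intervals
    total_seconds = (
        protocol.trial_duration_s * protocol.reps_per_isi + protocol.rest_between_blocks_s
    ) * protocol.n_intervals + sum(protocol.long_breaks_s)
    return total_trials, float(total_seconds)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

TRIAL_LOG_COLUMNS = [
    "trial_id",
    "subject_id",
    "t_valve_ms",
    "t_tms_ms",
    "t_hit_ms",
    "isi_ms",
    "mep_pp_mv",
]


def write_trial_log(df: pd.DataFrame, path) -> None:
    """Write a trial log CSV (one row per trial; missing t_hit left empty)."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    df.loc[:, TRIAL_LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    return df


def write_trace_csv(trace: SampledTrace, path) -> None:
    pd.DataFrame({"time_ms": trace.times, "value": trace.values}).to_csv(path, index=False)


def read_trace_csv(path, rel_tol: float = 1e-6) -> SampledTrace:
    """Read a ``time_ms,value`` CSV, validating a uniform sampling grid."""
    df = pd.read_csv(path)
    for c in ("time_ms", "value"):
        if c not in df.columns:
            raise ValueError(f"trace CSV missing column: {c}")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0 or np.any(np.abs(dt - step) > rel_tol * abs(step)):
        raise ValueError("trace CSV is not uniformly sampled")
    return SampledTrace(sampling_interval=step, values=df["value"].to_numpy(dtype=float),
                        start_time=float(t[0]))
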