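"""Virtual subjects for the paired mechanical–cortical stimulation protocol.

A virtual subject is defined by a ground-truth single-Gaussian ISI–MEP
enhancement profile riding on a small baseline response, a repeatable
pneumatic hammer delay, and multiplicative trial-to-trial MEP noise.
Population defaults follow the measured statistics of the protocol: effective
window lengths of 108 ± 45 ms (SD) across subjects, hammer delays of
195.5 ± 2 ms, and trial noise with a coefficient of variation of 0.3.

The module also executes the conventional incremental sweep (12 repetitions
per ISI, first 2 discarded) to produce the measured mean profile and the
ground-truth window that the adaptive estimators are scored against, and can
synthesize accelerometer/EMG traces with the timing structure of real trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import GaussianModel, TWO_SIGMA_FRACTION
from .timing import ProtocolConfig, SampledTrace, StimulationTiming, Window, TRIAL_LOG_COLUMNS

__all__ = [
    "PopulationParams",
    "SubjectParams",
    "SweepResult",
    "sample_subject",
    "expected_mep",
    "measure_mep",
    "incremental_sweep",
    "simulate_acceleration_trace",
    "simulate_emg_trace",
    "subject_to_json",
    "subject_from_json",
]

#: floor on sampled window lengths (ms); narrower windows than the 15–20 ms
#: reported for electrical nerve stimulation are not physiological here.
MIN_WINDOW_LENGTH = 20.0


@dataclass(frozen=True)
class PopulationParams:
    """Population statistics from which virtual subjects are drawn."""

    window_length_mean: float = 108.0   # ms
    window_length_sd: float = 45.0      # ms
    delay_mean: float = 195.5           # ms
    delay_sd: float = 2.0               # ms
    peak_amplitude_range: Tuple[float, float] = (0.3, 1.5)  # mV
    noise_cv: float = 0.3               # coefficient of variation of trial MEPs
    baseline_mep: float = 0.05          # mV, response at 100% resting motor threshold
    search_range_ms: float = 500.0      # valve-referenced search span

    def __post_init__(self) -> None:
        if self.window_length_mean <= 0:
            raise ValueError("window_length_mean must be positive")
        if self.window_length_sd < 0 or self.delay_sd < 0 or self.noise_cv < 0:
            raise ValueError("standard deviations and noise_cv must be non-negative")
        lo, hi = self.peak_amplitude_range
        if not (0 < lo <= hi):
            raise ValueError("peak_amplitude_range must be a positive interval")


@dataclass(frozen=True)
class SubjectParams:
    """One virtual subject's ground truth."""

    profile: GaussianModel
    t_delay: float
    baseline_mep: float
    noise_cv: float

    @property
    def true_window(self) -> Window:
        """The two-sigma window of the ground-truth profile."""
        return Window(self.profile.center - 2.0 * self.profile.width,
                      self.profile.center + 2.0 * self.profile.width)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of the conventional incremental sweep on one subject."""

    isis: np.ndarray
    mean_meps: np.ndarray
    window: Optional[Window]     # None when no supra-baseline response exists
    trial_log: pd.DataFrame

    @property
    def empty(self) -> bool:
        return self.window is None


def _truncnorm_length(pop: PopulationParams, rng: np.random.Generator) -> float:
    if pop.window_length_sd == 0:
        return max(pop.window_length_mean, MIN_WINDOW_LENGTH)
    a = (MIN_WINDOW_LENGTH - pop.window_length_mean) / pop.window_length_sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=pop.window_length_mean,
                                     scale=pop.window_length_sd, random_state=rng))


def sample_subject(pop: PopulationParams, seed) -> SubjectParams:
    """Draw one subject from the population; deterministic given the seed.

    The window length is drawn from a normal distribution truncated below at
    20 ms, the profile width is a quarter of it (so the two-sigma window has
    exactly that length), and the center is placed uniformly so that the
    window fits inside the impact-referenced search span
    ``[0, search_range - delay]``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = _truncnorm_length(pop, rng)
    sigma = length / 4.0
    delay = float(rng.normal(pop.delay_mean, pop.delay_sd))
    span_upper = pop.search_range_ms - delay
    lo, hi = 2.0 * sigma, span_upper - 2.0 * sigma
    center = float(rng.uniform(lo, hi)) if hi > lo else 0.5 * span_upper
    amplitude = float(rng.uniform(*pop.peak_amplitude_range))
    profile = GaussianModel(amplitude=amplitude, center=center, width=sigma)
    return SubjectParams(profile=profile, t_delay=delay,
                         baseline_mep=pop.baseline_mep, noise_cv=pop.noise_cv)


def expected_mep(subject: SubjectParams, isi) -> np.ndarray:
    """Noise-free expected MEP: baseline plus the Gaussian enhancement."""
    return subject.baseline_mep + subject.profile(isi)


def measure_mep(subject: SubjectParams, isi: float, rng: np.random.Generator) -> float:
    """One noisy trial MEP at a given ISI (mV, clipped at zero).

    The noise is multiplicative Gaussian — ``expected * (1 + cv * z)`` — which
    reproduces the larger scatter seen at larger MEP amplitudes.
    """
    expected = float(expected_mep(subject, isi))
    value = expected * (1.0 + subject.noise_cv * float(rng.standard_normal()))
    return max(value, 0.0)


def _longest_run(mask: np.ndarray) -> Optional[Tuple[int, int]]:
    """(start, stop) indices of the longest True run; earlier run wins ties."""
    best = None
    start = None
    for i, m in enumerate(np.append(mask, False)):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    return best


def incremental_sweep(subject: SubjectParams, protocol: ProtocolConfig,
                      rng: np.random.Generator, grid: Optional[np.ndarray] = None,
                      subject_id: str = "sim") -> SweepResult:
    """Run the conventional incremental sweep and extract the measured window.

    For every grid ISI, ``reps_per_isi`` trials are simulated, the first
    ``discard_first`` are dropped, and the mean of the remainder is recorded.
    The measured window is the longest contiguous run of grid ISIs whose mean
    MEP rises above the baseline by at least exp(-2) of the peak enhancement
    (the same normalized two-sigma threshold used everywhere in the method);
    this is the operational form of "above baseline" that is immune to the
    noise floor at far-tail ISIs.  Returns the per-ISI means, the window (or
    None when nothing exceeds the threshold), and the full trial log.
    """
    if grid is None:
        grid = protocol.grid_step_ms * np.arange(protocol.n_intervals)
    grid = np.asarray(grid, dtype=float)

    rows = []
    means = np.empty(grid.size)
    trial_id = 0
    for gi, isi in enumerate(grid):
        reps = [measure_mep(subject, float(isi), rng) for _ in range(protocol.reps_per_isi)]
        means[gi] = float(np.mean(reps[protocol.discard_first:]))
        t_hit = subject.t_delay  # valve command at trial time 0 reference
        for mep in reps:
            rows.append({
                "trial_id": trial_id, "subject_id": subject_id,
                "t_valve_ms": 0.0, "t_tms_ms": t_hit + isi, "t_hit_ms": t_hit,
                "isi_ms": float(isi), "mep_pp_mv": mep,
            })
            trial_id += 1
    log = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)

    peak = float(means.max())
    enhancement = peak - subject.baseline_mep
    threshold = subject.baseline_mep + TWO_SIGMA_FRACTION * enhancement
    # tolerance keeps grid points sitting exactly on the two-sigma level inside
    mask = means >= threshold - 1e-9 * max(enhancement, 1.0)
    if peak <= subject.baseline_mep or not mask.any():
        return SweepResult(isis=grid, mean_meps=means, window=None, trial_log=log)
    run = _longest_run(mask)
    window = Window(float(grid[run[0]]), float(grid[run[1] - 1]))
    return SweepResult(isis=grid, mean_meps=means, window=window, trial_log=log)


# ---------------------------------------------------------------------------
# Synthetic traces
# ---------------------------------------------------------------------------

def simulate_acceleration_trace(t_valve: float, t_delay: float,
                                sampling_interval: float = 0.5,
                                duration: float = 600.0,
                                swing_time: float = 30.0,
                                rng: Optional[np.random.Generator] = None,
                                noise_sd: float = 0.0) -> SampledTrace:
    """Hammer acceleration with the impact zero crossing at ``t_valve + t_delay``.

    The hammer accelerates over ``swing_time`` ms (positive half-sine reaching
    zero exactly at the impact), then the impact deceleration drives the
    signal negative — so the first post-onset zero crossing marks ``t_hit``.
    """
    t = sampling_interval * np.arange(int(duration / sampling_interval) + 1)
    t_hit = t_valve + t_delay
    a = np.zeros_like(t)
    swing = (t >= t_hit - swing_time) & (t < t_hit)
    a[swing] = 5.0 * np.sin(np.pi * (t[swing] - (t_hit - swing_time)) / swing_time)
    rebound = t >= t_hit
    a[rebound] = -8.0 * np.exp(-(t[rebound] - t_hit) / 5.0)
    if noise_sd > 0 and rng is not None:
        a = a + rng.normal(0.0, noise_sd, size=a.size)
    return SampledTrace(sampling_interval=sampling_interval, values=a)


def simulate_emg_trace(timing: StimulationTiming, mep_amplitude: float,
                       sampling_interval: float = 0.25, duration: float = 800.0,
                       mep_latency: float = 20.0, artifact_mv: float = 3.0) -> SampledTrace:
    """EMG with stimulation artifacts and an MEP burst after the TMS pulse.

    The MEP is one damped sine cycle starting ``mep_latency`` ms after
    ``t_TMS`` with the requested peak-to-peak amplitude; narrow artifact
    spikes are placed at the valve command and at the TMS pulse.
    """
    t = sampling_interval * np.arange(int(duration / sampling_interval) + 1)
    v = np.zeros_like(t)
    for t_art in (timing.t_valve, timing.t_tms):
        v += artifact_mv * np.exp(-((t - t_art) ** 2) / (2.0 * 0.5 ** 2))
    t0 = timing.t_tms + mep_latency
    burst = (t >= t0) & (t <= t0 + 20.0)
    v[burst] += 0.5 * mep_amplitude * np.sin(2.0 * np.pi * (t[burst] - t0) / 20.0)
    return SampledTrace(sampling_interval=sampling_interval, values=v)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def subject_to_json(subject: SubjectParams) -> str:
    d = {
        "profile": asdict(subject.profile),
        "t_delay": subject.t_delay,
        "baseline_mep": subject.baseline_mep,
        "noise_cv": subject.noise_cv,
        "true_window": {"lower": subject.true_window.lower,
                        "upper": subject.true_window.upper,
                        "length": subject.true_window.length},
    }
    return json.dumps(d, indent=2)


def subject_from_json(text: str) -> SubjectParams:
    d = json.loads(text)
    return SubjectParams(
        profile=GaussianModel(**d["profile"]),
        t_delay=float(d["t_delay"]),
        baseline_mep=float(d["baseline_mep"]),
        noise_cv=float(d["noise_cv"]),
    )
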