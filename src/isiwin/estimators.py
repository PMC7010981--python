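"""Adaptive estimation of the effective inter-stimulus interval window (ISI-W).

The enhanced-MEP profile over ISI is hill shaped and is modeled by a single
Gaussian ``A * exp(-(x - mu)^2 / (2 sigma^2))``.  Four strategies estimate the
effective window from noisy MEP observations while choosing where to sample
next:

* **NR** — nonlinear (least-squares) regression of the single Gaussian; the
  acquisition alternates between the current lower and upper window ends.
* **SVMR** — support-vector regression (RBF kernel); same end-refining
  acquisition; window read off the predicted curve at 13.5% of its peak.
* **GPR** — Gaussian-process regression (squared-exponential kernel plus a
  fitted noise term); acquisition at the grid ISI with maximal posterior
  predictive variance; window read off the posterior mean curve.
* **PF** — a particle filter that localizes the responsive ISI region with 30
  particles whose weights follow the observed MEP amplitudes; the final window
  comes from a single-Gaussian fit to the accumulated observations.

All strategies share the stopping rule: iteration ends when the sample
variances of both window ends over the last five iterations fall below
50 ms² (≈7 ms SD, i.e. about one 5 ms grid step), or after 99 iterations.
For the parametric Gaussian the window is ``mu ± 2 sigma`` — the points where
the normalized curve equals exp(-2) ≈ 0.135 of the peak; the nonparametric
curves use the same 0.135-of-peak threshold for consistency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.svm import SVR

from .timing import Window

__all__ = [
    "METHODS",
    "TWO_SIGMA_FRACTION",
    "GaussianModel",
    "EstimatorConfig",
    "EstimationResult",
    "EstimationState",
    "ParticleSet",
    "FlaggedWindow",
    "NoResponseError",
    "FitError",
    "fit_single_gaussian",
    "fit_two_gaussian",
    "window_from_gaussian",
    "window_from_curve",
    "acquire_next_isi",
    "pf_step",
    "check_stopping",
    "run_estimation",
]

METHODS = ("nr", "svmr", "gpr", "pf")

#: normalized Gaussian amplitude at mu +/- 2 sigma; the window threshold.
TWO_SIGMA_FRACTION = float(np.exp(-2.0))  # 0.1353..., printed as 0.135


class NoResponseError(ValueError):
    """All observed MEPs are zero: nothing to fit."""


class FitError(RuntimeError):
    """Every optimizer start failed to produce a valid fit."""


@dataclass(frozen=True)
class GaussianModel:
    """Single-Gaussian ISI–MEP enhancement profile."""

    amplitude: float  # peak enhancement, mV
    center: float     # mu, ms
    width: float      # sigma, ms

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def __call__(self, isi) -> np.ndarray:
        x = np.asarray(isi, dtype=float)
        return self.amplitude * np.exp(-((x - self.center) ** 2) / (2.0 * self.width ** 2))


@dataclass(frozen=True)
class FlaggedWindow(Window):
    """Window read off a curve; flags mark clipping at a search-range edge."""

    clipped_lower: bool = False
    clipped_upper: bool = False


@dataclass(frozen=True)
class EstimatorConfig:
    """Configuration of one estimation run.

    ``search_lower``/``search_upper`` bound the ISI search range (ms); with an
    accelerometer the lower bound starts at the detected impact (ISI 0),
    without one it extends back to the valve command.
    """

    method: str = "gpr"
    n_ini: int = 7
    grid_step: float = 5.0
    search_lower: float = 0.0
    search_upper: float = 300.0
    variance_threshold: float = 50.0   # ms^2, on each window end
    stop_history: int = 5
    max_iterations: int = 99
    threshold_fraction: float = 0.135
    n_particles: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_ini < 2:
            raise ValueError("n_ini must be at least 2")
        if self.method == "nr" and self.n_ini < 4:
            raise ValueError("NR needs n_ini >= 4 (four free-parameter fit)")
        if self.search_upper <= self.search_lower:
            raise ValueError("search_upper must exceed search_lower")
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.stop_history < 2:
            raise ValueError("stop_history must be at least 2")
        if self.n_particles < 2:
            raise ValueError("n_particles must be at least 2")

    @property
    def grid(self) -> np.ndarray:
        """ISI grid from search_lower to search_upper (inclusive) at grid_step."""
        n = int(math.floor((self.search_upper - self.search_lower) / self.grid_step + 1e-9))
        return self.search_lower + self.grid_step * np.arange(n + 1)


@dataclass
class EstimationState:
    """Mutable in-progress state handed to the acquisition rule."""

    config: EstimatorConfig
    observations: List[Tuple[float, float]] = field(default_factory=list)
    window: Optional[Window] = None
    model: Optional[object] = None       # fitted GaussianModel / SVR / GPR
    n_acquired: int = 0                  # acquisition steps taken so far

    @property
    def isis(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations], dtype=float)

    @property
    def meps(self) -> np.ndarray:
        return np.array([o[1] for o in self.observations], dtype=float)


@dataclass
class ParticleSet:
    """Particle positions (ISIs, ms) and normalized weights."""

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions.shape != self.weights.shape or self.positions.ndim != 1:
            raise ValueError("positions and weights must be matching 1-D arrays")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = self.weights / total

    @property
    def mean_position(self) -> float:
        return float(np.dot(self.weights, self.positions))


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of one adaptive run."""

    window: Window
    curve_isis: np.ndarray
    curve: np.ndarray
    observations: Tuple[Tuple[float, float], ...]
    converged: bool
    end_history: Tuple[Tuple[float, float], ...]
    method: str

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "window": {"lower": self.window.lower, "upper": self.window.upper,
                       "length": self.window.length},
            "curve": {"isi_ms": list(map(float, self.curve_isis)),
                      "mep_mv": list(map(float, self.curve))},
            "observations": [{"isi_ms": float(i), "mep_pp_mv": float(m)}
                             for i, m in self.observations],
            "n_observations": self.n_observations,
            "converged": bool(self.converged),
            "end_history": [{"lower": float(l), "upper": float(u)}
                            for l, u in self.end_history],
        }


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------

def _gaussian_residuals(params, x, y):
    a, mu, sigma = params
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) - y


def _fit_starts(x: np.ndarray, y: np.ndarray) -> List[Tuple[float, float, float]]:
    span = float(x.max() - x.min()) or 1.0
    ymax = float(y.max())
    starts = [(ymax, float(x[np.argmax(y)]), span / 8.0)]
    w = np.clip(y, 0.0, None)
    if w.sum() > 0:
        mu = float(np.dot(w, x) / w.sum())
        sigma = float(np.sqrt(np.dot(w, (x - mu) ** 2) / w.sum()))
        starts.append((ymax, mu, max(sigma, span / 50.0)))
    starts.append((ymax, float(0.5 * (x.min() + x.max())), span / 4.0))
    return starts


def fit_single_gaussian(isis: Sequence[float], meps: Sequence[float]) -> GaussianModel:
    """Least-squares fit of a single Gaussian to (ISI, MEP) observations.

    Runs a small multi-start (argmax-, moment- and midpoint-based initial
    guesses) and keeps the lowest-residual solution.  The center is box
    constrained within one span length of the observed ISI range and the
    width is kept positive.
    """
    x = np.asarray(isis, dtype=float)
    y = np.asarray(meps, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations to fit a single Gaussian")
    if np.unique(x).size < 3:
        raise ValueError("need observations at >= 3 distinct ISIs")
    if not np.any(y > 0):
        raise NoResponseError("no response detected")

    span = float(x.max() - x.min()) or 1.0
    lo = [0.0, x.min() - span, 1e-3]
    hi = [max(10.0 * y.max(), 1e-6), x.max() + span, 4.0 * span]

    best = None
    for a0, mu0, s0 in _fit_starts(x, y):
        p0 = np.clip([a0, mu0, s0], lo, hi)
        try:
            res = optimize.least_squares(
                _gaussian_residuals, p0, args=(x, y), bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if not res.success and not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("fit failed from every initialization")
    a, mu, sigma = best.x
    return GaussianModel(amplitude=float(a), center=float(mu), width=float(max(sigma, 1e-3)))


def _two_gaussian_residuals(params, x, y):
    a1, m1, s1, a2, m2, s2 = params
    g1 = a1 * np.exp(-((x - m1) ** 2) / (2.0 * s1 ** 2))
    g2 = a2 * np.exp(-((x - m2) ** 2) / (2.0 * s2 ** 2))
    return g1 + g2 - y


def fit_two_gaussian(isis: Sequence[float], meps: Sequence[float]) -> Tuple[GaussianModel, GaussianModel]:
    """Fit a sum of two Gaussians; components returned (high, low) by amplitude.

    Used to check whether a second response peak carries real amplitude; on
    truly unimodal data the low component's amplitude collapses toward zero.
    """
    x = np.asarray(isis, dtype=float)
    y = np.asarray(meps, dtype=float)
    if x.size < 7:
        raise ValueError("need at least 7 observations to fit two Gaussians")
    if not np.any(y > 0):
        raise NoResponseError("no response detected")

    span = float(x.max() - x.min()) or 1.0
    lo = [0.0, x.min() - span, 1e-3] * 2
    hi = [max(10.0 * y.max(), 1e-6), x.max() + span, 4.0 * span] * 2
    ymax = float(y.max())
    xmax = float(x[np.argmax(y)])
    quarter = span / 4.0
    # first start: the single-Gaussian solution with a zero second component,
    # so a truly unimodal profile keeps the second amplitude at zero; the
    # split starts handle genuinely two-peaked data.
    try:
        g = fit_single_gaussian(x, y)
        single = (g.amplitude, g.center, g.width)
    except (ValueError, FitError):
        single = (ymax, xmax, span / 8.0)
    starts = [
        (*single, 0.0, xmax + quarter, span / 8.0),
        (*single, 0.0, xmax - quarter, span / 8.0),
        (ymax, float(x.min()) + quarter, span / 8.0, ymax, float(x.max()) - quarter, span / 8.0),
    ]
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                _two_gaussian_residuals, np.clip(p0, lo, hi), args=(x, y),
                bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("fit failed from every initialization")
    a1, m1, s1, a2, m2, s2 = best.x
    g1 = GaussianModel(float(a1), float(m1), float(max(s1, 1e-3)))
    g2 = GaussianModel(float(a2), float(m2), float(max(s2, 1e-3)))
    return (g1, g2) if g1.amplitude >= g2.amplitude else (g2, g1)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def window_from_gaussian(model: GaussianModel) -> Window:
    """Two-sigma window ``[mu - 2 sigma, mu + 2 sigma]`` (95% of the mass)."""
    return Window(model.center - 2.0 * model.width, model.center + 2.0 * model.width)


def window_from_curve(isis: Sequence[float], values: Sequence[float],
                      threshold_fraction: float = 0.135) -> FlaggedWindow:
    """Window where a predicted curve exceeds ``threshold_fraction`` of its peak.

    The crossings bracketing the global-maximum grid point are located and
    refined by linear interpolation.  If the curve is still above threshold at
    a search-range edge the window is clipped there and flagged.
    """
    x = np.asarray(isis, dtype=float)
    v = np.asarray(values, dtype=float)
    if x.size != v.size or x.size < 2:
        raise ValueError("curve needs matching ISI/value arrays of length >= 2")
    if np.any(v < 0):
        raise ValueError("curve values must be non-negative")
    k = int(np.argmax(v))
    peak = v[k]
    if peak <= 0:
        raise NoResponseError("no response: curve maximum is zero")
    thr = threshold_fraction * peak

    clipped_lower = clipped_upper = False
    i = k
    while i > 0 and v[i - 1] >= thr:
        i -= 1
    if i == 0:
        lower, clipped_lower = float(x[0]), True
    else:
        frac = (thr - v[i - 1]) / (v[i] - v[i - 1])
        lower = float(x[i - 1] + frac * (x[i] - x[i - 1]))

    j = k
    while j < v.size - 1 and v[j + 1] >= thr:
        j += 1
    if j == v.size - 1:
        upper, clipped_upper = float(x[-1]), True
    else:
        frac = (v[j] - thr) / (v[j] - v[j + 1])
        upper = float(x[j] + frac * (x[j + 1] - x[j]))

    return FlaggedWindow(lower, upper, clipped_lower=clipped_lower, clipped_upper=clipped_upper)


# ---------------------------------------------------------------------------
# Stopping rule
# ---------------------------------------------------------------------------

def _ends_variance_ok(end_history: Sequence[Tuple[float, float]], config: EstimatorConfig) -> bool:
    if len(end_history) < config.stop_history:
        return False
    recent = np.asarray(end_history[-config.stop_history:], dtype=float)
    var_lower = float(np.var(recent[:, 0], ddof=1))
    var_upper = float(np.var(recent[:, 1], ddof=1))
    return var_lower < config.variance_threshold and var_upper < config.variance_threshold


def check_stopping(end_history: Sequence[Tuple[float, float]], config: EstimatorConfig) -> bool:
    """True when the window ends have stabilized or the iteration cap is hit.

    Stabilization means the sample variance (n-1 denominator) of both the
    lower and the upper end over the last ``stop_history`` iterations is below
    ``variance_threshold`` (50 ms² ≈ 7 ms SD by default).
    """
    if _ends_variance_ok(end_history, config):
        return True
    return len(end_history) >= config.max_iterations


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def _snap_to_grid(isi: float, config: EstimatorConfig) -> float:
    grid = config.grid
    return float(grid[np.argmin(np.abs(grid - isi))])


def _farthest_unsampled(state: EstimationState) -> float:
    grid = state.config.grid
    seen = state.isis
    unsampled = grid[~np.isin(grid, seen)]
    candidates = unsampled if unsampled.size else grid
    if seen.size == 0:
        return float(candidates[0])
    dist = np.min(np.abs(candidates[:, None] - seen[None, :]), axis=1)
    return float(candidates[int(np.argmax(dist))])


def acquire_next_isi(state: EstimationState, config: EstimatorConfig,
                     rng: Optional[np.random.Generator] = None) -> float:
    """Choose the next ISI to observe.

    NR/SVMR alternate between the current lower and upper window-end
    estimates (grid snapped), refining the boundaries that determine the
    interval-overlap score; GPR picks the grid ISI with the largest posterior
    predictive variance.  If no window estimate exists the fallback is the
    unsampled grid ISI farthest from all previous observations.  Repeat visits
    are allowed: responses are stochastic, so re-observing is informative.
    """
    if len(state.observations) < config.n_ini:
        raise ValueError("acquisition requires the initial observations")
    if config.method == "gpr":
        if state.model is None:
            return _farthest_unsampled(state)
        _, std = state.model.predict(config.grid.reshape(-1, 1), return_std=True)
        return float(config.grid[int(np.argmax(std))])
    if config.method in ("nr", "svmr"):
        if state.window is None:
            return _farthest_unsampled(state)
        end = state.window.lower if state.n_acquired % 2 == 0 else state.window.upper
        return _snap_to_grid(end, config)
    raise ValueError("particle filter does not use a pointwise acquisition rule")


# ---------------------------------------------------------------------------
# Particle filter
# ---------------------------------------------------------------------------

def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def pf_step(particles: ParticleSet, observe: Callable[[float], float],
            config: EstimatorConfig, rng: np.random.Generator,
            ) -> Tuple[ParticleSet, List[Tuple[float, float]]]:
    """One particle-filter iteration: observe, reweight, resample, jitter.

    Each particle observes the MEP at its ISI; weights are multiplied by the
    observed amplitude plus a small floor (1% of the largest MEP in the batch)
    so that an all-zero batch degrades gracefully to uniform weights.
    Systematic resampling follows, then Gaussian jitter with SD equal to one
    grid step, clipped to the search range.
    """
    meps = np.array([float(observe(p)) for p in particles.positions])
    floor = 0.01 * float(meps.max()) if meps.max() > 0 else 1.0
    new_w = particles.weights * (meps + floor)
    if new_w.sum() <= 0:
        new_w = np.full_like(new_w, 1.0 / new_w.size)
    new_w = new_w / new_w.sum()

    idx = _systematic_resample(new_w, rng)
    new_pos = particles.positions[idx] + rng.normal(0.0, config.grid_step, size=idx.size)
    new_pos = np.clip(new_pos, config.search_lower, config.search_upper)
    observations = list(zip(map(float, particles.positions), map(float, meps)))
    return ParticleSet(new_pos, np.full(idx.size, 1.0 / idx.size)), observations


# ---------------------------------------------------------------------------
# Regression backends
# ---------------------------------------------------------------------------

def _make_gpr() -> GaussianProcessRegressor:
    # squared-exponential prior over a smooth unimodal profile; length scale
    # initialized at 25 ms (5 grid steps), noise level fitted by marginal
    # likelihood.
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=25.0, length_scale_bounds=(2.0, 500.0))
        + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-12, 1e1))
    )
    return GaussianProcessRegressor(kernel=kernel, alpha=1e-10, normalize_y=False,
                                    n_restarts_optimizer=0)


def _make_svr(y: np.ndarray, length_scale: float = 25.0) -> SVR:
    # epsilon tube at 10% of the observed MEP range; the RBF width starts at
    # the 25 ms characteristic scale and is re-matched to the current window
    # estimate as the iteration sharpens it.
    span = float(y.max() - y.min())
    eps = max(0.1 * span, 1e-4)
    return SVR(kernel="rbf", gamma=1.0 / (2.0 * length_scale ** 2), C=10.0, epsilon=eps)


def _fit_and_extract(state: EstimationState, config: EstimatorConfig):
    """Fit the method's model on current observations; return (window, curve, model)."""
    x, y = state.isis, state.meps
    grid = config.grid
    if config.method in ("nr", "pf"):
        # fit the enhancement above the observed floor: the small baseline
        # response present at every ISI is not part of the Gaussian profile
        floor = float(y.min())
        model = fit_single_gaussian(x, y - floor)
        return window_from_gaussian(model), model(grid) + floor, model
    if config.method == "svmr":
        if state.window is not None and state.window.length > 0:
            scale = max(state.window.length / 4.0, 2.0 * config.grid_step)
        else:
            scale = 25.0
        model = _make_svr(y, length_scale=scale)
        model.fit(x.reshape(-1, 1), y)
        curve = np.clip(model.predict(grid.reshape(-1, 1)), 0.0, None)
    elif config.method == "gpr":
        model = _make_gpr()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            model.fit(x.reshape(-1, 1), y)
        curve = np.clip(model.predict(grid.reshape(-1, 1)), 0.0, None)
    else:
        raise ValueError(f"unknown method {config.method!r}")
    # threshold the enhancement above the curve's floor, so that the small
    # baseline response (present at every ISI) does not widen the window
    window = window_from_curve(grid, curve - curve.min(), config.threshold_fraction)
    return window, curve, model


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _initial_isis(config: EstimatorConfig) -> np.ndarray:
    raw = np.linspace(config.search_lower, config.search_upper, config.n_ini)
    grid = config.grid
    snapped = grid[np.argmin(np.abs(grid[:, None] - raw[None, :]), axis=0)]
    return snapped


def _expand_for_response(state: EstimationState, observe) -> bool:
    """Farthest-point sweep of unsampled grid ISIs until a response appears."""
    config = state.config
    while True:
        grid = config.grid
        unsampled = grid[~np.isin(grid, state.isis)]
        if unsampled.size == 0:
            return False
        dist = np.min(np.abs(unsampled[:, None] - state.isis[None, :]), axis=1)
        isi = float(unsampled[int(np.argmax(dist))])
        mep = float(observe(isi))
        state.observations.append((isi, mep))
        if mep > 0:
            return True


def run_estimation(observe: Callable[[float], float], config: EstimatorConfig) -> EstimationResult:
    """Run the full observe–fit–acquire loop for one subject.

    ``observe`` maps an ISI (ms) to a measured peak-to-peak MEP (mV); it is
    called once per stimulation trial, so ``n_observations`` of the result is
    the trial cost of the estimate.  Raises :class:`NoResponseError` when the
    subject never yields a positive MEP anywhere on the grid.
    """
    if config.method == "pf":
        return _run_particle_filter(observe, config)

    rng = np.random.default_rng(config.seed)
    state = EstimationState(config=config)
    for isi in _initial_isis(config):
        state.observations.append((float(isi), float(observe(float(isi)))))
    if not np.any(state.meps > 0):
        if not _expand_for_response(state, observe):
            raise NoResponseError("no response in search range")

    end_history: List[Tuple[float, float]] = []
    converged = False
    window: Optional[Window] = None
    curve = np.zeros_like(config.grid)

    while True:
        try:
            window, curve, model = _fit_and_extract(state, config)
            state.window, state.model = window, model
            end_history.append((window.lower, window.upper))
        except (NoResponseError, FitError):
            state.window = state.model = None
        if _ends_variance_ok(end_history, config):
            converged = True
            break
        if max(len(end_history), state.n_acquired + 1) > config.max_iterations or \
                config.max_iterations == 0:
            break
        isi = acquire_next_isi(state, config, rng)
        state.observations.append((isi, float(observe(isi))))
        state.n_acquired += 1

    if window is None:
        raise FitError("estimation ended without a successful fit")
    return EstimationResult(
        window=window, curve_isis=config.grid.copy(), curve=np.asarray(curve, dtype=float),
        observations=tuple(state.observations), converged=converged,
        end_history=tuple(end_history), method=config.method,
    )


def _run_particle_filter(observe: Callable[[float], float], config: EstimatorConfig) -> EstimationResult:
    rng = np.random.default_rng(config.seed)
    particles = ParticleSet(
        np.linspace(config.search_lower, config.search_upper, config.n_particles),
        np.full(config.n_particles, 1.0 / config.n_particles),
    )
    observations: List[Tuple[float, float]] = []
    end_history: List[Tuple[float, float]] = []
    converged = False
    model: Optional[GaussianModel] = None
    window: Optional[Window] = None

    iteration = 0
    while iteration < max(config.max_iterations, 1):
        iteration += 1
        particles, batch = pf_step(particles, observe, config, rng)
        observations.extend(batch)
        x = np.array([o[0] for o in observations])
        y = np.array([o[1] for o in observations])
        try:
            model = fit_single_gaussian(x, y - float(y.min()))
            window = window_from_gaussian(model)
            end_history.append((window.lower, window.upper))
        except (NoResponseError, FitError):
            pass
        if _ends_variance_ok(end_history, config):
            converged = True
            break
        if iteration >= config.max_iterations:
            break

    if window is None or model is None:
        raise NoResponseError("no response in search range")
    return EstimationResult(
        window=window, curve_isis=config.grid.copy(), curve=model(config.grid),
        observations=tuple(observations), converged=converged,
        end_history=tuple(end_history), method="pf",
    )
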