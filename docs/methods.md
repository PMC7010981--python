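# Methods

## Problem and model

Pairing a peripheral mechanical stimulus (a robotic tendon tap) with a
sub-threshold TMS pulse to the motor cortex enhances the motor evoked
potential (MEP) only when the two stimuli fall within a subject-specific
range of inter-stimulus intervals — the effective ISI window (ISI-W).  The
timing variable is `ISI = t_TMS − t_hit`, where `t_hit = t_valve + t_delay`
is the hammer impact time and `t_delay` the pneumatic system latency
(repeatable within a subject, ≈195.5 ± 2 ms SD).

The ISI–MEP enhancement profile is modeled as a single Gaussian riding on a
small baseline response `b`:

    E[MEP](x) = b + A · exp(−(x − μ)² / (2σ²))

The effective window is the two-sigma interval `[μ − 2σ, μ + 2σ]` — the
region holding ≈95% of the enhancement mass, whose endpoints sit at
`exp(−2) ≈ 0.135` of the normalized peak.  Mapping a full profile by
incrementally sweeping ISIs (12 trials per 5 ms step over 50 steps) costs
600 trials and ≈130 minutes per subject; the adaptive estimators below reach
a comparable window estimate in a few dozen trials.

## Estimation strategies

All methods observe noisy MEPs, refit a profile, extract a window, and
choose the next ISI, iterating until the stopping rule fires.

* **NR** — nonlinear least-squares fit of the single Gaussian
  (`scipy.optimize.least_squares`, three starts: argmax-, moment- and
  midpoint-based; box constraints keep `σ > 0` and `μ` within one span of
  the observed range).  Window = `μ ± 2σ`.
* **SVMR** — support-vector regression (RBF kernel, ε-tube at 10% of the
  observed MEP range, `C = 10`).  The RBF length scale starts at 25 ms and
  is re-matched to a quarter of the current window estimate as the iteration
  sharpens it.  Window read off the predicted curve (below).
* **GPR** — Gaussian-process regression with a squared-exponential kernel
  (length scale initialized at 25 ms) plus a white-noise term, both fitted
  by marginal likelihood.  Window read off the posterior mean curve.
* **PF** — 30 particles spread over the search range; each iteration every
  particle observes the MEP at its position, weights are multiplied by the
  observed amplitude (plus a 1% floor so an all-zero batch degrades to
  uniform), systematic resampling follows, and resampled positions receive
  Gaussian jitter with SD of one grid step.  The window comes from a
  single-Gaussian fit to all accumulated observations.

**Acquisition.**  The exact per-method acquisition rules are this package's
own concretization: NR and SVMR alternate between the current lower and
upper window-end estimates (grid-snapped) because boundary uncertainty
dominates the interval-overlap score; GPR observes the grid ISI with
maximal posterior predictive variance (the standard active-learning
criterion); PF observes at its resampled particle positions.  They are
implemented behind one dispatch point (`acquire_next_isi`) so alternative
rules can be swapped in.

**Curve-to-window extraction.**  Nonparametric curves are thresholded at
0.135 of their peak, with linear interpolation between grid points and edge
flags when the curve is still supra-threshold at a range boundary.  Because
the simulated response includes the baseline `b` at every ISI, the curve's
floor (its minimum over the grid) is subtracted before thresholding, and
the parametric fits are likewise applied to floor-subtracted observations;
otherwise every window would be biased wide by the offset, which is not
part of the enhancement profile.

**Stopping rule.**  Iteration ends when the sample variances (n−1
denominator) of both the lower and the upper window end over the last 5
iterations are below 50 ms², or at the 99th iteration.  `sqrt(50) ≈ 7 ms`
SD, i.e. about one 5 ms grid step of residual end motion is tolerated.
Sample rather than population variance is the stricter conventional choice;
at the threshold's printed precision the distinction is immaterial.  A run
is *converged* when the variance rule fires before the cap.

**Initial design.**  NR/SVMR/GPR start from `n_ini` evenly spaced grid
ISIs including both range endpoints (7 by default; NR needs ≥ 4 for its
four observations at three distinct ISIs).  If no initial observation is
positive, unsampled grid points are probed farthest-first; if the whole
grid stays silent the run fails with "no response in search range".

**Search-range modes.**  With an accelerometer the detected impact anchors
the range at ISI 0 (span `[0, 500 − t_delay]` ms); without one the range
extends back to the valve command (`[−t_delay, 500 − t_delay]`, rounded
outward to the grid).  The contrast is purely a search-range change.

## Virtual subjects

The generator emulates the statistical structure of the protocol's
measurements:

| parameter | default | meaning |
|---|---|---|
| window length | Normal(108, 45) ms, truncated ≥ 20 ms | subject-to-subject ISI-W variability; `σ = length/4` |
| delay | Normal(195.5, 2) ms | pneumatic latency; repeatable within subject |
| peak amplitude | Uniform(0.3, 1.5) mV | per-subject enhancement peak (not reported per subject; free parameter) |
| baseline | 0.05 mV | response at 100% resting motor threshold |
| trial noise | multiplicative Gaussian, CV 0.3 | `MEP = E[MEP]·(1 + cv·z)`, clipped at 0 |

The 20 ms truncation floor avoids degenerate near-zero windows (the
narrowest physiological windows discussed for electrical stimulation are
15–20 ms).  Multiplicative noise reproduces the visibly larger scatter at
larger MEP amplitudes; the CV default is a realistic order for MEP
variability and is exposed as a parameter.  The profile center is placed
uniformly so the true window fits inside the impact-referenced span.
Enhancement is centered on impact-referenced ISI, so accelerometer mode
removes the delay nuisance exactly; valve-referenced querying re-adds it.

**Ground truth.**  The conventional sweep records the mean of 10 kept
repetitions per grid ISI (2 of 12 discarded) and takes the longest
contiguous run of ISIs whose mean exceeds the baseline.  Because the
simulated expectation is strictly above the baseline at *every* ISI, a
literal "above baseline" comparison is ill-posed under this model; the
operational criterion used is `mean ≥ b + exp(−2)·(peak − b)` — the same
normalized two-sigma level used for window extraction.  With zero noise
this recovers the true window's grid-rounded endpoints exactly, and under
trial noise the exp(−2) margin dwarfs the standard error of a 10-trial
mean.  Ties between equal-length runs go to the earlier one.

**Normality stage.**  Whether a measured profile is consistent with the
Gaussian shape is checked by treating the baseline-subtracted mean profile
as a density over ISI, drawing a deterministic mid-quantile sample of ISIs
from it, and applying the Shapiro–Wilk test (`evaluation.profile_normality`).
On simulated populations the large majority of subjects pass at α = 0.05,
consistent with predominantly unimodal profiles.

**What the simulator does not capture:** bimodal or skewed physiological
profiles (a two-Gaussian fit exists for model criticism, not as a truth
mode), inhibitory responses under supra-threshold TMS, session drift,
startle habituation beyond the two discarded trials, and EMG artifacts
other than the synthetic spikes in `simulate_emg_trace`.  Passing tests
therefore demonstrate correctness of the procedure under the stated
statistical model, not performance on any particular human cohort.

## Evaluation

* **Interval F1** — computed on continuous interval lengths: TP is the
  overlap of estimated and true windows, FP/FN the uncovered remainders,
  `F1 = 2TP/(2TP + FP + FN)`.  The continuous form is invariant to grid
  bin offsets; identical windows score 1, disjoint ones 0.
* **Profile correlation** — Pearson r between the estimated curve and the
  sweep means on the shared grid.
* **Convergence percentage** — share of runs whose variance rule fired
  before the 99-iteration cap.
* **Observation count** — number of MEP measurements until stopping (for
  PF, all per-particle observations count).

The benchmark harness sweeps (method × n_ini × mode) cells over a seeded
population; each cell reports mean/SD of F1 and observation count, mean
correlation and convergence percentage.  NR cells with `n_ini < 4` are
marked unavailable.  Descriptive summaries only; significance testing
between methods is out of scope.

## Numerical choices and degenerate inputs

* Impact detection accepts the first post-onset zero crossing in either
  direction (sensor polarity unknown) and interpolates linearly; the onset
  threshold defaults to 10% of the trace's maximum magnitude.
* Gaussian fits use `xtol = ftol = 1e-14` so the noiseless limit recovers
  parameters to ≈1e-6 relative; a failed fit from every start raises
  rather than returning garbage, and the estimation loop falls back to
  farthest-point acquisition until a fit succeeds.
* The two-Gaussian fit is seeded with the single-Gaussian solution plus a
  zero-amplitude second component, so unimodal data keeps the second
  amplitude at zero instead of splitting the peak between two collinear
  components.
* Ties in curve maxima and acquisition argmaxes resolve to the lowest grid
  index; all randomness flows through `numpy` Generators seeded from the
  run seed, making every result bit-reproducible.
* Problem sizes in the test-suite and acceptance runs (20–50 subjects per
  population check, 1,000–10,000 draws for Monte-Carlo moments) were chosen
  as the smallest sizes at which the checked statistics are stable across
  seeds.

## Known limitations

* The estimators assume a single response hump; on genuinely bimodal
  profiles the window brackets only the dominant hump.
* SVMR's ε-tube (10% of range) limits its window precision at low
  amplitudes; GPR is the more reliable default, NR the cheapest.
* Valve-referenced mode wastes observations in the pre-impact dead zone,
  which is exactly the inefficiency the accelerometer mode removes; on
  narrow windows the end-refinement acquisition of NR/SVMR can converge on
  a locally stable but biased window.
* The offline-pool mode answers queries with the nearest recorded ISI,
  cycling through its repetitions; sparse pools therefore alias
  neighbouring ISIs (a warning is logged beyond one grid step).
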