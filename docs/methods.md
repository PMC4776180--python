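# Methods

## Generative model

The world model is a two-level hidden Markov process on the hue circle.
A category `c_t in {1..n}` (default n = 3, focal hues equally spaced) stays
put with probability `1 - switch_prob` and otherwise jumps uniformly to one
of the other categories (`switch_prob` default 0.02 per step — categories are
assumed to vary slowly relative to the sensory frame rate). Given the
category, the hue is redrawn every step from
`s_t ~ vonMises(mu_{c_t}, kappa_cat)`; the observation is
`x_t = s_t + wrapped Gaussian noise`.

Parameter defaults and rationale:

| parameter | default | units | rationale |
|---|---|---|---|
| `n_units` | 300 | — | hue-selective units tiling the circle |
| `kappa` | 2.0 | — | tuning half-width ≈ 48°, plausible for IT color cells |
| `gain` | 1.0 | rate | peak rate; all rates are in units of it |
| `kappa_cat` | 8.0 | — | emission SD ≈ 20°: hues fluctuate tightly around the focal hue, well inside a 120° category span |
| `obs_noise_sd` | 10° | deg | matched to human hue-discrimination thresholds |
| `switch_prob` | 0.02 | /step | slow category dynamics |
| `lambda_hue` | 0.7 | — | continuity-prior weight; must be < 1 for bounded activity |
| `lambda_cat` | 0.3 | gain | categorical-prior weight in the categorization task; 0 models discrimination |
| `topdown_kappa` | = `kappa_cat` | — | the top-down bump encodes exactly the categorical prior |

`kappa_cat` was initially considered at 2.0 (SD ≈ 40°) but that regime puts a
large fraction of emissions nearer a neighboring category's focal hue,
contradicting the intended picture of small fluctuations around
representative hues with discontinuous transitions between them; 8.0 is the
frozen default.

## Network

Activity is updated as
`r(t) = b(t) + lambda_hue * r(t-1) + lambda_cat * h(theta - mu_{c_hat})`,
rectified at zero (the clip never binds under the default nonnegative
terms; a config switch disables it). The category estimate `c_hat` is a
winner-take-all argmax of linear readouts
`u_c = sum_i kappa_cat * cos(theta_i - mu_c) * r_i` — the log of the
category-conditional von Mises without its normalizer, which cancels in the
argmax. Ties break to the lowest index everywhere (argmax, winner-take-all,
peak decoding); at an exact category boundary this makes the memory drift
direction deterministic.

**First update from rest.** From an all-zero state the winner-take-all has no
evidence; the category estimate is `None` and the top-down term is zero for
that step. Without this guard, the lowest-index tie-break would inject a
category-0 bump at stimulus onset in every trial regardless of the stimulus.
Consequently the first post-onset activity is the pure bottom-up pattern, and
the top-down signal first acts on the second update.

**Decoders.** The peak decoder returns the preferred hue of the most active
unit (grid resolution 2π/N); the population-vector decoder (activity-weighted
circular mean) resolves sub-grid structure and is used where grid
quantization would mask small biases (clustering analysis).

## Exact filter oracle

`exact_online_posterior` runs the exact forward filter for the same
generative model on a hue grid: the category belief is propagated through the
transition matrix (the hue carries no inertia of its own, being redrawn from
the category each step), combined with the grid-normalized von Mises emission
and the wrapped-Gaussian observation likelihood (±3 wraps), and normalized.
All arithmetic is in the log domain with per-step normalization; an
everywhere-vanishing likelihood raises an explicit underflow error.

Agreement between network and filter is measured per step as the Pearson
correlation, across grid points, of the mean-removed log activity profile
with the mean-removed log posterior (the population code represents
log-probability up to an affine map, so the comparison is scale-free). In the
stable-category regime the mean correlation exceeds 0.9. After a category
switch the exact posterior relocates within one step while the network's
lateral memory takes ~3 steps to decay, so sequences containing switches
average lower (~0.87–0.89 at `switch_prob` 0.02 over 20-step horizons). This
transient lag is inherent to the continuity prior of the three-term
recurrence and is the price of its hardware simplicity; it is reported, not
hidden.

## Ideal observer

Fisher information uses the Poisson-population form `J = sum_i f_i'^2 / f_i`
on the effective (trial-averaged) tuning at a fixed post-onset step.
Derivatives use a fourth-order (5-point) circular central-difference stencil:
at the 0.1° grid used for analytic validation the truncation error is far
below the 1e-6 relative agreement checked against the single-neuron closed
form, and terms with `f_i = f_i' = 0` contribute zero. The threshold constant
in `delta = k/sqrt(J)` is 1; reported profiles are normalized.

Effective tuning is measured with **common random numbers**: one sensory-
noise offset matrix (trials × steps) is drawn and shared across the whole
stimulus grid, so the trial-averaged tuning is a smooth function of the
stimulus and its finite differences measure signal, not independent
Monte-Carlo jitter (without CRN the threshold profile of even the top-down-
free network shows spurious ~3x max/min structure at 200 trials; with CRN it
is exactly flat). Defaults: 72-point stimulus grid, 200 trials per stimulus.
Noise-averaged tuning is the default; a single deterministic run is available
by setting `noise_sd = 0`.

A consequence of measuring the code at step 2 with the default
`lambda_cat = 0.3` is that the trial-averaged winner transition at category
boundaries (width ≈ the 10° sensory noise) already contributes boundary
Fisher information early: the early threshold profile has max/min ≈ 1.4
rather than being flat. The categorical structure still grows strongly with
time (max/min ≈ 2.7 by step 20, with thresholds at category centers clearly
above boundaries), so the early/late *contrast* is robust even though the
early profile is not strictly flat under the default top-down weight.

## Phenomenon drivers

All four drivers run under the single shared default parameterization.

* **Gain modulation** compares late-step (step 20) trial-averaged tuning with
  `lambda_cat = 0.3` vs `0.0`, using the same noise draws in both conditions
  (paired design) so per-unit differences isolate the top-down effect.
  Reported: per-unit Pearson correlation between conditions, amplitude
  difference, preferred-stimulus shift.
* **Clustering** decodes each stimulus's late-step representation as
  (population-vector hue, peak height) in 2-D and reports the within- vs
  between-category mean pairwise distance ratio; stimuli are offset slightly
  from exact boundaries so true memberships are unambiguous.
* **Memory** runs one noiseless encoding step and then input-free updates;
  the decoded peak drifts monotonically onto the nearest focal hue, which is
  an exact fixed point.
* **Discrimination** builds early (step 2) and late (step 20) threshold
  profiles and returns the late profile normalized by the early one.

## Population peak-shift pipeline

Recording tables are tidy DataFrames (`neuron_id, task, stimulus,
time_bin_ms, rate`). Preferred stimuli are classified by the argmax of the
stimulus-mean response in the *fixation* task (the task-neutral condition
that also anchors normalization; an all-task variant is a keyword away).
Rates are divided per neuron by the maximum fixation rate; zero-max neurons
are dropped with a warning. Population profiles (mean normalized rate per
preference group) are fitted with an unweighted Gaussian over the linear
stimulus index 1..11 — the 11 stimuli span a red→green line, not a closed
circle — with multi-start initialization (argmax and weighted-mean starts,
two width starts) and no baseline term by default; fits with peaks outside
[1, 11] or widths beyond the stimulus range are flagged unreliable. Flat
profiles yield an unreliable flag, not a spurious peak.

Peak-shift curves cover stimuli 2..10 (the extremes suffer boundary effects
in the Gaussian fit) and are normalized per stimulus by the absolute
difference at the 100 ms bin; values below a 1e-3 index-unit floor leave the
curve unnormalized with a flag. The bootstrap resamples neurons with
replacement (100 resamples by default), keeps the original preference
assignment, seeds each refit from the original fit (single start), and scales
resampled raw shifts by the original normalization decision, so the SDs are
error bars for the reported curve. The boundary is the linearly interpolated
zero crossing of the late-window (450–550 ms) mean shifts.

The synthetic generator assigns 125 neurons balanced across 11 preferred
stimuli, Gaussian tuning (width 1.5 index units, 10% amplitude
heterogeneity), task gains (categorization 1.2, others 1.0), additive rate
noise (SD 0.5 spikes/s on a 10 spikes/s peak), and — in the categorization
task — a peak displacement growing linearly from 0.1 index units at 100 ms
to 0.5 at 550 ms, directed away from the boundary at 5.5 (zero exactly on a
boundary stimulus). It emulates trial-averaged, task-modulated IT-like data
with a known injected effect; it does not emulate spike-count variability,
noise correlations between neurons, response latencies, or baseline firing,
so pipeline tests establish estimator correctness, not biological realism.

## Numerical choices and limitations

* Angles are radians on [0, 2π) internally; degrees at the CLI boundary.
* One user-facing seed fans out to named `SeedSequence` substreams per
  experiment, so adding an experiment never perturbs another's draws.
* Winner-take-all ties at exact category boundaries are resolved by unit
  index; rotation-equivariance holds everywhere except on that knife edge,
  where floating-point noise picks the winner.
* The model is strictly 1-D on the hue circle: no vividness/saturation
  dimension, no cone-opponent front end, and no spiking or noise-correlation
  structure.
* The mapping from model time steps to milliseconds is a free scaling; the
  drivers use steps 2 and 20 as "early" and "late".
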