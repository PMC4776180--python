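# catpop

Recurrent population-code model of categorical color perception, with an
ideal-observer analysis and a neural-population peak-shift analysis pipeline.

## The problem

Categorical perception shapes seemingly low-level sensory processing: recalled
colors drift toward focal colors, same-category hues are harder to tell apart
than hues straddling a category boundary, and color-selective cortical neurons
change their response gain with task demands. `catpop` implements a single
mechanistic account of these effects: a bank of hue-selective neurons whose
recurrent dynamics approximate *online hierarchical Bayesian inference* over a
world in which a discrete color category `c_t` evolves slowly (a Markov chain
with switch probability `p`), the hue `s_t ~ vonMises(mu_c, kappa_cat)`
fluctuates around the focal hue of the active category, and observations carry
wrapped-Gaussian sensory noise (SD 10° by default).

## The model

Each of N = 300 hue-selective units has a von Mises tuning curve
`f_i(s) = g * exp(kappa * (cos(s - theta_i) - 1))` with preferred hues
`theta_i` tiling the circle. The population activity `r(t)` carries an
(affine-transformed) log posterior over hue and is updated by three additive
terms per time step:

```
r_i(t) = b_i(t)  +  lambda_hue * r_i(t-1)  +  lambda_cat * h(theta_i - mu_{c_hat(t-1)})
```

* `b_i(t)` — bottom-up drive: the tuning response to the (noisy) observation,
  playing the role of the sensory likelihood;
* `lambda_hue * r(t-1)` — lateral self-feedback: a continuity prior on hue;
* the top-down term — a bell-shaped bump (von Mises, sharpness `kappa_cat`)
  centered on the focal hue of the category `c_hat(t-1)` estimated by a
  winner-take-all readout `c_hat = argmax_c sum_i kappa_cat * cos(theta_i - mu_c) * r_i`,
  playing the role of the categorical prior.

An exact forward filter for the same generative model on a hue grid
(`exact_online_posterior`) serves as the oracle the network is meant to
approximate. The ideal-observer module computes Fisher information
`J(s) = sum_i f_i'(s)^2 / f_i(s)` of the network's effective tuning and the
asymptotic discrimination threshold `delta(s) = 1/sqrt(J(s))`. The
`neuroanalysis` module implements a population peak-shift pipeline for tidy
recording tables (neuron × task × stimulus × time bin): preferred-stimulus
grouping, fixation-max normalization, Gaussian fits of 11-point population
profiles, task-difference peak-shift dynamics normalized at the 100 ms bin,
neuron-level bootstrap, and boundary localization — plus a synthetic
multi-task recording generator (125 neurons, 11 stimuli on a red→green line,
3 tasks) with known ground truth.

## Worked example

```python
import numpy as np
from catpop import (make_uniform_population, CategorySet, NetworkParams,
                    run_memory, run_clustering, run_gain_modulation)

pop = make_uniform_population()            # 300 hue-selective units
cats = CategorySet.equally_spaced(3)       # focal hues at 0, 120, 240 deg
task_cat = NetworkParams()                 # categorization: top-down on
task_disc = NetworkParams(lambda_cat=0.0)  # discrimination: top-down off

mem = run_memory(pop, cats, task_cat, initial_hue=np.deg2rad(150), n_steps=20)
print("memory drift (deg from nearest focal hue):",
      np.round(np.rad2deg(mem.distance_to_center[[0, 4, 9, 19]]), 1))

rng = np.random.default_rng(0)
gain = run_gain_modulation(pop, cats, task_cat, task_disc,
                           rng=rng, noise_sd=np.deg2rad(10))
print(f"amplitude difference (cat - disc): {gain.mean_amplitude_difference:+.3f}")
print(f"median tuning correlation:         {gain.median_correlation:.3f}")

clus_cat = run_clustering(pop, cats, task_cat, rng=np.random.default_rng(1),
                          noise_sd=np.deg2rad(10))
clus_disc = run_clustering(pop, cats, task_disc, rng=np.random.default_rng(1),
                           noise_sd=np.deg2rad(10))
print(f"clustering index: {clus_cat.clustering_index:.3f} (categorization) "
      f"vs {clus_disc.clustering_index:.3f} (discrimination)")
```

prints

```
memory drift (deg from nearest focal hue): [30.   1.2  0.   0. ]
amplitude difference (cat - disc): +0.143
median tuning correlation:         0.997
clustering index: 0.443 (categorization) vs 0.519 (discrimination)
```

A remembered hue 30° from a focal color drifts onto it within a few steps of
input-free recurrence; turning the top-down signal on raises mean response
amplitude by ~14% of the peak rate while leaving tuning shape intact
(median correlation 0.997); and decoded population representations of
same-category hues move closer together relative to different-category hues
(smaller within/between distance ratio).

## Command line

```sh
catpop simulate --seed 1 --out run1            # generative sequence + network run
catpop phenomenon memory --seed 1 --out run2   # gain | clustering | memory | threshold
catpop observe --time-step 20 --out run3       # Fisher / threshold profile
catpop synth --preset effect --seed 2 --out fix # synthetic recording table
catpop analyze --table fix/recording.csv --out ana
```

Each run writes CSV artifacts plus a `manifest.json` (config echo, seed,
version) sufficient to reproduce it byte-for-byte. Angles are degrees at the
CLI boundary, radians internally.

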