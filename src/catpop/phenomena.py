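"""Experiment drivers for the four categorical-perception phenomena.

Each driver exercises the recurrent network under the shared default
parameterization and summarizes one reported effect:

* gain modulation -- categorization (top-down on) boosts single-unit
  response amplitude while preserving tuning shape;
* clustering -- decoded population representations are attracted toward
  the focal hues, so same-category stimuli cluster;
* memory drift -- with the input removed, the remembered hue drifts to
  the nearest focal hue;
* discrimination -- the late-response discrimination threshold is elevated
  at category centers relative to boundaries, while the early response
  shows little categorical structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ._angles import TWO_PI, circ_diff, circ_dist
from .exceptions import InvalidParameterError
from .network import (NetworkParams, population_vector_decode, run_trial,
                      run_trial_batch)
from .observer import (EffectiveTuning, ThresholdProfile,
                       effective_tuning_at_step, threshold_profile)
from .popcode import (DEFAULT_OBS_NOISE_SD, CategorySet, HuePopulation,
                      PopulationActivity)

#: Measurement step for "late" responses in tuning/clustering analyses.
LATE_STEP = 20
EARLY_STEP = 2


@dataclass(frozen=True, eq=False)
class GainModulationResult:
    """Per-unit comparison of tuning under categorization vs discrimination."""

    stimulus_set: np.ndarray
    tuning_categorization: np.ndarray  # (N, S)
    tuning_discrimination: np.ndarray  # (N, S)
    correlation: np.ndarray            # per-unit Pearson r between conditions
    amplitude_difference: np.ndarray   # per-unit mean-rate difference (cat - disc)
    preferred_shift: np.ndarray        # per-unit circular shift of preferred stimulus

    @property
    def median_correlation(self) -> float:
        return float(np.median(self.correlation))

    @property
    def mean_amplitude_difference(self) -> float:
        return float(np.mean(self.amplitude_difference))

    @property
    def mean_preferred_shift(self) -> float:
        return float(np.mean(self.preferred_shift))


@dataclass(frozen=True, eq=False)
class ClusteringResult:
    """Decoded 2-D representation per stimulus and the within/between ratio."""

    stimulus_hues: np.ndarray
    decoded_points: np.ndarray     # (S, 2): peak-height radius, pop-vector angle
    memberships: np.ndarray        # true category per stimulus (nearest center)
    within_distance: float
    between_distance: float

    @property
    def clustering_index(self) -> float:
        return self.within_distance / self.between_distance

    def decoded_points_angle(self) -> np.ndarray:
        """Decoded hue per stimulus (direction of the 2-D point)."""
        return np.mod(np.arctan2(self.decoded_points[:, 1],
                                 self.decoded_points[:, 0]), TWO_PI)


@dataclass(frozen=True, eq=False)
class MemoryTrajectory:
    """Decoded-peak evolution after the input is removed."""

    initial_hue: float
    decoded_peaks: np.ndarray
    distance_to_center: np.ndarray  # circular distance to nearest focal hue

    @property
    def final_distance(self) -> float:
        return float(self.distance_to_center[-1])


def _measure_tuning(population: HuePopulation, categories: CategorySet,
                    params: NetworkParams, stimulus_set: np.ndarray,
                    offsets: np.ndarray, time_step: int) -> np.ndarray:
    rates = np.empty((population.n_units, stimulus_set.size))
    n_trials = offsets.shape[0]
    for j, stim in enumerate(stimulus_set):
        act = run_trial_batch(stim, population, categories, params,
                              n_steps=time_step, n_trials=n_trials,
                              noise_sd=0.0, noise_offsets=offsets)
        rates[:, j] = act.mean(axis=0)
    return rates


def run_gain_modulation(population: HuePopulation, categories: CategorySet,
                        params_cat: NetworkParams, params_disc: NetworkParams,
                        stimulus_set: Optional[Sequence[float]] = None,
                        n_trials: int = 100,
                        rng: Optional[np.random.Generator] = None,
                        noise_sd: float = DEFAULT_OBS_NOISE_SD,
                        time_step: int = LATE_STEP) -> GainModulationResult:
    """Compare late-step tuning curves with and without the top-down signal.

    The two conditions must differ only in ``lambda_cat``.  Both are driven
    with the same sensory-noise draws (paired design), so per-unit
    differences isolate the top-down effect rather than noise jitter.
    """
    if (params_cat.lambda_hue != params_disc.lambda_hue
            or params_cat.rectify != params_disc.rectify):
        raise InvalidParameterError("conditions must differ only in lambda_cat")
    if stimulus_set is None:
        stimulus_set = TWO_PI * np.arange(24) / 24
    stimulus_set = np.asarray(stimulus_set, dtype=float)
    if stimulus_set.size < 3:
        raise InvalidParameterError("need at least 3 stimuli for correlations")

    if noise_sd > 0:
        if rng is None:
            raise InvalidParameterError("noise_sd > 0 requires an rng")
        offsets = rng.normal(0.0, noise_sd, size=(n_trials, time_step))
    else:
        offsets = np.zeros((n_trials, time_step))

    tc = _measure_tuning(population, categories, params_cat, stimulus_set,
                         offsets, time_step)
    td = _measure_tuning(population, categories, params_disc, stimulus_set,
                         offsets, time_step)

    tc_c = tc - tc.mean(axis=1, keepdims=True)
    td_c = td - td.mean(axis=1, keepdims=True)
    denom = np.sqrt((tc_c ** 2).sum(axis=1) * (td_c ** 2).sum(axis=1))
    corr = (tc_c * td_c).sum(axis=1) / denom

    amp_diff = tc.mean(axis=1) - td.mean(axis=1)
    shift = circ_diff(stimulus_set[np.argmax(tc, axis=1)],
                      stimulus_set[np.argmax(td, axis=1)])
    return GainModulationResult(stimulus_set=stimulus_set,
                                tuning_categorization=tc,
                                tuning_discrimination=td,
                                correlation=corr,
                                amplitude_difference=amp_diff,
                                preferred_shift=shift)


def run_clustering(population: HuePopulation, categories: CategorySet,
                   params: NetworkParams, n_stimuli: int = 12,
                   n_trials: int = 50,
                   rng: Optional[np.random.Generator] = None,
                   noise_sd: float = DEFAULT_OBS_NOISE_SD,
                   time_step: int = LATE_STEP,
                   stimulus_offset: float = 0.1) -> ClusteringResult:
    """Decode late-step representations of evenly spaced stimuli.

    Each stimulus maps to a 2-D point: direction = population-vector hue
    (sub-grid resolution), radius = trial-averaged peak height.  The
    clustering index is the ratio of mean pairwise distances within vs
    between true categories (smaller = stronger clustering).  A small
    ``stimulus_offset`` keeps stimuli off exact category boundaries.
    """
    if n_stimuli < 2 * categories.n:
        raise InvalidParameterError("need at least 2 stimuli per category")
    stims = TWO_PI * np.arange(n_stimuli) / n_stimuli + stimulus_offset
    if noise_sd > 0 and rng is None:
        raise InvalidParameterError("noise_sd > 0 requires an rng")
    points = np.empty((n_stimuli, 2))
    for j, s in enumerate(stims):
        act = run_trial_batch(s, population, categories, params,
                              n_steps=time_step, n_trials=n_trials,
                              noise_sd=noise_sd, rng=rng)
        mean_act = act.mean(axis=0)
        hue = population_vector_decode(PopulationActivity(mean_act), population)
        radius = float(mean_act.max())
        points[j] = radius * np.array([np.cos(hue), np.sin(hue)])
    member = np.asarray(categories.nearest(stims))

    within, between = [], []
    for i in range(n_stimuli):
        for j in range(i + 1, n_stimuli):
            d = float(np.linalg.norm(points[i] - points[j]))
            (within if member[i] == member[j] else between).append(d)
    if not within or not between:
        raise InvalidParameterError("degenerate stimulus/category layout")
    return ClusteringResult(stimulus_hues=stims, decoded_points=points,
                            memberships=member,
                            within_distance=float(np.mean(within)),
                            between_distance=float(np.mean(between)))


def run_memory(population: HuePopulation, categories: CategorySet,
               params: NetworkParams, initial_hue: float, n_steps: int = 20,
               rng: Optional[np.random.Generator] = None,
               noise_sd: float = 0.0) -> MemoryTrajectory:
    """One encoding step at ``initial_hue``, then updates with zero input.

    Noiseless by default so the trajectory is deterministic; pass
    ``noise_sd`` > 0 (with an rng) for a noisy encoding variant.
    """
    if n_steps < 2:
        raise InvalidParameterError("n_steps must be >= 2")
    traj = run_trial([initial_hue] + [None] * n_steps, population, categories,
                     params, rng=rng, noise_sd=noise_sd)
    peaks = traj.decoded_peaks
    dist = np.array([np.min(circ_dist(p, categories.centers)) for p in peaks])
    return MemoryTrajectory(initial_hue=float(initial_hue), decoded_peaks=peaks,
                            distance_to_center=dist)


def run_discrimination(population: HuePopulation, categories: CategorySet,
                       params: NetworkParams, early_step: int = EARLY_STEP,
                       late_step: int = LATE_STEP,
                       rng: Optional[np.random.Generator] = None,
                       n_trials: int = 200, grid_size: int = 72,
                       noise_sd: float = DEFAULT_OBS_NOISE_SD
                       ) -> Tuple[ThresholdProfile, ThresholdProfile]:
    """Early threshold profile and the late profile normalized by it."""
    if early_step >= late_step:
        raise InvalidParameterError("early_step must precede late_step")
    early_tuning = effective_tuning_at_step(population, categories, params,
                                            early_step, n_trials=n_trials,
                                            rng=rng, grid_size=grid_size,
                                            noise_sd=noise_sd)
    late_tuning = effective_tuning_at_step(population, categories, params,
                                           late_step, n_trials=n_trials,
                                           rng=rng, grid_size=grid_size,
                                           noise_sd=noise_sd)
    early = threshold_profile(early_tuning)
    late_normalized = threshold_profile(late_tuning, normalize_by=early)
    return early, late_normalized
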