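"""Ideal-observer analysis: Fisher information and discrimination thresholds.

Under Poisson-like spiking statistics, a population with trial-averaged
tuning curves f_i(theta) carries Fisher information

    J(theta) = sum_i f_i'(theta)^2 / f_i(theta)

about the stimulus, and an ideal decoder's asymptotic discrimination
threshold is delta(theta) = k / sqrt(J(theta)) (the constant k is absorbed
whenever profiles are normalized).  Effective tuning curves are measured
from the running network at a fixed post-onset time step, trial-averaged
over sensory-noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._angles import TWO_PI
from .exceptions import (InvalidInputError, InvalidParameterError,
                         SingularInformationError)
from .network import NetworkParams, run_trial_batch
from .popcode import DEFAULT_OBS_NOISE_SD, CategorySet, HuePopulation

DEFAULT_GRID_SIZE = 72
DEFAULT_N_TRIALS = 200


@dataclass(frozen=True, eq=False)
class EffectiveTuning:
    """Trial-averaged rates of every unit across an even stimulus grid.

    ``mean_rates[i, j]`` is unit i's mean rate when stimulus ``stimulus_grid[j]``
    was held constant up to the measurement step.
    """

    stimulus_grid: np.ndarray
    mean_rates: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.stimulus_grid, dtype=float)
        rates = np.asarray(self.mean_rates, dtype=float)
        object.__setattr__(self, "stimulus_grid", grid)
        object.__setattr__(self, "mean_rates", rates)
        if grid.ndim != 1 or grid.size < 5:
            raise InvalidInputError("stimulus grid needs at least 5 points")
        spacing = TWO_PI / grid.size
        if not np.allclose(np.diff(grid), spacing, atol=1e-9):
            raise InvalidInputError("stimulus grid must be even over [0, 2*pi)")
        if rates.ndim != 2 or rates.shape[1] != grid.size:
            raise InvalidInputError("mean_rates must be (n_units, grid)")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise InvalidInputError("mean rates must be finite and nonnegative")

    @property
    def grid_spacing(self) -> float:
        return TWO_PI / self.stimulus_grid.size


@dataclass(frozen=True, eq=False)
class ThresholdProfile:
    """Discrimination threshold per grid stimulus, optionally normalized."""

    stimulus_grid: np.ndarray
    threshold: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "stimulus_grid",
                           np.asarray(self.stimulus_grid, dtype=float))
        object.__setattr__(self, "threshold",
                           np.asarray(self.threshold, dtype=float))
        if self.threshold.shape != self.stimulus_grid.shape:
            raise InvalidInputError("threshold/grid shape mismatch")
        if not np.all(np.isfinite(self.threshold)) or np.any(self.threshold <= 0):
            raise InvalidInputError("thresholds must be positive and finite")


def circular_gradient(values: np.ndarray, spacing: float, axis: int = -1) -> np.ndarray:
    """Fourth-order central difference on a periodic grid."""
    v = np.asarray(values, dtype=float)
    return (-np.roll(v, -2, axis) + 8.0 * np.roll(v, -1, axis)
            - 8.0 * np.roll(v, 1, axis) + np.roll(v, 2, axis)) / (12.0 * spacing)


def fisher_information_profile(tuning: EffectiveTuning) -> np.ndarray:
    """J(theta) = sum_i f_i'^2 / f_i over the whole stimulus grid."""
    f = tuning.mean_rates
    df = circular_gradient(f, tuning.grid_spacing, axis=1)
    zero_rate = f == 0.0
    if np.any(zero_rate & (df != 0.0)):
        raise SingularInformationError(
            "zero mean rate with nonzero slope: Fisher information diverges")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(zero_rate, 0.0, df ** 2 / np.where(zero_rate, 1.0, f))
    return terms.sum(axis=0)


def fisher_information(tuning: EffectiveTuning, hue: float) -> float:
    """Fisher information at the grid point nearest ``hue`` (radians^-2)."""
    j = fisher_information_profile(tuning)
    idx = int(np.argmin(np.abs(np.angle(np.exp(1j * (tuning.stimulus_grid - hue))))))
    return float(j[idx])


def discrimination_threshold(J: Union[float, np.ndarray]):
    """Asymptotic threshold delta = 1/sqrt(J); strictly decreasing in J."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise InvalidParameterError("threshold undefined for J <= 0")
    out = 1.0 / np.sqrt(J)
    return float(out) if out.ndim == 0 else out


def effective_tuning_at_step(population: HuePopulation, categories: CategorySet,
                             params: NetworkParams, time_step: int,
                             n_trials: int = DEFAULT_N_TRIALS,
                             rng: Optional[np.random.Generator] = None,
                             grid_size: int = DEFAULT_GRID_SIZE,
                             noise_sd: float = DEFAULT_OBS_NOISE_SD) -> EffectiveTuning:
    """Measure trial-averaged network tuning at a fixed post-onset step.

    Each grid stimulus is held constant for ``time_step`` steps and the
    final-step activity is averaged over ``n_trials`` sensory-noise draws.
    One noise-offset matrix is drawn up front and shared by every grid
    stimulus (common random numbers), so the mean tuning is a smooth
    function of the stimulus and finite differences of it are not swamped
    by independent Monte-Carlo jitter.
    """
    if time_step < 1:
        raise InvalidParameterError("time_step must be >= 1")
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if noise_sd > 0 and rng is None:
        raise InvalidParameterError("noise_sd > 0 requires an rng")

    grid = TWO_PI * np.arange(grid_size) / grid_size
    if noise_sd > 0:
        offsets = rng.normal(0.0, noise_sd, size=(n_trials, time_step))
    else:
        offsets = np.zeros((n_trials, time_step))
    rates = np.empty((population.n_units, grid_size))
    for j, stim in enumerate(grid):
        act = run_trial_batch(stim, population, categories, params,
                              n_steps=time_step, n_trials=n_trials,
                              noise_sd=noise_sd, noise_offsets=offsets)
        rates[:, j] = act.mean(axis=0)
    return EffectiveTuning(stimulus_grid=grid, mean_rates=rates)


def threshold_profile(tuning: EffectiveTuning,
                      normalize_by: Optional[ThresholdProfile] = None) -> ThresholdProfile:
    """Threshold per grid stimulus; optionally divided by a reference profile."""
    delta = discrimination_threshold(fisher_information_profile(tuning))
    if normalize_by is not None:
        if normalize_by.stimulus_grid.shape != tuning.stimulus_grid.shape or \
                not np.allclose(normalize_by.stimulus_grid, tuning.stimulus_grid):
            raise InvalidInputError("normalization profile grid mismatch")
        delta = delta / normalize_by.threshold
    return ThresholdProfile(stimulus_grid=tuning.stimulus_grid, threshold=delta)
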