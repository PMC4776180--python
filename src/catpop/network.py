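"""Recurrent inference network and the exact Bayes-filter oracle.

The hue-selective population carries an (unnormalized, affine-transformed)
log-posterior over hue.  Each time step combines three terms:

* bottom-up input -- the sensory likelihood, encoded as tuned drive;
* lateral self-feedback -- the continuity prior, a scalar decay ``lambda_hue``
  on the population's own previous activity;
* top-down signal -- the categorical prior, a bell-shaped bump centered on
  the focal hue of the category estimated from the previous activity by a
  winner-take-all readout.

`exact_online_posterior` implements the exact forward filter for the same
hierarchical hidden Markov model on a hue grid, and serves as the oracle the
network is meant to approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from ._angles import TWO_PI, circ_diff, wrap_angle
from .exceptions import (InvalidInputError, InvalidParameterError,
                         UndefinedPeakError, UnderflowError)
from .popcode import (CategorySet, GenerativeConfig, HuePopulation,
                      PopulationActivity, encode_stimulus)

DEFAULT_LAMBDA_HUE = 0.7
DEFAULT_LAMBDA_CAT = 0.3


@dataclass(frozen=True)
class NetworkParams:
    """Weights of the recurrent update.

    lambda_hue : weight of the lateral self-feedback (continuity prior);
        must lie in [0, 1) so activity stays bounded under constant input.
    lambda_cat : amplitude of the top-down categorical signal; 0 models the
        discrimination task (no categorical prior), > 0 categorization.
    topdown_kappa : sharpness of the top-down bump; ``None`` means "use the
        category set's kappa_cat", i.e. the top-down signal encodes exactly
        the categorical prior p(s|c).
    rectify : clip activities at zero after each update (firing rates are
        nonnegative; the clip never binds with the default nonnegative
        terms).
    """

    lambda_hue: float = DEFAULT_LAMBDA_HUE
    lambda_cat: float = DEFAULT_LAMBDA_CAT
    topdown_kappa: Optional[float] = None
    rectify: bool = True

    def __post_init__(self):
        if not (0.0 <= self.lambda_hue < 1.0):
            raise InvalidParameterError("lambda_hue must be in [0, 1)")
        if self.lambda_cat < 0:
            raise InvalidParameterError("lambda_cat must be nonnegative")
        if self.topdown_kappa is not None and self.topdown_kappa <= 0:
            raise InvalidParameterError("topdown_kappa must be positive")

    def topdown_kappa_for(self, categories: CategorySet) -> float:
        return categories.kappa_cat if self.topdown_kappa is None else self.topdown_kappa


@dataclass(frozen=True, eq=False)
class NetworkState:
    """Per-step snapshot: activity, current category estimate, step index."""

    activity: PopulationActivity
    category_estimate: Optional[int] = None
    step: int = 0


@dataclass(eq=False)
class Trajectory:
    """Ordered per-step states plus decoded activity peaks."""

    states: list = field(default_factory=list)
    decoded_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))

    def activity_matrix(self) -> np.ndarray:
        """(T, N) matrix of activities."""
        return np.stack([s.activity.rates for s in self.states])

    def category_estimates(self) -> list:
        return [s.category_estimate for s in self.states]


def initial_state(population: HuePopulation) -> NetworkState:
    return NetworkState(activity=PopulationActivity(np.zeros(population.n_units)),
                        category_estimate=None, step=0)


def category_weight_matrix(population: HuePopulation, categories: CategorySet) -> np.ndarray:
    """(n_categories, N) readout weights w_ci = kappa_cat * cos(theta_i - mu_c).

    This is the log of the category-conditional von Mises up to an additive
    constant, which cancels in the winner-take-all argmax.
    """
    theta = population.preferred_hues[None, :]
    mu = categories.centers[:, None]
    return categories.kappa_cat * np.cos(theta - mu)


def category_input(activity: PopulationActivity, population: HuePopulation,
                   categories: CategorySet) -> np.ndarray:
    """Drive to each category unit: u_c = sum_i w_ci * r_i."""
    r = activity.rates
    if r.size != population.n_units:
        raise InvalidInputError("activity length does not match population")
    return category_weight_matrix(population, categories) @ r


def estimate_category(drives) -> int:
    """Winner-take-all: argmax drive, ties broken by lowest index."""
    drives = np.asarray(drives, dtype=float)
    if drives.size < 2:
        raise InvalidInputError("need at least 2 category drives")
    if not np.all(np.isfinite(drives)):
        raise InvalidInputError("drives must be finite")
    return int(np.argmax(drives))


def top_down_signal(category_estimate: int, population: HuePopulation,
                    categories: CategorySet, params: NetworkParams) -> np.ndarray:
    """Categorical-prior bump lambda_cat * exp(k_td*(cos(theta_i - mu_c) - 1))."""
    if not (0 <= category_estimate < categories.n):
        raise InvalidInputError(f"category index {category_estimate} out of range")
    if params.lambda_cat == 0:
        return np.zeros(population.n_units)
    k = params.topdown_kappa_for(categories)
    mu = categories.centers[category_estimate]
    return params.lambda_cat * np.exp(k * (np.cos(population.preferred_hues - mu) - 1.0))


def update_step(state: NetworkState, bottom_up: PopulationActivity,
                population: HuePopulation, categories: CategorySet,
                params: NetworkParams) -> NetworkState:
    """One recurrence step.

    The category is estimated from the *incoming* activity (the previous
    step's posterior); from an all-zero state there is no evidence, the
    estimate stays ``None`` and the top-down term is zero for that step.
    """
    r = state.activity.rates
    b = bottom_up.rates
    if b.size != r.size or r.size != population.n_units:
        raise InvalidInputError("activity/bottom-up length mismatch")

    if np.any(r != 0.0):
        c_hat = estimate_category(category_input(state.activity, population, categories))
        td = top_down_signal(c_hat, population, categories, params)
    else:
        c_hat = None
        td = 0.0

    new = b + params.lambda_hue * r + td
    if params.rectify:
        new = np.maximum(new, 0.0)
    return NetworkState(activity=PopulationActivity(new),
                        category_estimate=c_hat, step=state.step + 1)


def decode_peak(activity: PopulationActivity, population: HuePopulation) -> float:
    """Preferred hue of the maximally active unit (ties: lowest index)."""
    r = activity.rates
    if r.size != population.n_units:
        raise InvalidInputError("activity length does not match population")
    if np.all(r == 0.0):
        raise UndefinedPeakError("peak undefined for all-zero activity")
    return float(population.preferred_hues[int(np.argmax(r))])


def population_vector_decode(activity: PopulationActivity,
                             population: HuePopulation) -> float:
    """Activity-weighted circular mean of preferred hues (sub-grid resolution)."""
    r = activity.rates
    if np.all(r == 0.0):
        raise UndefinedPeakError("population vector undefined for all-zero activity")
    z = np.sum(r * np.exp(1j * population.preferred_hues))
    return float(wrap_angle(np.angle(z)))


def run_trial(stimulus_observations: Sequence[Optional[float]],
              population: HuePopulation, categories: CategorySet,
              params: NetworkParams, rng: Optional[np.random.Generator] = None,
              noise_sd: float = 0.0) -> Trajectory:
    """Drive the network with a sequence of hue observations.

    ``None`` entries mean "no input this step" (zero bottom-up drive), used
    for memory-period simulation.  Each present observation is encoded with
    wrapped-Gaussian sensory noise of SD ``noise_sd`` (0 = noiseless).
    Decoded peaks are NaN while the activity is all-zero.
    """
    if len(stimulus_observations) == 0:
        raise InvalidParameterError("need at least one step")
    if noise_sd > 0 and rng is None:
        raise InvalidParameterError("noise_sd > 0 requires an rng")

    zero = PopulationActivity(np.zeros(population.n_units))
    state = initial_state(population)
    traj = Trajectory()
    peaks = []
    for obs in stimulus_observations:
        if obs is None:
            b = zero
        else:
            b = encode_stimulus(population, obs, noise_sd,
                                rng if rng is not None else np.random.default_rng(0))
        state = update_step(state, b, population, categories, params)
        traj.states.append(state)
        if np.all(state.activity.rates == 0.0):
            peaks.append(np.nan)
        else:
            peaks.append(decode_peak(state.activity, population))
    traj.decoded_peaks = np.asarray(peaks)
    return traj


def run_trial_batch(stimulus_hue: Optional[float], population: HuePopulation,
                    categories: CategorySet, params: NetworkParams,
                    n_steps: int, n_trials: int, noise_sd: float,
                    rng: Optional[np.random.Generator] = None,
                    initial: Optional[np.ndarray] = None,
                    noise_offsets: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized constant-stimulus trials; returns final (n_trials, N) rates.

    Semantically equivalent to ``n_trials`` independent :func:`run_trial`
    calls with a constant stimulus, but runs them as one matrix recursion so
    the ideal-observer sweeps stay fast.  ``noise_offsets`` (n_trials,
    n_steps) supplies pre-drawn sensory-noise offsets; sharing one offset
    matrix across stimuli gives common random numbers, which keeps
    finite-difference derivatives of the trial-averaged tuning clean.
    """
    if n_steps < 1 or n_trials < 1:
        raise InvalidParameterError("n_steps and n_trials must be >= 1")
    if noise_offsets is None:
        if noise_sd > 0:
            if rng is None:
                raise InvalidParameterError("noise_sd > 0 requires an rng")
            noise_offsets = rng.normal(0.0, noise_sd, size=(n_trials, n_steps))
        else:
            noise_offsets = np.zeros((n_trials, n_steps))
    elif noise_offsets.shape != (n_trials, n_steps):
        raise InvalidInputError("noise_offsets must have shape (n_trials, n_steps)")
    N = population.n_units
    theta = population.preferred_hues
    W = category_weight_matrix(population, categories)
    k_td = params.topdown_kappa_for(categories)
    td_table = params.lambda_cat * np.exp(
        k_td * (np.cos(theta[None, :] - categories.centers[:, None]) - 1.0))

    act = np.zeros((n_trials, N)) if initial is None else np.array(initial, dtype=float)
    for t in range(n_steps):
        if stimulus_hue is None:
            b = 0.0
        else:
            hues = float(stimulus_hue) + noise_offsets[:, t]
            b = population.gain * np.exp(
                population.kappa * (np.cos(hues[:, None] - theta[None, :]) - 1.0))
        has_evidence = np.any(act != 0.0, axis=1)
        td = np.zeros((n_trials, N))
        if params.lambda_cat > 0 and np.any(has_evidence):
            winners = np.argmax(act @ W.T, axis=1)
            td[has_evidence] = td_table[winners[has_evidence]]
        act = b + params.lambda_hue * act + td
        if params.rectify:
            np.maximum(act, 0.0, out=act)
    return act


# ---------------------------------------------------------------------------
# Exact grid filter for the hierarchical HMM
# ---------------------------------------------------------------------------

def _log_wrapped_normal(delta: np.ndarray, sd: float, n_wraps: int = 3) -> np.ndarray:
    """Log density of a wrapped Gaussian at angular differences ``delta``."""
    if sd == 0:
        raise InvalidParameterError("observation noise must be positive for filtering")
    ks = np.arange(-n_wraps, n_wraps + 1)
    d = delta[..., None] + TWO_PI * ks
    return logsumexp(-0.5 * (d / sd) ** 2, axis=-1) - 0.5 * np.log(TWO_PI * sd ** 2)


def exact_online_posterior(observations: Sequence[float], config: GenerativeConfig,
                           grid_size: int = 60):
    """Exact forward filter for the category/hue model on a hue grid.

    State: joint (category, hue cell).  Per step: propagate the category
    through the Markov transition (the hue is redrawn from the category each
    step), apply the von Mises emission and the wrapped-Gaussian observation
    likelihood, and normalize.  All arithmetic is in the log domain.

    Returns
    -------
    grid : (G,) hue grid
    hue_posterior : (T, G) per-step posterior over hue cells (sums to 1)
    cat_posterior : (T, n) per-step posterior over categories
    """
    import warnings

    if grid_size < 36:
        warnings.warn("hue grid coarser than 36 cells; posterior may alias",
                      RuntimeWarning)
    observations = np.asarray(observations, dtype=float)
    cats = config.categories
    n = cats.n
    grid = TWO_PI * np.arange(grid_size) / grid_size

    # log p(s | c) on the grid, normalized over cells
    log_emis = cats.kappa_cat * np.cos(grid[None, :] - cats.centers[:, None])
    log_emis = log_emis - logsumexp(log_emis, axis=1, keepdims=True)

    with np.errstate(divide="ignore"):  # switch_prob 0 is a valid chain
        log_T = np.log(config.transition_matrix())

    T_steps = observations.size
    hue_post = np.empty((T_steps, grid_size))
    cat_post = np.empty((T_steps, n))

    log_cat = np.full(n, -np.log(n))  # uniform initial category belief
    for t in range(T_steps):
        if t > 0:
            log_cat = logsumexp(log_cat[:, None] + log_T, axis=0)
        log_lik = _log_wrapped_normal(circ_diff(observations[t], grid),
                                      config.obs_noise_sd)
        log_joint = log_cat[:, None] + log_emis + log_lik[None, :]
        norm = logsumexp(log_joint)
        if not np.isfinite(norm):
            raise UnderflowError(f"filter underflow at step {t}")
        log_joint -= norm
        log_cat = logsumexp(log_joint, axis=1)
        hue_post[t] = np.exp(logsumexp(log_joint, axis=0))
        cat_post[t] = np.exp(log_cat)
    return grid, hue_post, cat_post


def oracle_profile_correlation(observations: Sequence[float],
                               population: HuePopulation, categories: CategorySet,
                               params: NetworkParams, config: GenerativeConfig,
                               grid_size: Optional[int] = None) -> np.ndarray:
    """Per-step Pearson correlation between network and exact log-posterior.

    The network consumes the same observation sequence noiselessly (the
    observations already carry the generative noise).  Its activity profile
    is compared in the log domain -- the population code represents
    log-probability, so ``log r_i(t)`` (mean-removed) is correlated with the
    mean-removed exact log-posterior evaluated at the preferred hues.
    Requires ``grid_size == n_units`` so grids align (the default).
    """
    if grid_size is None:
        grid_size = population.n_units
    if grid_size != population.n_units:
        raise InvalidParameterError("grid must align with the population")
    traj = run_trial(list(observations), population, categories, params)
    _, hue_post, _ = exact_online_posterior(observations, config, grid_size)
    act = traj.activity_matrix()
    log_act = np.log(np.maximum(act, 1e-300))
    log_post = np.log(np.maximum(hue_post, 1e-300))
    cors = np.empty(act.shape[0])
    for t in range(act.shape[0]):
        a = log_act[t] - log_act[t].mean()
        p = log_post[t] - log_post[t].mean()
        cors[t] = float(a @ p / np.sqrt((a @ a) * (p @ p)))
    return cors
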