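"""Hue population codes and the hierarchical generative model of stimuli.

A bank of hue-selective units tiles the color circle with von Mises tuning
curves.  Stimulus sequences come from a two-level generative process: a
color category evolves as a slow Markov chain, the hue of each frame is
drawn from a von Mises distribution around the active category's focal hue,
and the observed hue carries wrapped-Gaussian sensory noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._angles import TWO_PI, circ_dist, wrap_angle
from .exceptions import InvalidInputError, InvalidParameterError

#: Default tuning sharpness; half-width at half-maximum ~48 deg, a plausible
#: bandwidth for color-selective IT neurons.
DEFAULT_KAPPA = 2.0
#: Default peak firing rate (arbitrary rate units).
DEFAULT_GAIN = 1.0
#: Default number of hue-selective units.
DEFAULT_N_UNITS = 300
#: Default concentration of the category-conditional hue distribution
#: (circular SD ~20 deg: hues fluctuate tightly around the focal hue,
#: well inside a 120-deg category span).
DEFAULT_KAPPA_CAT = 8.0
#: Default sensory noise, 10 azimuth degrees on the hue circle.
DEFAULT_OBS_NOISE_SD = np.deg2rad(10.0)


@dataclass(frozen=True, eq=False)
class HuePopulation:
    """Evenly spaced bank of hue-selective units.

    Attributes
    ----------
    preferred_hues : ndarray
        Strictly increasing preferred hues on [0, 2*pi), spacing 2*pi/N.
    kappa : float
        Tuning sharpness (> 0).
    gain : float
        Peak firing rate at the preferred hue (> 0).
    """

    preferred_hues: np.ndarray
    kappa: float
    gain: float

    def __post_init__(self):
        hues = np.asarray(self.preferred_hues, dtype=float)
        object.__setattr__(self, "preferred_hues", hues)
        if hues.ndim != 1 or hues.size < 3:
            raise InvalidParameterError("population needs at least 3 units")
        if self.kappa <= 0 or self.gain <= 0:
            raise InvalidParameterError("kappa and gain must be positive")
        if np.any(np.diff(hues) <= 0):
            raise InvalidParameterError("preferred hues must be strictly increasing")
        spacing = TWO_PI / hues.size
        if not np.allclose(np.diff(hues), spacing, atol=1e-9):
            raise InvalidParameterError("preferred hues must be evenly spaced")

    @property
    def n_units(self) -> int:
        return self.preferred_hues.size

    @property
    def spacing(self) -> float:
        return TWO_PI / self.n_units


@dataclass(frozen=True, eq=False)
class CategorySet:
    """Color categories: focal hues plus the concentration of p(s|c).

    The default layout is three categories with centers spaced equally
    around the hue circle.
    """

    centers: np.ndarray
    kappa_cat: float = DEFAULT_KAPPA_CAT

    def __post_init__(self):
        centers = wrap_angle(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise InvalidParameterError("need at least 2 categories")
        if self.kappa_cat <= 0:
            raise InvalidParameterError("kappa_cat must be positive")
        for i in range(centers.size):
            for j in range(i + 1, centers.size):
                if circ_dist(centers[i], centers[j]) < 1e-9:
                    raise InvalidParameterError("category centers must be distinct")

    @property
    def n(self) -> int:
        return self.centers.size

    @classmethod
    def equally_spaced(cls, n: int = 3, kappa_cat: float = DEFAULT_KAPPA_CAT,
                       offset: float = 0.0) -> "CategorySet":
        """n categories with focal hues at offset + 2*pi*k/n."""
        centers = wrap_angle(offset + TWO_PI * np.arange(n) / n)
        return cls(centers=np.sort(centers), kappa_cat=kappa_cat)

    def nearest(self, hue) -> np.ndarray:
        """Index of the category whose center is circularly nearest each hue."""
        hue = np.atleast_1d(np.asarray(hue, dtype=float))
        d = circ_dist(hue[:, None], self.centers[None, :])
        idx = np.argmin(d, axis=1)
        return idx if idx.size > 1 else idx[0]


@dataclass(frozen=True, eq=False)
class GenerativeConfig:
    """Hierarchical hidden Markov model for stimulus sequences.

    Category c_t stays put with probability 1 - switch_prob and otherwise
    jumps uniformly to one of the other categories; hue s_t ~ von Mises
    (center_{c_t}, kappa_cat); observation x_t = s_t + wrapped Gaussian
    noise with SD obs_noise_sd.
    """

    categories: CategorySet
    switch_prob: float = 0.02
    obs_noise_sd: float = DEFAULT_OBS_NOISE_SD
    horizon: int = 20

    def __post_init__(self):
        if not (0.0 <= self.switch_prob < 1.0):
            raise InvalidParameterError("switch_prob must be in [0, 1)")
        if self.obs_noise_sd < 0:
            raise InvalidParameterError("obs_noise_sd must be nonnegative")
        if self.horizon < 1:
            raise InvalidParameterError("horizon must be >= 1")

    def transition_matrix(self) -> np.ndarray:
        n = self.categories.n
        off = self.switch_prob / (n - 1)
        T = np.full((n, n), off)
        np.fill_diagonal(T, 1.0 - self.switch_prob)
        return T


@dataclass(frozen=True, eq=False)
class PopulationActivity:
    """Nonnegative activity vector aligned with a population's units."""

    rates: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if rates.ndim != 1 or rates.size == 0:
            raise InvalidInputError("rates must be a nonempty 1-D vector")
        if not np.all(np.isfinite(rates)):
            raise InvalidInputError("rates must be finite")
        if np.any(rates < 0):
            raise InvalidInputError("rates must be nonnegative")

    def __len__(self) -> int:
        return self.rates.size


def make_uniform_population(n_units: int = DEFAULT_N_UNITS,
                            kappa: float = DEFAULT_KAPPA,
                            gain: float = DEFAULT_GAIN) -> HuePopulation:
    """Population with preferred hues 2*pi*i/n_units, i = 0..n_units-1."""
    if n_units < 3:
        raise InvalidParameterError("n_units must be >= 3")
    hues = TWO_PI * np.arange(n_units) / n_units
    return HuePopulation(preferred_hues=hues, kappa=kappa, gain=gain)


def von_mises_tuning(stimulus_hue, preferred_hue, kappa: float, gain: float):
    """Tuning curve g * exp(kappa * (cos(s - theta) - 1)).

    Peak value is exactly ``gain``, attained iff the stimulus equals the
    preferred hue (mod 2*pi); 2*pi-periodic in both angle arguments.
    """
    if kappa <= 0 or gain <= 0:
        raise InvalidParameterError("kappa and gain must be positive")
    s = np.asarray(stimulus_hue, dtype=float)
    p = np.asarray(preferred_hue, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(p))):
        raise InvalidInputError("angles must be finite")
    return gain * np.exp(kappa * (np.cos(s - p) - 1.0))


def population_tuning(population: HuePopulation, stimulus_hue: float) -> PopulationActivity:
    """Noiseless response of every unit to a stimulus hue."""
    rates = von_mises_tuning(stimulus_hue, population.preferred_hues,
                             population.kappa, population.gain)
    return PopulationActivity(rates=rates)


def encode_stimulus(population: HuePopulation, stimulus_hue: float,
                    noise_sd: float, rng: np.random.Generator) -> PopulationActivity:
    """Response to a hue jittered by wrapped-Gaussian sensory noise.

    With ``noise_sd == 0`` this is exactly :func:`population_tuning`;
    otherwise the stimulus is perturbed once per call and the deterministic
    tuning is evaluated at the perturbed hue.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be nonnegative")
    hue = float(stimulus_hue)
    if noise_sd > 0:
        hue = wrap_angle(hue + rng.normal(0.0, noise_sd))
    return population_tuning(population, hue)


def generate_stimulus_sequence(config: GenerativeConfig, rng: np.random.Generator):
    """Sample (categories, hues, observations) of length ``config.horizon``.

    Returns
    -------
    categories : ndarray of int
    hues : ndarray of float, radians on [0, 2*pi)
    observations : ndarray of float, radians on [0, 2*pi)
    """
    n = config.categories.n
    horizon = config.horizon
    cats = np.empty(horizon, dtype=int)
    hues = np.empty(horizon, dtype=float)

    c = int(rng.integers(n))
    for t in range(horizon):
        if t > 0 and rng.random() < config.switch_prob:
            others = [k for k in range(n) if k != c]
            c = int(others[rng.integers(n - 1)])
        cats[t] = c
        hues[t] = wrap_angle(rng.vonmises(config.categories.centers[c],
                                          config.categories.kappa_cat))
    obs = hues.copy()
    if config.obs_noise_sd > 0:
        obs = wrap_angle(obs + rng.normal(0.0, config.obs_noise_sd, size=horizon))
    return cats, hues, obs
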