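"""Run configuration: defaults, YAML round-trip, seed fan-out."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import InvalidParameterError
from .network import DEFAULT_LAMBDA_CAT, DEFAULT_LAMBDA_HUE, NetworkParams
from .popcode import (DEFAULT_GAIN, DEFAULT_KAPPA, DEFAULT_KAPPA_CAT,
                      DEFAULT_N_UNITS, CategorySet, GenerativeConfig,
                      HuePopulation, make_uniform_population)


@dataclass
class RunConfig:
    """Flat, serializable bundle of every model parameter.

    Angles are degrees in the file/CLI representation and converted to
    radians when objects are built.
    """

    n_units: int = DEFAULT_N_UNITS
    kappa: float = DEFAULT_KAPPA
    gain: float = DEFAULT_GAIN
    n_categories: int = 3
    kappa_cat: float = DEFAULT_KAPPA_CAT
    category_offset_deg: float = 0.0
    lambda_hue: float = DEFAULT_LAMBDA_HUE
    lambda_cat: float = DEFAULT_LAMBDA_CAT
    topdown_kappa: Optional[float] = None
    rectify: bool = True
    switch_prob: float = 0.02
    obs_noise_sd_deg: float = 10.0
    horizon: int = 20
    seed: int = 0

    def population(self) -> HuePopulation:
        return make_uniform_population(self.n_units, self.kappa, self.gain)

    def categories(self) -> CategorySet:
        return CategorySet.equally_spaced(self.n_categories, self.kappa_cat,
                                          offset=np.deg2rad(self.category_offset_deg))

    def network_params(self, lambda_cat: Optional[float] = None) -> NetworkParams:
        return NetworkParams(lambda_hue=self.lambda_hue,
                             lambda_cat=self.lambda_cat if lambda_cat is None else lambda_cat,
                             topdown_kappa=self.topdown_kappa,
                             rectify=self.rectify)

    def generative(self) -> GenerativeConfig:
        return GenerativeConfig(categories=self.categories(),
                                switch_prob=self.switch_prob,
                                obs_noise_sd=np.deg2rad(self.obs_noise_sd_deg),
                                horizon=self.horizon)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream: independent per name, reproducible per seed.

    Fanning one user-facing seed out to named streams means adding a new
    experiment never perturbs another experiment's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
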