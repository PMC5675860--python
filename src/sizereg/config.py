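"""Model configuration for the size-regulation simulators.

A single flat :class:`ModelConfig` selects the regulation mechanism
(inhibitor *dilution* or initiator *accumulation*), how synthesis noise
enters the dilution model (*noisy_integrator* or *noisy_synthesis_rate*),
how growth noise enters budded growth (*noisy_asymmetry* or
*noisy_timing*), and the growth morphology (*budding* or *nonbudding*),
together with every mean parameter and noise strength.

Units are dimensionless by convention: the concentration scales ``c1``
(dilution threshold) and ``c2`` (initiator yield per volume) default to 1
and only set the scale of the size distribution; time is measured so that
the mean exponential growth rate ``mean_lambda = ln 2`` gives one volume
doubling per time unit (``t_db = 1``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

LN2 = math.log(2.0)

MECHANISMS = ("dilution", "accumulation")
SYNTHESIS_VARIANTS = ("noisy_integrator", "noisy_synthesis_rate")
GROWTH_VARIANTS = ("noisy_asymmetry", "noisy_timing")
MORPHOLOGIES = ("budding", "nonbudding")


class ConfigError(ValueError):
    """Raised for inconsistent or unphysical model configurations."""


@dataclass
class ModelConfig:
    """Complete parameterization of one simulation.

    Parameters
    ----------
    mechanism:
        ``"dilution"`` — commitment (Start / replication initiation) when
        an inhibitor synthesized post-commitment is diluted below the
        concentration ``c1``; ``"accumulation"`` — commitment when an
        initiator synthesized in proportion to growth reaches the absolute
        abundance threshold ``mean_Ac`` (initiator fully degraded at
        commitment).
    synthesis_variant:
        Dilution only. ``"noisy_integrator"``: the per-cycle inhibitor
        increment is drawn as N(mean_delta, sigma_delta), uncorrelated
        with growth. ``"noisy_synthesis_rate"``: the increment is K * t
        with K ~ N(mean_K, sigma_K) and t the realized post-commitment
        duration, coupling synthesis to timing noise.
    growth_variant:
        Budding only. ``"noisy_asymmetry"``: Vd = Vi (1 + x) with
        x ~ N(mean_x, sigma_x); ``"noisy_timing"``: Vd = Vi exp(lambda t)
        with lambda ~ N(mean_lambda, sigma_lambda), t ~ N(mean_t, sigma_t).
        Non-budding cells always grow as Vd = Vi exp(lambda t) with
        t = C + D.
    f:
        Non-budding division fraction; progeny receive f Vd and (1 - f) Vd.
    monotonic_constraint:
        Cells born already past the commitment criterion commit
        immediately at their birth volume, so volume never decreases
        ("immediate Start").
    seed:
        Root seed; all randomness derives from it via independent
        substreams.
    """

    mechanism: str = "dilution"
    synthesis_variant: str = "noisy_integrator"
    growth_variant: str = "noisy_asymmetry"
    morphology: str = "budding"
    c1: float = 1.0
    c2: float = 1.0
    mean_delta: float = 1.0
    sigma_delta: float = 0.0
    mean_K: float = 1.0
    sigma_K: float = 0.0
    sigma_s: float = 0.0
    mean_Ac: float = 1.0
    sigma_i: float = 0.0
    mean_x: float = 0.5
    sigma_x: float = 0.0
    mean_t: float = 0.7
    sigma_t: float = 0.0
    mean_lambda: float = LN2
    sigma_lambda: float = 0.0
    f: float = 0.5
    monotonic_constraint: bool = True
    seed: int = 0
    #: derived doubling time ln 2 / mean_lambda, filled by validation
    t_db: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        validate_config(self)

    # -- derived quantities -------------------------------------------------

    def mean_r(self) -> float:
        """Mean division asymmetry r = Vb(daughter)/Vb(mother).

        In the noisy-asymmetry model r = x exactly; in the noisy-timing
        model r = exp(lambda t) - 1 at the means.
        """
        if self.morphology == "budding" and self.growth_variant == "noisy_timing":
            return math.exp(self.mean_lambda * self.mean_t) - 1.0
        return self.mean_x

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("t_db")  # derived, not an input
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in fields(cls) if f.init}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load from a flat YAML or JSON key/value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **changes) -> "ModelConfig":
        """Return a revalidated copy with ``changes`` applied."""
        return dataclasses.replace(self, **changes)


_POSITIVE_MEANS = (
    "c1", "c2", "mean_delta", "mean_K", "mean_Ac", "mean_x", "mean_t",
    "mean_lambda",
)
_SIGMAS = (
    "sigma_delta", "sigma_K", "sigma_s", "sigma_i", "sigma_x", "sigma_t",
    "sigma_lambda",
)


def validate_config(config: ModelConfig) -> ModelConfig:
    """Validate and normalize a configuration in place.

    Fills the derived doubling time ``t_db`` and raises
    :class:`ConfigError` on negative means, negative noise strengths,
    ``f`` outside (0, 1), unknown selector values, or noise assigned to a
    variant in which it plays no role (e.g. ``sigma_delta`` under the
    noisy-synthesis-rate variant).
    """
    if config.mechanism not in MECHANISMS:
        raise ConfigError(f"mechanism must be one of {MECHANISMS}")
    if config.synthesis_variant not in SYNTHESIS_VARIANTS:
        raise ConfigError(f"synthesis_variant must be one of {SYNTHESIS_VARIANTS}")
    if config.growth_variant not in GROWTH_VARIANTS:
        raise ConfigError(f"growth_variant must be one of {GROWTH_VARIANTS}")
    if config.morphology not in MORPHOLOGIES:
        raise ConfigError(f"morphology must be one of {MORPHOLOGIES}")

    for name in _POSITIVE_MEANS:
        if getattr(config, name) <= 0:
            raise ConfigError(f"{name} must be strictly positive")
    for name in _SIGMAS:
        if getattr(config, name) < 0:
            raise ConfigError(f"{name} must be non-negative")
    if not (0.0 < config.f < 1.0):
        raise ConfigError("division fraction f must lie in (0, 1)")

    def _forbid(name: str, why: str) -> None:
        if getattr(config, name) != 0.0:
            raise ConfigError(f"{name} is inapplicable {why}")

    if config.mechanism == "dilution":
        _forbid("sigma_i", "to the dilution mechanism")
        if config.synthesis_variant == "noisy_integrator":
            _forbid("sigma_K", "under noisy_integrator synthesis")
        else:
            _forbid("sigma_delta", "under noisy_synthesis_rate synthesis")
    else:  # accumulation
        _forbid("sigma_delta", "to the accumulation mechanism")
        _forbid("sigma_K", "to the accumulation mechanism")
        _forbid("sigma_s", "to the accumulation mechanism")

    if config.morphology == "budding":
        if config.growth_variant == "noisy_asymmetry":
            _forbid("sigma_t", "under noisy_asymmetry growth")
            _forbid("sigma_lambda", "under noisy_asymmetry growth")
        else:
            _forbid("sigma_x", "under noisy_timing growth")
    else:  # nonbudding: growth is always exponential timing with t = C + D
        _forbid("sigma_x", "to non-budding growth")
        if config.mechanism == "accumulation":
            _forbid("sigma_lambda", "to the non-budding accumulation model")

    config.t_db = LN2 / config.mean_lambda
    return config
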