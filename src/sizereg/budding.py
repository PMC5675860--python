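"""Single-cycle update rules for budding (yeast-like) cells.

A budding cell of birth volume Vb grows in G1 to its commitment (Start)
volume Vi, then confines all further growth to a bud until division at
volume Vd. At division the main cell body keeps its Start volume
(mother, Vb' = Vi) and the bud separates as the daughter (Vb' = Vd - Vi);
the regulator present at division is partitioned between the two in
proportion to their volumes.

Commitment volume:

* dilution — the inhibitor inherited at birth must be diluted below the
  threshold concentration c1, so Vi = (Ib + eta)/c1 with additive
  threshold noise eta ~ N(0, sigma_s);
* accumulation — the initiator must reach the abundance threshold
  Ac ~ N(mean_Ac, sigma_i), so Vi = Vb + (Ac - Ab)/c2.

Cells born already past the criterion commit immediately at their birth
volume (volume never decreases) when the monotonic constraint is on.
"""

from __future__ import annotations

import math

import numpy as np  # noqa: F401  (Generator type in signatures)

from .config import ModelConfig
from .core import CellState, CycleRecord, sample_gaussian


def start_volume_dilution(
    cell: CellState, config: ModelConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Commitment volume under inhibitor dilution.

    Returns ``(Vi, eta)`` where the candidate volume is
    (Ib + eta)/c1. With the monotonic constraint the result is clamped
    to at least the birth volume (immediate Start); without it an
    unphysical non-positive candidate raises.
    """
    eta = sample_gaussian(0.0, config.sigma_s, rng)
    candidate = (cell.regulator + eta) / config.c1
    if config.monotonic_constraint:
        return max(candidate, cell.volume), eta
    if candidate <= 0.0:
        raise ValueError("unphysical non-positive Start volume with constraint off")
    return candidate, eta


def start_volume_accumulation(
    cell: CellState, config: ModelConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Commitment volume under initiator accumulation.

    Draws the threshold Ac ~ N(mean_Ac, sigma_i) (positive) and returns
    ``(Vi, Ac)`` with candidate Vi = Vb + (Ac - Ab)/c2: the growth
    needed to synthesize the missing initiator. A cell born with
    Ab >= Ac commits immediately at its birth volume.
    """
    Ac = sample_gaussian(config.mean_Ac, config.sigma_i, rng, positive=True)
    candidate = cell.volume + (Ac - cell.regulator) / config.c2
    if config.monotonic_constraint:
        return max(candidate, cell.volume), Ac
    if candidate <= 0.0:
        raise ValueError("unphysical non-positive Start volume with constraint off")
    return candidate, Ac


def budded_growth(
    Vi: float, config: ModelConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Grow from commitment to division.

    Returns ``(Vd, t_budded, growth_rate)``.

    noisy_timing: draws lambda and t independently (positive) and sets
    Vd = Vi exp(lambda t). noisy_asymmetry: draws x (positive), sets
    Vd = Vi (1 + x), and imputes t_budded = ln(1 + x)/mean_lambda — the
    duration consistent with exponential growth at the mean rate, used
    only for population time-tracking. Either way Vd > Vi.
    """
    if config.growth_variant == "noisy_timing":
        lam = sample_gaussian(config.mean_lambda, config.sigma_lambda, rng, positive=True)
        t = sample_gaussian(config.mean_t, config.sigma_t, rng, positive=True)
        return Vi * math.exp(lam * t), t, lam
    x = sample_gaussian(config.mean_x, config.sigma_x, rng, positive=True)
    return Vi * (1.0 + x), math.log1p(x) / config.mean_lambda, config.mean_lambda


def divide_budding(
    Vi: float,
    Vd: float,
    regulator_at_division: float,
    *,
    birth_time: float = 0.0,
    lineage_id: int = 0,
) -> tuple[CellState, CellState]:
    """Split a divided cell into mother (Vi) and daughter (Vd - Vi).

    The regulator is distributed by volumetric fraction, so volume and
    regulator are conserved exactly.
    """
    if not Vd > Vi or not Vi > 0:
        raise ValueError("division requires Vd > Vi > 0")
    if regulator_at_division < 0:
        raise ValueError("regulator must be non-negative")
    bud = Vd - Vi
    mother = CellState(
        volume=Vi,
        regulator=regulator_at_division * (Vi / Vd),
        label="M",
        birth_time=birth_time,
        lineage_id=lineage_id,
    )
    daughter = CellState(
        volume=bud,
        regulator=regulator_at_division * (bud / Vd),
        label="D",
        birth_time=birth_time,
        lineage_id=lineage_id,
    )
    return mother, daughter


def run_cycle_budding(
    cell: CellState,
    config: ModelConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[CellState, CellState, CycleRecord]:
    """Advance one cell through a full budding cycle.

    Dilution: Vi from :func:`start_volume_dilution`, budded growth, then
    Id = Ib + delta where delta ~ N(mean_delta, sigma_delta)
    (noisy_integrator) or delta = K t_budded with K ~ N(mean_K, sigma_K)
    (noisy_synthesis_rate; the same realized t_budded couples synthesis
    to timing noise). Accumulation: Vi from
    :func:`start_volume_accumulation` (initiator degraded at
    commitment), then Ad = c2 (Vd - Vi).

    Returns ``(mother, daughter, record)``; G1 duration is
    ln(Vi/Vb)/growth_rate, zero for immediate-Start cells.
    """
    if config.mechanism == "dilution":
        Vi, _ = start_volume_dilution(cell, config, rng)
        Vd, t_budded, lam = budded_growth(Vi, config, rng)
        if config.synthesis_variant == "noisy_integrator":
            delta = sample_gaussian(config.mean_delta, config.sigma_delta, rng, positive=True)
        else:
            K = sample_gaussian(config.mean_K, config.sigma_K, rng, positive=True)
            delta = K * t_budded
        Rd = cell.regulator + delta
    else:
        Vi, _ = start_volume_accumulation(cell, config, rng)
        Vd, t_budded, lam = budded_growth(Vi, config, rng)
        Rd = config.c2 * (Vd - Vi)

    t_G1 = 0.0 if Vi == cell.volume else math.log(Vi / cell.volume) / lam
    division_time = cell.birth_time + t_G1 + t_budded
    mother, daughter = divide_budding(
        Vi, Vd, Rd, birth_time=division_time, lineage_id=cell.lineage_id
    )
    record = CycleRecord(
        Vb=cell.volume,
        Vi=Vi,
        Vd=Vd,
        Rb=cell.regulator,
        Rd=Rd,
        r_realized=(Vd - Vi) / Vi,
        t_G1=t_G1,
        t_budded=t_budded,
        label=cell.label,
        generation=generation,
        birth_time=cell.birth_time,
    )
    return mother, daughter, record
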