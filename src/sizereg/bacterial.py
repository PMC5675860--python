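"""Single-cycle updates for non-budding, symmetrically dividing cells.

Non-budding (bacterial) cells grow fully before setting the division
plane: a newborn grows to its replication-initiation volume Vi, waits
the C + D period t, divides at Vd = Vi exp(lambda t), and the two
progeny receive fractions f and 1 - f of Vd. We consider the
slow-growth regime (C + D < t_db) with at most one initiation per
cycle, excluding overlapping replication rounds.

Two mechanisms:

* dilution — initiation when the inherited inhibitor concentration
  falls below c1 (alternation of initiation and division enforced:
  cells born below threshold initiate immediately at birth);
* accumulation — the initiation-to-initiation recursion
  2 Vi' = Vi + (Ac + xi_i)/c2 under perfectly symmetric division, with
  per-cycle birth volume Vb = Vi exp(lambda (mean_t + xi_t))/2 and
  division volume Vd = 2 Vb(next cycle). The noise terms xi_i, xi_t are
  unbounded Gaussians, matching the assumptions under which the
  closed-form birth-division slope (see
  :func:`sizereg.analytics.analytic_slope_accumulation`) is derived; a
  monotonic clamp exists but defaults off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import ModelConfig
from .core import CellState, CycleRecord, RECORD_COLUMNS, sample_gaussian


def run_cycle_bacterial_dilution(
    cell: CellState,
    config: ModelConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[CellState, CellState, CycleRecord]:
    """One cycle of the non-budding inhibitor-dilution model.

    Vi = max(Vb, (Ib + eta)/c1); t = C + D and lambda drawn positive;
    Vd = Vi exp(lambda t). Inhibitor at division is Ib + delta with
    delta ~ N(mean_delta, sigma_delta) (noisy integrator) or K t
    (noisy synthesis rate). Progeny get volumes f Vd and (1 - f) Vd and
    the same fractions of the inhibitor.
    """
    eta = sample_gaussian(0.0, config.sigma_s, rng)
    Vi = max(cell.volume, (cell.regulator + eta) / config.c1)
    t = sample_gaussian(config.mean_t, config.sigma_t, rng, positive=True)
    lam = sample_gaussian(config.mean_lambda, config.sigma_lambda, rng, positive=True)
    Vd = Vi * math.exp(lam * t)
    if config.synthesis_variant == "noisy_integrator":
        delta = sample_gaussian(config.mean_delta, config.sigma_delta, rng, positive=True)
    else:
        K = sample_gaussian(config.mean_K, config.sigma_K, rng, positive=True)
        delta = K * t
    Id = cell.regulator + delta

    t_G1 = 0.0 if Vi == cell.volume else math.log(Vi / cell.volume) / lam
    division_time = cell.birth_time + t_G1 + t
    d1 = CellState(
        volume=config.f * Vd,
        regulator=config.f * Id,
        label="D",
        birth_time=division_time,
        lineage_id=cell.lineage_id,
    )
    d2 = CellState(
        volume=(1.0 - config.f) * Vd,
        regulator=(1.0 - config.f) * Id,
        label="D",
        birth_time=division_time,
        lineage_id=cell.lineage_id,
    )
    record = CycleRecord(
        Vb=cell.volume,
        Vi=Vi,
        Vd=Vd,
        Rb=cell.regulator,
        Rd=Id,
        r_realized=float("nan"),
        t_G1=t_G1,
        t_budded=t,
        label="D",
        generation=generation,
        birth_time=cell.birth_time,
    )
    return d1, d2, record


@dataclass
class InitiationState:
    """State of the accumulation initiation chain: the volume at the most
    recent replication initiation and the birth volume of the cycle in
    which the next initiation will occur."""

    Vi: float
    Vb: float
    birth_time: float = 0.0
    generation: int = 0


def init_bacterial_accumulation(
    config: ModelConfig, rng: np.random.Generator
) -> InitiationState:
    """Start the chain at the noiseless fixed point Vi* = mean_Ac/c2."""
    Vi0 = config.mean_Ac / config.c2
    xi_t = sample_gaussian(0.0, config.sigma_t, rng)
    Vb0 = Vi0 * math.exp(config.mean_lambda * (config.mean_t + xi_t)) / 2.0
    return InitiationState(Vi=Vi0, Vb=Vb0)


def run_cycle_bacterial_accumulation(
    state: InitiationState,
    config: ModelConfig,
    rng: np.random.Generator,
    clamp: bool = False,
) -> tuple[InitiationState, CycleRecord]:
    """Advance the initiation-to-initiation recursion by one cycle.

    Draws xi_i and the next cycle's timing noise xi_t, computes
    Vi' = (Vi + (mean_Ac + xi_i)/c2)/2, the next birth volume
    Vb' = Vi' exp(lambda (mean_t + xi_t))/2, and emits the completed
    cycle's record with Vd = 2 Vb'. At most one initiation occurs per
    cycle. ``clamp=True`` additionally enforces Vi' >= Vb (volume
    monotonicity); the default follows the bare recursion.
    """
    lam = config.mean_lambda
    Ac = sample_gaussian(config.mean_Ac, config.sigma_i, rng)
    Vi_next = (state.Vi + Ac / config.c2) / 2.0
    if clamp:
        Vi_next = max(Vi_next, state.Vb)
    xi_t = sample_gaussian(0.0, config.sigma_t, rng)
    t_next = config.mean_t + xi_t
    Vb_next = Vi_next * math.exp(lam * t_next) / 2.0
    Vd = 2.0 * Vb_next

    record = CycleRecord(
        Vb=state.Vb,
        Vi=Vi_next,
        Vd=Vd,
        Rb=float("nan"),
        Rd=Ac,
        r_realized=float("nan"),
        t_G1=math.log(Vi_next / state.Vb) / lam,
        t_budded=t_next,
        label="D",
        generation=state.generation,
        birth_time=state.birth_time,
    )
    cycle_time = record.t_G1 + t_next
    next_state = InitiationState(
        Vi=Vi_next,
        Vb=Vb_next,
        birth_time=state.birth_time + cycle_time,
        generation=state.generation + 1,
    )
    return next_state, record


def simulate_bacterial_accumulation(
    config: ModelConfig,
    n_cycles: int,
    burn_in: int = 50,
    rng: np.random.Generator | None = None,
    clamp: bool = False,
) -> pd.DataFrame:
    """Vectorized driver for the accumulation chain.

    The unclamped recursion Vi[n+1] = Vi[n]/2 + (mean_Ac + xi_i[n])/(2 c2)
    is a linear AR(1) process and is run through ``scipy.signal.lfilter``;
    the clamped variant falls back to the per-cycle operation. Returns
    ``n_cycles`` post-burn-in records as a DataFrame.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_total = burn_in + n_cycles
    if clamp:
        state = init_bacterial_accumulation(config, rng)
        rows = []
        for gen in range(n_total):
            state, rec = run_cycle_bacterial_accumulation(state, config, rng, clamp=True)
            if gen >= burn_in:
                rows.append([getattr(rec, c) for c in RECORD_COLUMNS])
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    lam = config.mean_lambda
    Vi0 = config.mean_Ac / config.c2
    if config.sigma_i > 0:
        xi_i = rng.normal(0.0, config.sigma_i, n_total)
    else:
        xi_i = np.zeros(n_total)
    if config.sigma_t > 0:
        xi_t = rng.normal(0.0, config.sigma_t, n_total + 1)
    else:
        xi_t = np.zeros(n_total + 1)

    drive = (config.mean_Ac + xi_i) / (2.0 * config.c2)
    Vi_tail, _ = lfilter([1.0], [1.0, -0.5], drive, zi=[0.5 * Vi0])
    Vi = np.concatenate(([Vi0], Vi_tail))  # Vi[n], n = 0..n_total

    t_cd = config.mean_t + xi_t
    Vb = Vi * np.exp(lam * t_cd) / 2.0  # Vb[n], n = 0..n_total
    Vd = 2.0 * Vb[1:]                   # Vd[n] = 2 Vb[n+1]

    sl = slice(burn_in, n_total)
    out = pd.DataFrame(
        {
            "Vb": Vb[sl],
            "Vi": Vi[burn_in + 1 : n_total + 1],
            "Vd": Vd[sl],
            "Rb": np.nan,
            "Rd": config.mean_Ac + xi_i[sl],
            "r_realized": np.nan,
            "t_G1": np.log(Vi[burn_in + 1 : n_total + 1] / Vb[sl]) / lam,
            "t_budded": t_cd[burn_in + 1 : n_total + 1],
            "label": "D",
            "generation": np.arange(burn_in, n_total),
            "birth_time": np.nan,
        }
    )
    return out[RECORD_COLUMNS]


def simulate_bacterial_dilution(
    config: ModelConfig,
    n_cycles: int,
    burn_in: int = 50,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-progeny chain of the non-budding dilution model.

    Follows one progeny after each division (the two are exchangeable
    for f = 0.5; otherwise one is chosen uniformly at random) and
    returns ``n_cycles`` post-burn-in records.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cell = CellState(
        volume=config.mean_delta / config.c1,
        regulator=config.mean_delta,
        label="D",
    )
    rows = []
    for gen in range(burn_in + n_cycles):
        d1, d2, rec = run_cycle_bacterial_dilution(cell, config, rng, generation=gen)
        if gen >= burn_in:
            rows.append([getattr(rec, c) for c in RECORD_COLUMNS])
        cell = d1 if rng.random() < 0.5 else d2
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
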