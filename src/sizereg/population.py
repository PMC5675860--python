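"""Lineage and population drivers, growth-dilution passaging, statistics.

Two sampling schemes are provided:

* :func:`simulate_records` — lineage chains that emit one
  :class:`~sizereg.core.CycleRecord` per completed cycle, used for
  birth-vs-division regressions. For budding cells the default follows
  a *random-descent* lineage: after each division the chain continues
  with the mother or the daughter with equal probability. Because every
  division produces exactly one continuing mother and one daughter, this
  chain samples the stationary distribution of the full branching
  population (each generation-n individual carries weight 2^-n), so
  time-averages along the chain equal population averages — the
  weighting under which the stationary identities <Ib> = <delta> and the
  mean-G1-growth formula hold. ``descent="mother"`` instead follows the
  mother indefinitely and records each new daughter's own first cycle as
  a side branch.

* :func:`passage_simulation` — an asynchronous whole-population
  simulation with repeated growth-dilution passaging: every cell's cycle
  duration is t_G1 + t_budded at its own drawn rates, both progeny are
  kept, and whenever the population exceeds ``n_max`` it is reseeded
  with ``n_keep`` cells drawn uniformly at random. Snapshots of the
  extant population's birth volumes are taken on a fixed grid of times
  (in doubling-time units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .bacterial import (
    run_cycle_bacterial_dilution,
    simulate_bacterial_accumulation,
    simulate_bacterial_dilution,
)
from .budding import run_cycle_budding
from .config import ModelConfig
from .core import CellState, RECORD_COLUMNS, sample_gaussian_array, spawn_rngs


@dataclass
class PopulationSnapshot:
    """Time-stamped statistics of the extant population's birth volumes."""

    time: float
    n_cells: int
    mean_Vb: float
    sd_Vb: float
    cv_Vb: float
    sd_logVb: float


SNAPSHOT_COLUMNS = [f.name for f in fields(PopulationSnapshot)]

#: guard against runaway record tables (~GBs); passaging mode keeps the
#: population bounded instead
_MAX_RECORDS = 50_000_000


def initial_cell(config: ModelConfig) -> CellState:
    """A daughter cell near the noiseless stationary state.

    Dilution: a daughter of a fixed-point mother has Vb = r Vi* and
    Ib = mean_delta. Accumulation: Vb = r Vi* and
    Ab = c2 r^2 Vi*/(1 + r). Burn-in removes any residual transient.
    """
    r = config.mean_r()
    if config.mechanism == "dilution":
        Vi_star = config.mean_delta / (r * config.c1)
        return CellState(volume=r * Vi_star, regulator=config.mean_delta)
    Vi_star = config.mean_Ac * (1.0 + r) / (r * config.c2)
    Ab = config.c2 * r * r * Vi_star / (1.0 + r)
    return CellState(volume=r * Vi_star, regulator=Ab)


def simulate_records(
    config: ModelConfig,
    n_lineages: int = 1,
    n_generations: int = 1000,
    burn_in: int = 50,
    seed=None,
    descent: str = "random",
) -> pd.DataFrame:
    """Simulate lineage chains and return post-burn-in cycle records.

    Deterministic given ``seed`` (defaults to ``config.seed``): each
    lineage runs on its own spawned substream. Budding lineages follow
    the descent rule described in the module docstring; non-budding
    lineages are independent single-progeny chains.
    """
    if n_generations <= burn_in:
        raise ValueError("n_generations must exceed burn_in")
    if descent not in ("random", "mother"):
        raise ValueError("descent must be 'random' or 'mother'")
    n_records = n_lineages * (n_generations - burn_in)
    if n_records > _MAX_RECORDS:
        raise MemoryError(
            f"{n_records} records requested; use passage_simulation for "
            "long population runs"
        )
    seed = config.seed if seed is None else seed
    rngs = spawn_rngs(seed, n_lineages)

    if config.morphology == "nonbudding":
        n_cycles = n_generations - burn_in
        if config.mechanism == "accumulation":
            frames = [
                simulate_bacterial_accumulation(config, n_cycles, burn_in, rng)
                for rng in rngs
            ]
        else:
            frames = [
                simulate_bacterial_dilution(config, n_cycles, burn_in, rng)
                for rng in rngs
            ]
        for lineage_id, frame in enumerate(frames):
            frame["lineage_id"] = lineage_id
        return pd.concat(frames, ignore_index=True)

    rows: list[list] = []
    for lineage_id, rng in enumerate(rngs):
        cell = initial_cell(config)
        cell.lineage_id = lineage_id
        for gen in range(n_generations):
            mother, daughter, rec = run_cycle_budding(cell, config, rng, generation=gen)
            if gen >= burn_in:
                rows.append([getattr(rec, c) for c in RECORD_COLUMNS] + [lineage_id])
            if descent == "random":
                cell = mother if rng.random() < 0.5 else daughter
            else:
                # daughter's own first cycle as a side branch, progeny discarded
                _, _, drec = run_cycle_budding(
                    daughter, config, rng, generation=gen + 1
                )
                if gen >= burn_in:
                    rows.append(
                        [getattr(drec, c) for c in RECORD_COLUMNS] + [lineage_id]
                    )
                cell = mother
    return pd.DataFrame(rows, columns=RECORD_COLUMNS + ["lineage_id"])


# ---------------------------------------------------------------------------
# growth-dilution passaging
# ---------------------------------------------------------------------------


def _cycle_vec(Vb, Rb, config: ModelConfig, rng, pure_timer: bool):
    """Vectorized full-cycle computation for arrays of newborn cells.

    Returns ``(Vi, Vd, Rd, duration)``; semantics match the scalar
    single-cycle operations in :mod:`sizereg.budding`.
    """
    n = Vb.size
    lam = config.mean_lambda
    if pure_timer:
        # size control disabled: Vd = 2 Vb e^eps, eps ~ N(0, sigma_x)
        eps = rng.normal(0.0, config.sigma_x, n) if config.sigma_x > 0 else np.zeros(n)
        Vd = 2.0 * Vb * np.exp(eps)
        duration = (math.log(2.0) + eps) / lam
        return Vb.copy(), Vd, np.zeros(n), duration

    if config.mechanism == "dilution":
        eta = rng.normal(0.0, config.sigma_s, n) if config.sigma_s > 0 else 0.0
        candidate = (Rb + eta) / config.c1
        Vi = np.maximum(Vb, candidate) if config.monotonic_constraint else candidate
        if not config.monotonic_constraint and np.any(Vi <= 0):
            raise ValueError("unphysical non-positive Start volume with constraint off")
    else:
        Ac = sample_gaussian_array(config.mean_Ac, config.sigma_i, n, rng, positive=True)
        candidate = Vb + (Ac - Rb) / config.c2
        Vi = np.maximum(Vb, candidate) if config.monotonic_constraint else candidate

    if config.growth_variant == "noisy_timing":
        lam_arr = sample_gaussian_array(
            config.mean_lambda, config.sigma_lambda, n, rng, positive=True
        )
        t_budded = sample_gaussian_array(config.mean_t, config.sigma_t, n, rng, positive=True)
        Vd = Vi * np.exp(lam_arr * t_budded)
        t_G1 = np.log(Vi / Vb) / lam_arr
    else:
        x = sample_gaussian_array(config.mean_x, config.sigma_x, n, rng, positive=True)
        Vd = Vi * (1.0 + x)
        t_budded = np.log1p(x) / lam
        t_G1 = np.log(Vi / Vb) / lam

    if config.mechanism == "dilution":
        if config.synthesis_variant == "noisy_integrator":
            delta = sample_gaussian_array(
                config.mean_delta, config.sigma_delta, n, rng, positive=True
            )
        else:
            K = sample_gaussian_array(config.mean_K, config.sigma_K, n, rng, positive=True)
            delta = K * t_budded
        Rd = Rb + delta
    else:
        Rd = config.c2 * (Vd - Vi)

    return Vi, Vd, Rd, t_G1 + t_budded


def _passage_one(
    config: ModelConfig,
    total_time: float,
    n_max: int,
    n_keep: int,
    snapshot_every: float,
    rng: np.random.Generator,
    pure_timer: bool,
) -> pd.DataFrame:
    t_db = config.t_db
    if pure_timer:
        Vb0, R0 = 1.0, 0.0
    else:
        seed_cell = initial_cell(config)
        Vb0, R0 = seed_cell.volume, seed_cell.regulator

    Vb = np.full(n_keep, Vb0)
    Rb = np.full(n_keep, R0)
    Vi, Vd, Rd, dur = _cycle_vec(Vb, Rb, config, rng, pure_timer)
    tdiv = dur.copy()  # all cells born at t = 0

    snapshots: list[list] = []
    n_steps = int(round(total_time))  # internal sub-slices of one t_db
    snap_stride = max(1, int(round(snapshot_every)))
    for step in range(1, n_steps + 1):
        t_end = step * t_db
        while True:
            div = tdiv < t_end
            if not div.any():
                break
            Vi_p, Vd_p, Rd_p, td_p = Vi[div], Vd[div], Rd[div], tdiv[div]
            if pure_timer:
                child_Vb = np.concatenate([Vd_p / 2.0, Vd_p / 2.0])
                child_Rb = np.zeros(child_Vb.size)
            else:
                bud = Vd_p - Vi_p
                child_Vb = np.concatenate([Vi_p, bud])
                child_Rb = np.concatenate([Rd_p * Vi_p / Vd_p, Rd_p * bud / Vd_p])
            child_tb = np.concatenate([td_p, td_p])
            c_Vi, c_Vd, c_Rd, c_dur = _cycle_vec(child_Vb, child_Rb, config, rng, pure_timer)

            keep = ~div
            Vb = np.concatenate([Vb[keep], child_Vb])
            Rb = np.concatenate([Rb[keep], child_Rb])
            Vi = np.concatenate([Vi[keep], c_Vi])
            Vd = np.concatenate([Vd[keep], c_Vd])
            Rd = np.concatenate([Rd[keep], c_Rd])
            tdiv = np.concatenate([tdiv[keep], child_tb + c_dur])

            if Vb.size > n_max:
                idx = rng.choice(Vb.size, n_keep, replace=False)
                Vb, Rb, Vi, Vd, Rd, tdiv = (
                    a[idx] for a in (Vb, Rb, Vi, Vd, Rd, tdiv)
                )
        if step % snap_stride == 0:
            n = Vb.size
            mean = float(Vb.mean())
            sd = float(Vb.std(ddof=1)) if n >= 2 else 0.0
            snapshots.append(
                [
                    step * 1.0,  # time in doubling-time units
                    n,
                    mean,
                    sd,
                    sd / mean,
                    float(np.log(Vb).std(ddof=1)) if n >= 2 else 0.0,
                ]
            )
    return pd.DataFrame(snapshots, columns=SNAPSHOT_COLUMNS)


def passage_simulation(
    config: ModelConfig,
    total_time: float,
    n_max: int = 2000,
    n_keep: int = 200,
    snapshot_every: float = 10.0,
    n_replicates: int = 5,
    seed=None,
    pure_timer: bool = False,
) -> pd.DataFrame:
    """Replicated growth-dilution passaging runs.

    ``total_time`` and ``snapshot_every`` are in doubling-time units
    (internally quantized to whole doublings). Each replicate starts
    from ``n_keep`` identical cells at the noiseless stationary state
    and runs on its own seeded substream; the returned snapshot table
    carries a ``replicate`` column. ``pure_timer=True`` replaces the
    regulator circuit with Vd = 2 Vb e^eps (eps ~ N(0, sigma_x)), the
    geometric-random-walk control.
    """
    if n_keep >= n_max:
        raise ValueError("n_keep must be smaller than n_max")
    seed = config.seed if seed is None else seed
    frames = []
    for rep, rng in enumerate(spawn_rngs(seed, n_replicates)):
        frame = _passage_one(
            config, total_time, n_max, n_keep, snapshot_every, rng, pure_timer
        )
        frame["replicate"] = rep
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def loglog_sigma_slope(snapshots: pd.DataFrame, window: tuple[float, float]) -> float:
    """OLS slope of log(sd_logVb) on log(time) over a time window.

    A geometric random walk in volume gives 0.5; weak size control gives
    a smaller exponent. Snapshots with ``sd_logVb == 0`` (monodisperse)
    are excluded; fewer than 3 usable snapshots raise. If the table
    carries several replicates the slope is fitted per replicate and
    averaged.
    """
    t0, t1 = window
    def _one(df: pd.DataFrame) -> float:
        sel = df[(df["time"] > t0) & (df["time"] <= t1) & (df["sd_logVb"] > 0)]
        if len(sel) < 3:
            raise ValueError("need at least 3 snapshots with sd_logVb > 0 in window")
        fit = stats.linregress(np.log(sel["time"]), np.log(sel["sd_logVb"]))
        return float(fit.slope)

    if "replicate" in snapshots.columns and snapshots["replicate"].nunique() > 1:
        return float(
            np.mean([_one(g) for _, g in snapshots.groupby("replicate")])
        )
    return _one(snapshots)
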