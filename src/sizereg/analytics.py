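"""Regression, adder classification, closed-form results, parameter sweeps.

The central observable throughout is the ordinary-least-squares slope of
division volume on birth volume,

    S(Vb, Vd) = Cov(Vb, Vd) / Var(Vb),

whose value classifies the size-control phenotype: 0 for a critical-size
threshold (sizer), 1 for an adder (volume added per cycle independent of
birth volume), 2 for a timer with exponential growth and symmetric
division.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .population import simulate_records


@dataclass
class SlopeResult:
    """OLS fit of Vd on Vb."""

    slope: float
    intercept: float
    n: int
    stderr: float


def ols_slope(pairs, Vd=None) -> SlopeResult:
    """OLS slope of division volume on birth volume.

    ``pairs`` may be a DataFrame with columns ``Vb`` and ``Vd``, or the
    two arrays may be passed separately. Requires n >= 3 and non-zero
    birth-volume variance (a noiseless fixed-point table is degenerate).
    """
    if Vd is None:
        Vb = np.asarray(pairs["Vb"], dtype=float)
        Vd = np.asarray(pairs["Vd"], dtype=float)
    else:
        Vb = np.asarray(pairs, dtype=float)
        Vd = np.asarray(Vd, dtype=float)
    if Vb.size < 3:
        raise ValueError("need at least 3 (Vb, Vd) pairs")
    if np.var(Vb) == 0:
        raise ValueError("zero birth-volume variance: regression is degenerate")
    fit = stats.linregress(Vb, Vd)
    return SlopeResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(Vb.size),
        stderr=float(fit.stderr),
    )


#: half-width of the adder classification band around slope 1
ADDER_TOLERANCE = 0.1


def classify_adder(slope: float) -> bool:
    """Adder iff 0.9 <= slope <= 1.1 (boundaries inclusive).

    A small epsilon keeps the boundaries inclusive under floating-point
    representation (1.1 - 1.0 > 0.1 in binary).
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    return abs(slope - 1.0) <= ADDER_TOLERANCE + 1e-9


def analytic_slope_accumulation(
    growth_rate: float, sigma_t: float, sigma_i: float, mean_Ac: float
) -> float:
    """Closed-form birth-division slope of the bacterial accumulation model.

    With a = exp(growth_rate^2 sigma_t^2 / 2) and b = sigma_i / mean_Ac,

        S(Vb, Vd) = 1 / (a^2 + 3 (a^2 - 1) / b^2),

    valid under perfectly symmetric division with at most one initiation
    per cycle. For sigma_t = 0 the slope is exactly 1 for any b > 0; for
    b = 0 with sigma_t > 0 the S -> 0 limit is returned with a warning.
    """
    if mean_Ac <= 0:
        raise ValueError("mean_Ac must be positive")
    a2 = math.exp((growth_rate * sigma_t) ** 2)
    b = sigma_i / mean_Ac
    if b == 0.0:
        if sigma_t == 0.0:
            return 1.0
        warnings.warn(
            "sigma_i = 0 with sigma_t > 0: slope limit is 0", stacklevel=2
        )
        return 0.0
    return 1.0 / (a2 + 3.0 * (a2 - 1.0) / (b * b))


def approx_slope_accumulation(
    growth_rate: float, sigma_t: float, sigma_i: float, mean_Ac: float
) -> float:
    """Lowest-order small-noise approximation 1/(1 + 3 lambda^2 sigma_t^2 / b^2)."""
    b = sigma_i / mean_Ac
    if b == 0.0:
        return 1.0 if sigma_t == 0.0 else 0.0
    return 1.0 / (1.0 + 3.0 * (growth_rate * sigma_t) ** 2 / (b * b))


def dilution_fixed_point(
    mean_delta: float, r: float, c1: float
) -> tuple[float, float]:
    """Noiseless mother-lineage fixed point of the budding dilution model.

    The mother recursion Vi' = (Vi + mean_delta/c1)/(1 + r) converges to
    Vi* = mean_delta/(r c1) with inhibitor Ib* = c1 Vi*: mothers saturate
    with no G1 growth, producing progeny born exactly at threshold.
    """
    if min(mean_delta, r, c1) <= 0:
        raise ValueError("all inputs must be positive")
    Vi_star = mean_delta / (r * c1)
    return Vi_star, c1 * Vi_star


@dataclass
class AccumulationFixedPoint:
    """Both closed forms of the noiseless accumulation mother fixed point.

    ``value`` is the fixed point of the recursion obtained by composing
    the accumulation threshold rule with volumetric regulator
    partitioning, Vi' = mean_Ac/c2 + Vi/(1 + r), namely
    mean_Ac (1 + r)/(r c2). ``alternate`` is a closed form circulating
    in the literature with recursion coefficient r/(1 + r) and fixed
    point mean_Ac (1 + r)/c2. The two coincide exactly at r = 1 (the
    symmetric case, where both give 2 mean_Ac/c2) and disagree
    otherwise; ``agree`` flags coincidence. Which form is intended for
    r != 1 is left open; downstream code uses ``value``.
    """

    value: float
    alternate: float
    agree: bool


def accumulation_fixed_point(
    mean_Ac: float, r: float, c2: float
) -> AccumulationFixedPoint:
    """Noiseless mother-lineage fixed point of the budding accumulation model."""
    if min(mean_Ac, r, c2) <= 0:
        raise ValueError("all inputs must be positive")
    first_principles = mean_Ac * (1.0 + r) / (r * c2)
    alternate = mean_Ac * (1.0 + r) / c2
    return AccumulationFixedPoint(
        value=first_principles,
        alternate=alternate,
        agree=math.isclose(first_principles, alternate, rel_tol=1e-12),
    )


def mean_g1_growth_dilution(mean_delta: float, r: float, c1: float) -> float:
    """Stationary mean total G1 growth of a mother-daughter pair,
    mean_delta (1 - r)/c1; exactly zero for symmetric division (r = 1)."""
    if min(mean_delta, r, c1) <= 0:
        raise ValueError("all inputs must be positive")
    return mean_delta * (1.0 - r) / c1


def sweep_heatmap(
    base_config: ModelConfig,
    axis1: tuple[str, list],
    axis2: tuple[str, list],
    label_filter: str = "D",
    n_records: int = 10_000,
    seed=None,
    n_lineages: int = 20,
    burn_in: int = 50,
    descent: str = "random",
) -> pd.DataFrame:
    """Grid of birth-division regression slopes over two config axes.

    For each grid cell the base configuration is copied with the two
    axis parameters overridden, ``n_records`` post-burn-in records with
    the requested label ("D", "M" or "all") are simulated on a
    deterministic per-cell substream of ``seed``, and the OLS slope is
    fitted. Degenerate cells (zero birth-volume variance) are reported
    with NaN slope rather than raising. Columns: the two parameter
    names, slope, stderr, n, adder.
    """
    name1, values1 = axis1
    name2, values2 = axis2
    if label_filter not in ("D", "M", "all"):
        raise ValueError("label_filter must be 'D', 'M' or 'all'")
    seed = base_config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    cells = [(v1, v2) for v1 in values1 for v2 in values2]
    cell_seeds = ss.spawn(len(cells))

    # label "D"/"M" keeps ~half the records of a random-descent chain
    frac = 1.0 if label_filter == "all" or base_config.morphology == "nonbudding" else 0.5
    gens = burn_in + int(np.ceil(1.1 * n_records / (n_lineages * frac))) + 1

    rows = []
    for (v1, v2), cell_seed in zip(cells, cell_seeds):
        config = base_config.replace(**{name1: v1, name2: v2})
        table = simulate_records(
            config,
            n_lineages=n_lineages,
            n_generations=gens,
            burn_in=burn_in,
            seed=cell_seed,
            descent=descent,
        )
        if label_filter != "all" and base_config.morphology == "budding":
            table = table[table["label"] == label_filter]
        table = table.head(n_records)
        try:
            fit = ols_slope(table)
            rows.append(
                [v1, v2, fit.slope, fit.stderr, fit.n, classify_adder(fit.slope)]
            )
        except ValueError:
            rows.append([v1, v2, np.nan, np.nan, len(table), False])
    return pd.DataFrame(
        rows, columns=[name1, name2, "slope", "stderr", "n", "adder"]
    )
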