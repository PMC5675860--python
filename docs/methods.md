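# Methods

## Models

`sizereg` simulates two abstracted molecular circuits for cell-size
control and asks what birth-vs-division volume correlations they
produce under two growth morphologies.

**Inhibitor dilution.** A regulator `I` inhibits commitment to division
(Start in budding yeast, initiation of DNA replication in bacteria). It
is synthesized only in the post-commitment part of the cycle, and the
next cycle's commitment occurs when growth has diluted its
concentration below a threshold `c1`:

    Vi = (Ib + eta) / c1,        eta ~ N(0, sigma_s)
    Id = Ib + delta

with two synthesis variants for the per-cycle increment `delta`: a
*noisy integrator* (`delta ~ N(mean_delta, sigma_delta)`, uncorrelated
with growth) and a *noisy synthesis rate* (`delta = K t` with
`K ~ N(mean_K, sigma_K)` and `t` the realized post-commitment duration,
which couples synthesis noise to timing noise).

**Initiator accumulation.** A regulator `A` is synthesized in
proportion to volume growth (`dA = c2 dV`), triggers commitment when it
reaches an absolute threshold `Ac ~ N(mean_Ac, sigma_i)`, and is
degraded entirely at commitment:

    Vi = Vb + (Ac - Ab) / c2
    Ad = c2 (Vd - Vi)

**Budding morphology.** After commitment all growth goes to the bud;
at division the mother keeps its commitment volume `Vi` and the bud
separates as a daughter of volume `Vd - Vi`. Post-commitment growth is
either *noisy asymmetry* (`Vd = Vi (1 + x)`, `x ~ N(mean_x, sigma_x)`;
the realized division asymmetry r equals x exactly) or *noisy timing*
(`Vd = Vi e^{lambda t}` with independent Gaussian `lambda` and `t`).
The regulator at division is split between mother and daughter by
volumetric fraction, so volume and regulator are conserved exactly at
every division.

**Non-budding (bacterial) morphology.** Cells grow fully before
dividing into fractions `f` and `1 - f` of `Vd` (f = 0.5 for
symmetric division). Growth is exponential over the C + D period
`t ~ N(mean_t, sigma_t)` between replication initiation and division;
we stay in the slow-growth regime (C + D < t_db) with at most one
initiation per cycle and no overlapping replication rounds.

**Immediate commitment (monotonic constraint).** Cells born already
past the commitment criterion (inhibitor below threshold, or initiator
above threshold) commit immediately at their birth volume, so volume
never decreases. This is on by default everywhere except the bacterial
accumulation recursion, which follows the bare initiation-to-initiation
map

    2 Vi' = Vi + (Ac + xi_i)/c2,
    Vb = Vi e^{lambda (mean_t + xi_t)} / 2

under which the closed-form slope below is derived (a clamp flag
exists but defaults off there).

## Key closed forms

* Dilution mother-lineage fixed point: `Vi* = mean_delta / (r c1)`,
  `Ib* = c1 Vi*`. Mothers saturate with no G1 growth and progeny are
  born exactly at threshold; with noise, a finite fraction of cells is
  born past threshold, which is why the monotonic constraint matters.
* Accumulation mother recursion. Composing the threshold rule with
  volumetric partitioning gives `Vi' = mean_Ac/c2 + Vi/(1 + r)`, fixed
  point `Vi* = mean_Ac (1 + r)/(r c2)`. An alternative closed form with
  coefficient `r/(1 + r)` and fixed point `mean_Ac (1 + r)/c2`
  circulates in the literature; the two coincide exactly at r = 1
  (both give `2 mean_Ac/c2`, the only case used quantitatively here)
  and `accumulation_fixed_point` returns both with a disagreement flag
  rather than silently choosing one for r != 1.
* Stationary identities (population-weighted): `<Ib> = mean_delta`
  (conservation at division plus doubling of the population), and the
  mean G1 growth of a mother-daughter pair equals
  `mean_delta (1 - r)/c1` — exactly zero for symmetric division, the
  root of the symmetric-budding failure.
* Bacterial accumulation slope: with `a = exp(lambda^2 sigma_t^2 / 2)`
  and `b = sigma_i / mean_Ac`,

      S(Vb, Vd) = 1 / (a^2 + 3 (a^2 - 1) / b^2),

  approaching 1 when threshold noise dominates timing noise
  (`b >> lambda sigma_t`) and 0 in the opposite limit. The lowest-order
  approximation `1/(1 + 3 lambda^2 sigma_t^2 / b^2)` is exposed
  alongside. Note that at the frequently quoted noise point
  `b = sigma_t/t_db = 0.1` the formula (and our simulations, which
  agree with it to Monte-Carlo precision) gives S ~ 0.41, not an adder:
  adder behavior requires `b` several times `lambda sigma_t`.

## Sampling ensembles

All noise variables are Gaussian, drawn independently per cycle and per
cell. Physically positive quantities (x, t, lambda, delta, K, Ac in the
budding models) are rejection-resampled at non-positive draws; at the
biological regime CV <= 0.3 this is a < 5e-4 event with relative mean
bias < 1e-3 (asserted by a million-draw test). The additive threshold
noise eta may be negative, and the bacterial accumulation noises xi_i,
xi_t are left unbounded to match the closed form's assumptions. A draw
with sigma = 0 returns the mean exactly and consumes no random state,
so noiseless runs are closed-form-checkable. All randomness derives
from one root seed through `SeedSequence` substreams per
lineage/replicate, so enlarging a run never reshuffles earlier streams.

**Lineage records.** `simulate_records` follows, by default, a
*random-descent* lineage: after each division the chain continues with
the mother or the daughter with probability 1/2. Because every division
produces exactly one continuing mother and one new daughter, this chain
samples the stationary measure of the full branching population, which
is the weighting under which the stationary identities above hold (a
chain that always follows the mother instead converges to the old-age
mother distribution and, e.g., overestimates `<Ib>` by (1 + 1/r)/2).
The mother-chain scheme, with each daughter's own first cycle recorded
as a side branch, remains available as `descent="mother"` for
mother/daughter-resolved statistics.

**Slope estimation.** Birth-division slopes are ordinary least squares
of Vd on Vb (`scipy.stats.linregress`); daughter-only records are the
default surface for asymmetric budding heatmaps. Symmetric budding is
non-stationary (sizes random-walk), so there the slope is estimated as
the mean of per-lineage OLS fits: pooling lineages that have drifted to
different scales would add a between-lineage variance component that
pulls the estimate toward exactly 2 regardless of the within-population
correlation. Lineages of ~1000 records keep the per-lineage
autocorrelation bias below ~0.01.

**Passaging.** `passage_simulation` is an asynchronous population
simulation: each cell's full cycle (and hence its division time) is
drawn at birth; both progeny are kept; when the population exceeds
`n_max` it is reseeded with `n_keep` cells chosen uniformly at random.
Defaults `n_max = 2000`, `n_keep = 200`, 5 replicates, snapshots every
10 doubling times; statistics (mean, sd, CV, sd of log) are over the
extant cells' current birth volumes. Internally, division events are
processed in vectorized batches within one-doubling-time sub-slices;
per-cell dynamics are exact, and only the timing of the dilution cull
is quantized to these batches (the cull is a uniform subsample either
way, so snapshot statistics are unbiased — checked against two caps).

**Coalescence caveat.** Repeated bottlenecks to `n_keep` cells make
lineages coalesce, which caps the *within-population* variance after
roughly the coalescence time (order `n_keep` generations). Two
consequences, both visible in the tests: the pure-timer control
reproduces the geometric-random-walk exponent 0.5 only over a window
before coalescence (we use the first 100 doubling times at caps
5000/500; at 2000 doubling times the measured exponent has fallen to
~0.2), and the desk-scale symmetric/asymmetric sd(Vb) fold-ratio
plateaus around 15-20 at the default caps over 1e4 doubling times,
an order of magnitude, rather than the two orders reached by
paper-scale populations over 2.5e5 doubling times (available via
`run_scenario("fig4", full=True)`).

## Problem sizes and defaults

Slope points use 1e4 post-burn-in records (burn-in 50 generations);
sweep grids default to 7x7 cells at 1e4 records per cell (13x13 with
`--full`); the variance-growth exponent uses 8 replicates of 1000
doubling times; the saturation ratio uses 5 replicates of 1e4 doubling
times per arm. With these sizes the whole test suite runs in about half
a minute and `scripts/acceptance.py` in under a minute on one core.

Default units: `c1 = c2 = 1` (they only set the size scale; correlations
are independent of them when noise strengths are given relatively),
`mean_lambda = ln 2` so one time unit is one volume doubling, and
`mean_t = 0.7` for bacteria (slow growth, C + D < t_db).

## Limitations

No cell death, no correlated or non-Gaussian noise, no mother-daughter
noise inheritance, no multiple replication forks or extra initiation
rounds (the bacterial closed form is known to degrade for
sigma_i/mean_Ac >~ 0.3 where extra initiations would matter), and no
molecular detail beneath the two abstracted circuits. The generators
emulate idealized exponential single-cell growth with volumetric
regulator partitioning; passing tests therefore validate the circuit
logic and its statistical signatures, not organism-specific biology.
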