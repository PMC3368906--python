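# Methods

## The model

`fragforage` simulates individual parasitoid females foraging for hosts in a
fragmented landscape and asks which heritable strategy maximises lifetime
reproductive success. The landscape is non-spatial: it consists of identical
habitat patches of quality `n0` (hosts per patch) separated by a fixed travel
time `T` (time steps of host-free matrix). A female is born on a
host-containing patch with probability `p` (environmental stability);
otherwise she must first disperse for `T` steps.

### Trade-off and plasticity

Each female has a fixed resource budget split between somatic maintenance
(longevity) and egg production along a linear trade-off running from
(0 eggs, `max_longevity` = 1000 time steps) to (`max_eggload` = 1000 eggs,
0 lifespan). Three heritable parameters describe a strategy:

- **g1** — initial position on the trade-off, in longevity units (0–1000);
- **g2** — phenotypic plasticity: the width, in trade-off units, of the
  interval of positions reachable during life (0–1000);
- **g3** — memory factor of the learning rule (0–1).

Plasticity is costly: carrying a plastic range `g2` at cost fraction `c`
rescales *both* axes of the trade-off by `1 − c·g2/1000` (a symmetric,
linear cost; with maximal plasticity and `c = 0.5` a female is limited to
half of both her maximal lifetime and egg load). The plasticity interval is
centred on the cost-scaled `g1` by default; because a one-sided placement is
an equally defensible reading of the trade-off picture, `bounds_mode="upward"`
selects it instead. Clipping at the frontier edges shifts the interval rather
than truncating it, so the full (cost-scaled) width is always available.

### Within-patch dynamics and patch leaving

On a patch the cumulative number of progeny after `t` steps follows the
depletion curve `N(t) = n0·(1 − exp(−α·t))`, a standard saturating gain
model; α defaults to 0.01 per time step, which makes marginal-value-theorem
residence times commensurate with travel times of 100–500 steps. The curve
is a pluggable contract (`GainCurve`); the per-step increment is the exact
discrete difference `N(t) − N(t−1)`, so increments sum to the cumulative
curve without drift. Progeny are discrete: increments accumulate in a
fractional accumulator and a whole egg is laid each time it exceeds one
(if the female still has a whole egg to lay; surplus encounters are lost).

A female leaves a patch at the smallest integer residence time at which her
local production rate has fallen to the average rate of the environment as a
whole, `N(t)/(t+T)` — the marginal value theorem. For the exponential gain
curve this crossing is independent of `n0`. Leaving is additionally gated by
a dynamic rule re-evaluated every step: she only departs if her remaining
lifespan covers the travel time `T`; otherwise she stays on the depleting
patch. There is no travel mortality; a female who can never reach another
patch lives out her time (and keeps learning). The MVT residence time is
computed from the analytic environment-wide rate; setting
`mvt_reference="learned"` instead leaves when the local rate falls below the
female's own current estimate µ (see below).

### Learning and reallocation

Females estimate their overall host-encounter rate µ with a linear operator.
The observable each step is the instantaneous rate λ: 0.0 while travelling,
the per-step gain increment while on a patch, capped at `1/t1` where `t1` is
the time to the first host on a fresh patch (so `1/t1` is the attainable
maximum). The prior `µ0` is the midpoint of the two extremes, `1/(2·t1)`.
Updates are `µ_i = g3·µ_{i−1} + (1−g3)·λ_i`; `g3 = 1` never updates,
`g3 = 0` is memoryless. Updates happen every time step of life, including
during travel (`update_during_travel=False` restricts them to patches).

µ is mapped linearly onto the plasticity interval — µ = 0 aims at the
longevity end, µ ≥ `1/t1` at the egg end — and each step the female re-aims
the *unspent* part of her budget at that target. Accounting is dimensionless:
living one step consumes `1/eff_longevity` of the budget and committing one
egg consumes `1/eff_eggload`; time already lived and eggs already laid are
irrevocable, so the feasible positions at any moment are
`[time_lived, eff_longevity·(1 − progeny/eff_eggload)]`. This scheme makes
the bidirectional conversion exact (the three normalized components — time
spent, eggs committed, unspent remainder — sum to 1 to machine precision at
every step) and is what lets an egg-exhausted female with remaining lifespan
trade time back into new eggs, and vice versa. Reallocation defaults to
every step; `realloc_every_step=False` confines it to patch transitions.

The step order is fixed and tested: (1) live one step; (2) accrue gain and
lay; (3) observe λ, update µ; (4) reallocate; (5) patch-leaving/arrival.
The order is a modelling choice that matters only at edges (e.g. death and
last egg in the same step) and is therefore frozen.

### Fitness

A generation ends when the female runs out of time (eggs alone do not end a
life, since plasticity may buy new ones, but a female with neither eggs nor
plasticity simply lives out her remaining time). Fitness of a strategy in an
environment is the arithmetic mean progeny over 20 independent generations.
The only stochastic element of a generation is the Bernoulli(`p`) natal
draw; conditional on it, a life is deterministic. The implementation
therefore draws the 20 Bernoulli starts and reuses the at most two distinct
trajectories — exactly equivalent to simulating 20 generations, at a tenth
of the cost. The inner loop also exists as a numba-compiled kernel that
mirrors the object-level `step` statement for statement; the test suite
asserts exact agreement of the two paths.

## Optimisation

Optimal (g1, g2, g3) per environment are found with a steady-state,
GENITOR-style genetic algorithm: a population of 100 real-coded chromosomes
(genes in [0,1]³ decoded linearly to the strategy ranges), one offspring per
cycle produced from two parents drawn by linear rank selection (bias 1.5,
configurable), blend crossover with probability 0.60 (else a clone of the
fitter parent), per-gene mutation by uniform redraw with probability 0.025,
evaluation once at creation, and replacement of the current worst member;
500 cycles. Because fitness is stochastic a chromosome can be lucky at its
single evaluation; the classic mitigation is used: each environment is
optimised 10 times from independent seeds and the best solution kept.
Operator choices (blend crossover, uniform redraw) are standard real-coded
defaults; rates and population structure are fixed study conditions.

## Experiment and analysis

The full design crosses `n0 ∈ {25,50,100,250,500,750,1000}`,
`T ∈ {100,…,500}`, `p ∈ {0,…,1}` and `c ∈ {0.1,…,0.5}`: 875 environments.
Optimised g1/g2/g3 are analysed with a four-way fixed-effects ANOVA with
all six two-way interactions (factors categorical; with one observation per
cell of a balanced factorial, Type I/II/III sums of squares coincide, and
sequential SS are used). Model df are 18 (main) + 120 (interactions),
residual df 736. Trend summaries report per-level mean ± SE.

Per-cell seeds derive from a master seed and the cell index via
`numpy.random.SeedSequence`, and restart streams via `Generator.spawn`, so a
batch run is bit-reproducible and independent of the worker count.

## Problem sizes used in tests and the acceptance script

The full 875-cell × 10-restart optimisation is the package's production
workload. The shipped checks run a reduced study chosen to exercise the
extreme factor levels: the 16-cell grid `n0 ∈ {25,1000} × T ∈ {100,500} ×
p ∈ {0,1} × c ∈ {0.1,0.5}` with GA settings (population 50, 200 cycles,
3 restarts), repeated over five master seeds, and directional contrasts of
the optimised parameters are computed from the pooled results. The
budget-conservation audit uses 10⁴ random lives; the MVT oracle comparison
covers all study levels of `n0` and `T` at three depletion rates.

## What the generator does and does not emulate

Environments are homogeneous: all patches share one quality and one travel
time, and stochasticity enters only through the natal draw. Host feeding,
superparasitism, egg-maturation delays, larval/adult mortality and
competition are deliberately excluded, as is any spatially explicit
landscape. Passing trend checks therefore demonstrate the direction of
selection under the model's assumptions, not quantitative predictions for
any real species.

## Numerical choices and degenerate inputs

- Positions and resources are real-valued; eggs are integerised only at
  laying, via the fractional accumulator.
- A female dies when her remaining time budget drops below one full step.
- `cost = 1` with maximal plasticity collapses the frontier to a point; the
  simulation returns zero progeny rather than dividing by zero.
- Patches with `n0 < 1` can never yield a host and are rejected.
- The MVT crossing is found by integer scan (residence times are a few
  hundred steps at the default α, so the scan is cheap and exact).
- Ties in GA ranking are broken by stable sort; the best member can never
  be replaced (population ≥ 2), making the best-fitness history monotone.

## Known limitations

- The learned-threshold leaving variant and the transition-only
  reallocation cadence are provided as switches but the study conditions
  use the analytic MVT time and per-step reallocation.
- GA selection pressure (rank bias) is weakly identified by the algorithm
  description it follows; 1.5 is the conventional default and configurable.
- With `p ∈ {0,1}` the reduced-scale study is fully deterministic per
  restart; variability across master seeds comes from GA initialisation
  and operators only.
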