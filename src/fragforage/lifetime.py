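"""Discrete-time simulation of a female's life and strategy fitness.

One simulated female carries a resource budget that she has pre-split
between lifespan and egg load at the heritable position ``g1`` on the
cost-scaled trade-off frontier.  Every time step she (1) lives one step,
(2) if on a patch accrues the gain increment and lays whole eggs,
(3) observes an instantaneous encounter rate and updates her estimate
``mu``, (4) re-aims the *unspent* part of her budget at the allocation
position her learning rule currently favours (time already lived and eggs
already laid are irrevocable), and (5) leaves the patch once past the MVT
residence time provided she can survive the travel to the next one.

Fitness of a strategy in an environment is the arithmetic mean progeny
over 20 independent generations; the only stochastic element of a
generation is the Bernoulli(p) draw of whether the female is born on a
host-containing patch, so a generation is deterministic given that draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .learning import allocation_target, current_lambda, update_estimate
from .patch import (
    GainCurve,
    dynamic_leave_decision,
    mvt_leaving_time,
    per_step_gain,
    time_to_first_host,
)
from .tradeoff import Strategy, TradeoffSpec, effective_frontier, plasticity_bounds

__all__ = [
    "Environment",
    "FemaleContext",
    "FemaleState",
    "female_context",
    "init_female",
    "step",
    "budget_audit",
    "simulate_generation",
    "simulate_trajectory",
    "fitness",
]


@dataclass(frozen=True)
class Environment:
    """One habitat configuration.

    n0 : hosts per habitat patch.
    travel_time : time steps spent travelling between patches (T).
    p_natal : probability that a female starts her life on a
        host-containing patch (environmental stability, p).
    cost : plasticity cost fraction (c).
    alpha : depletion rate of the within-patch gain curve.
    tradeoff : extent of the longevity–fecundity trade-off.
    bounds_mode : placement of the plasticity interval around g1
        ("centered" or "upward").
    update_during_travel : whether the encounter-rate estimate is also
        updated (with lambda = 0) while travelling.
    realloc_every_step : reallocate the unspent budget every step (True)
        or only at patch arrivals/departures (False).
    mvt_reference : "global" uses the analytic MVT residence time;
        "learned" leaves when the local rate falls below the female's own
        estimate mu.
    """

    n0: float
    travel_time: float
    p_natal: float
    cost: float
    alpha: float = 0.01
    tradeoff: TradeoffSpec = field(default_factory=TradeoffSpec)
    bounds_mode: str = "centered"
    update_during_travel: bool = True
    realloc_every_step: bool = True
    mvt_reference: str = "global"

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.travel_time < 1:
            raise ValueError("travel_time must be at least 1")
        if not 0.0 <= self.p_natal <= 1.0:
            raise ValueError("p_natal must be in [0, 1]")
        if not 0.0 <= self.cost <= 1.0:
            raise ValueError("cost must be in [0, 1]")
        if self.mvt_reference not in ("global", "learned"):
            raise ValueError("mvt_reference must be 'global' or 'learned'")


@dataclass(frozen=True)
class FemaleContext:
    """Constants of one (strategy, environment) pairing."""

    curve: GainCurve
    scale: float
    eff_longevity: float
    eff_eggload: float
    lo: float
    hi: float
    pos0: float
    t_star: int
    t1: int
    rate_max: float
    g3: float


@dataclass
class FemaleState:
    """Mutable state of a live female."""

    ctx: FemaleContext
    position: float
    remaining_time: float
    eggs_remaining: float
    time_lived: float = 0.0
    progeny: int = 0
    egg_accumulator: float = 0.0
    phase: str = "foraging"
    patch_clock: int = 0
    travel_remaining: float = 0.0
    mu: float = 0.0

    @property
    def alive(self) -> bool:
        return self.remaining_time >= 1.0


def female_context(strategy: Strategy, env: Environment) -> FemaleContext:
    strategy.validate(env.tradeoff)
    frontier = effective_frontier(env.tradeoff, strategy.g2, env.cost)
    lo, hi = plasticity_bounds(strategy.g1, strategy.g2, frontier, env.bounds_mode)
    curve = GainCurve(env.n0, env.alpha)
    t1 = time_to_first_host(curve)
    return FemaleContext(
        curve=curve,
        scale=frontier.scale,
        eff_longevity=frontier.eff_longevity,
        eff_eggload=frontier.eff_eggload,
        lo=lo,
        hi=hi,
        pos0=strategy.g1 * frontier.scale,
        t_star=mvt_leaving_time(curve, env.travel_time),
        t1=t1,
        rate_max=1.0 / t1,
        g3=strategy.g3,
    )


def init_female(
    strategy: Strategy,
    env: Environment,
    rng: np.random.Generator,
    start_on_patch: bool | None = None,
) -> FemaleState:
    """Create a newborn female; draws the natal-patch Bernoulli unless
    ``start_on_patch`` is forced."""
    ctx = female_context(strategy, env)
    if start_on_patch is None:
        start_on_patch = bool(rng.random() < env.p_natal)
    eff_l = ctx.eff_longevity
    eggs0 = 0.0 if eff_l <= 0 else ctx.eff_eggload * (1.0 - ctx.pos0 / eff_l)
    return FemaleState(
        ctx=ctx,
        position=ctx.pos0,
        remaining_time=ctx.pos0,
        eggs_remaining=eggs0,
        phase="foraging" if start_on_patch else "travelling",
        travel_remaining=0.0 if start_on_patch else float(env.travel_time),
        mu=0.5 * ctx.rate_max,
    )


def _reallocate(state: FemaleState, target: float) -> None:
    ctx = state.ctx
    position, remaining, eggs = _kernel._reallocate(
        target, state.time_lived, state.progeny, ctx.eff_longevity, ctx.eff_eggload
    )
    state.position = position
    state.remaining_time = remaining
    state.eggs_remaining = eggs


def step(state: FemaleState, env: Environment) -> FemaleState:
    """Advance the female by one time step (in place; also returned)."""
    if not state.alive:
        raise RuntimeError("stepping a dead female")
    ctx = state.ctx
    state.time_lived += 1.0
    state.remaining_time -= 1.0
    gain_inc = 0.0
    on_patch = state.phase == "foraging"
    if on_patch:
        state.patch_clock += 1
        gain_inc = per_step_gain(ctx.curve, state.patch_clock)
        state.egg_accumulator += gain_inc
        while state.egg_accumulator >= 1.0:
            state.egg_accumulator -= 1.0
            if state.eggs_remaining >= 1.0:
                state.eggs_remaining -= 1.0
                state.progeny += 1
    else:
        state.travel_remaining -= 1.0
    lam = current_lambda(on_patch, gain_inc, ctx.rate_max)
    if on_patch or env.update_during_travel:
        state.mu = update_estimate(state.mu, lam, ctx.g3)
    if env.realloc_every_step:
        _reallocate(state, allocation_target(state.mu, ctx.rate_max, (ctx.lo, ctx.hi)))
    transitioned = False
    if on_patch:
        if env.mvt_reference == "learned":
            leave = gain_inc <= state.mu and state.remaining_time >= env.travel_time
        else:
            leave = dynamic_leave_decision(
                state.patch_clock, ctx.t_star, state.remaining_time, env.travel_time
            )
        if leave:
            state.phase = "travelling"
            state.travel_remaining = float(env.travel_time)
            state.patch_clock = 0
            state.egg_accumulator = 0.0
            transitioned = True
    else:
        if state.travel_remaining <= 0.0:
            state.phase = "foraging"
            state.patch_clock = 0
            transitioned = True
    if transitioned and not env.realloc_every_step:
        _reallocate(state, allocation_target(state.mu, ctx.rate_max, (ctx.lo, ctx.hi)))
    return state


def budget_audit(state: FemaleState) -> tuple[float, float, float]:
    """Normalized (time spent, eggs committed, unspent remainder).

    The three components sum to 1 throughout a female's life: living one
    step consumes ``1/eff_longevity`` of the budget, committing one egg
    consumes ``1/eff_eggload``, and reallocation only re-aims the rest.
    """
    ctx = state.ctx
    if ctx.eff_longevity <= 0:
        return 0.0, 0.0, 1.0
    spent_time = state.time_lived / ctx.eff_longevity
    committed = state.progeny / ctx.eff_eggload
    unspent = (
        state.remaining_time / ctx.eff_longevity
        + state.eggs_remaining / ctx.eff_eggload
    )
    return spent_time, committed, unspent


def _kernel_run(strategy: Strategy, env: Environment, start_on_patch: bool):
    ctx = female_context(strategy, env)
    return _kernel.live_one_life(
        ctx.pos0,
        ctx.g3,
        float(env.n0),
        float(env.alpha),
        float(env.travel_time),
        ctx.eff_longevity,
        ctx.eff_eggload,
        ctx.lo,
        ctx.hi,
        ctx.t_star,
        ctx.rate_max,
        bool(start_on_patch),
        env.update_during_travel,
        env.realloc_every_step,
        env.mvt_reference == "learned",
    )


def simulate_generation(
    strategy: Strategy,
    env: Environment,
    rng: np.random.Generator | None = None,
    start_on_patch: bool | None = None,
    engine: str = "fast",
) -> int:
    """Lifetime progeny of one female (one generation).

    ``engine="fast"`` runs the compiled kernel, ``"reference"`` the
    object-level :func:`step` loop; both implement the same model.
    """
    if start_on_patch is None:
        if rng is None:
            raise ValueError("need an rng when start_on_patch is not forced")
        start_on_patch = bool(rng.random() < env.p_natal)
    if engine == "fast":
        return int(_kernel_run(strategy, env, start_on_patch)[0])
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")
    state = init_female(strategy, env, rng=np.random.default_rng(0),
                        start_on_patch=start_on_patch)
    while state.alive:
        step(state, env)
    return state.progeny


def simulate_trajectory(
    strategy: Strategy, env: Environment, start_on_patch: bool
):
    """Full per-step trajectory of one female as a pandas DataFrame.

    Columns: time, phase, position, mu, eggs_remaining, progeny.
    Intended for debugging and for the ``fragforage simulate`` command.
    """
    import pandas as pd

    state = init_female(strategy, env, rng=np.random.default_rng(0),
                        start_on_patch=start_on_patch)
    rows = []
    while state.alive:
        step(state, env)
        rows.append(
            (
                state.time_lived,
                state.phase,
                state.position,
                state.mu,
                state.eggs_remaining,
                state.progeny,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["time", "phase", "position", "mu", "eggs_remaining", "progeny"],
    )


def fitness(
    strategy: Strategy,
    env: Environment,
    rng: np.random.Generator,
    n_generations: int = 20,
    engine: str = "fast",
) -> float:
    """Arithmetic mean progeny per generation over independent generations.

    Each generation redraws the Bernoulli(p) natal start; conditional on
    that draw a life is deterministic, so the two possible trajectories
    are simulated once each and reused.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be at least 1")
    starts = rng.random(n_generations) < env.p_natal
    cache: dict[bool, int] = {}
    total = 0
    for s in starts:
        s = bool(s)
        if s not in cache:
            cache[s] = simulate_generation(
                strategy, env, start_on_patch=s, engine=engine
            )
        total += cache[s]
    return total / n_generations
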