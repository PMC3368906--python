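"""Steady-state (GENITOR-style) genetic algorithm over strategy triplets.

One chromosome carries three real-coded genes in [0, 1] that decode to
(g1, g2, g3).  Each cycle ranks the population, draws two parents with
linear rank bias, produces a single offspring by blend crossover (with
the configured recombination probability, else a clone of the fitter
parent), mutates each gene independently by uniform redraw, evaluates it
once, and replaces the current worst chromosome.  Because the best
member is never discarded, the best evaluated fitness is non-decreasing
across cycles.  Stochastic fitness surfaces are handled by the classic
multi-restart rule: optimise several times and keep the best solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tradeoff import Strategy, TradeoffSpec

__all__ = [
    "Chromosome",
    "GAConfig",
    "decode",
    "encode",
    "evolve",
    "best_of_restarts",
    "make_sim_fitness",
]


@dataclass(frozen=True)
class GAConfig:
    """GA settings; defaults are the full-scale optimisation settings."""

    population_size: int = 100
    cycles: int = 500
    mutation_rate: float = 0.025
    recombination_rate: float = 0.60
    restarts: int = 10
    fitness_generations: int = 20
    selection_bias: float = 1.5
    tradeoff: TradeoffSpec = field(default_factory=TradeoffSpec)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.cycles < 1 or self.restarts < 1 or self.fitness_generations < 1:
            raise ValueError("cycles, restarts and fitness_generations must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.recombination_rate <= 1.0:
            raise ValueError("recombination_rate must be in [0, 1]")
        if not 1.0 <= self.selection_bias <= 2.0:
            raise ValueError("selection_bias must be in [1, 2]")


@dataclass
class Chromosome:
    """Real-coded genes in [0, 1]^3 plus the fitness evaluated at creation."""

    genes: np.ndarray
    fitness: float

    @property
    def strategy(self) -> Strategy:
        return decode(self.genes)


def decode(genes: np.ndarray, spec: TradeoffSpec = TradeoffSpec()) -> Strategy:
    """Map unit-interval genes onto the strategy ranges; exact at endpoints."""
    return Strategy(
        g1=float(genes[0]) * spec.max_longevity,
        g2=float(genes[1]) * spec.max_plasticity,
        g3=float(genes[2]),
    )


def encode(strategy: Strategy, spec: TradeoffSpec = TradeoffSpec()) -> np.ndarray:
    return np.array(
        [
            strategy.g1 / spec.max_longevity,
            strategy.g2 / spec.max_plasticity,
            strategy.g3,
        ]
    )


def make_sim_fitness(env, n_generations: int = 20, engine: str = "fast"):
    """Fitness contract backed by the lifetime simulator."""
    from .lifetime import fitness as sim_fitness

    def _fitness(strategy: Strategy, rng: np.random.Generator) -> float:
        return sim_fitness(strategy, env, rng, n_generations=n_generations,
                           engine=engine)

    return _fitness


def _rank_index(u: float, n: int, bias: float) -> int:
    """Linear rank selection: index 0 is the best-ranked individual.

    With bias b in [1, 2], rank i is drawn with probability proportional
    to ``b - 2*(b-1)*i/(n-1)`` (the classic GENITOR bias curve).
    """
    if bias == 1.0:
        return int(u * n)
    i = n * (bias - math.sqrt(bias * bias - 4.0 * (bias - 1.0) * u)) / (
        2.0 * (bias - 1.0)
    )
    return min(int(i), n - 1)


def _evaluate(fitness_fn, genes, rng, cfg) -> float:
    value = float(fitness_fn(decode(genes, cfg.tradeoff), rng))
    if not math.isfinite(value):
        raise ValueError(f"non-finite fitness {value} for genes {genes.tolist()}")
    return value


def evolve(
    env,
    cfg: GAConfig,
    rng: np.random.Generator,
    fitness_fn=None,
) -> tuple[Chromosome, list[float]]:
    """One steady-state GA run; returns the best chromosome and the
    per-cycle best-fitness history (monotonically non-decreasing).

    ``fitness_fn(strategy, rng) -> float`` may be injected (e.g. an
    analytic surface for testing); by default it is the lifetime
    simulator on ``env``.
    """
    if fitness_fn is None:
        if env is None:
            raise ValueError("need an Environment or an injected fitness_fn")
        fitness_fn = make_sim_fitness(env, cfg.fitness_generations)
    n = cfg.population_size
    genes = rng.random((n, 3))
    fit = np.empty(n)
    for i in range(n):
        fit[i] = _evaluate(fitness_fn, genes[i], rng, cfg)
    history: list[float] = []
    for _ in range(cfg.cycles):
        order = np.argsort(-fit, kind="stable")  # order[0] = current best
        i1 = order[_rank_index(rng.random(), n, cfg.selection_bias)]
        i2 = order[_rank_index(rng.random(), n, cfg.selection_bias)]
        if rng.random() < cfg.recombination_rate:
            w = rng.random(3)
            child = w * genes[i1] + (1.0 - w) * genes[i2]
        else:
            child = genes[i1 if fit[i1] >= fit[i2] else i2].copy()
        for k in range(3):
            if rng.random() < cfg.mutation_rate:
                child[k] = rng.random()
        child_fit = _evaluate(fitness_fn, child, rng, cfg)
        worst = int(np.argmin(fit))
        genes[worst] = child
        fit[worst] = child_fit
        history.append(float(np.max(fit)))
    best = int(np.argmax(fit))
    return Chromosome(genes=genes[best].copy(), fitness=float(fit[best])), history


def best_of_restarts(
    env,
    cfg: GAConfig,
    rng: np.random.Generator,
    fitness_fn=None,
) -> Chromosome:
    """Run ``cfg.restarts`` independent GA runs; keep the fittest solution."""
    streams = rng.spawn(cfg.restarts)
    best: Chromosome | None = None
    for stream in streams:
        cand, _ = evolve(env, cfg, stream, fitness_fn=fitness_fn)
        if best is None or cand.fitness > best.fitness:
            best = cand
    assert best is not None
    return best
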