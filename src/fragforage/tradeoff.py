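"""Geometry of the linear longevity–fecundity trade-off.

A female parasitoid has a fixed resource budget that she can allocate
anywhere along a straight line between two extremes: all somatic
maintenance (long life, zero eggs) or all reproduction (maximal egg load,
zero lifespan).  Positions on this line are expressed in longevity units.
Phenotypic plasticity — the ability to move along the line during life —
is itself costly: maintaining a plastic range ``g2`` shrinks *both* axes
of the trade-off by the same proportion, ``1 - c * g2 / max_plasticity``.

Everything here is pure, deterministic computation consumed by
:mod:`fragforage.lifetime`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TradeoffSpec",
    "Strategy",
    "EffectiveFrontier",
    "effective_frontier",
    "allocation_at",
    "plasticity_bounds",
]


@dataclass(frozen=True)
class TradeoffSpec:
    """Extent of the longevity–fecundity trade-off.

    Parameters
    ----------
    max_longevity : float
        Lifespan at the all-survival endpoint, in time steps.
    max_eggload : float
        Egg load at the all-reproduction endpoint, in eggs.

    The maximal plasticity range (``max_plasticity``) equals
    ``max_longevity`` because plasticity is measured in units along the
    trade-off, which is parameterised by longevity.
    """

    max_longevity: float = 1000.0
    max_eggload: float = 1000.0

    def __post_init__(self) -> None:
        if self.max_longevity <= 0 or self.max_eggload <= 0:
            raise ValueError("trade-off axes must be positive")

    @property
    def max_plasticity(self) -> float:
        return self.max_longevity


@dataclass(frozen=True)
class Strategy:
    """Heritable strategy triplet.

    g1 : initial allocation position, longevity units in [0, max_longevity].
    g2 : phenotypic plasticity range, trade-off units in [0, max_plasticity].
    g3 : memory factor of the learning rule, dimensionless in [0, 1];
         1 never updates the encounter-rate estimate, 0 is memoryless.
    """

    g1: float
    g2: float
    g3: float

    def validate(self, spec: TradeoffSpec) -> "Strategy":
        if not 0.0 <= self.g1 <= spec.max_longevity:
            raise ValueError(f"g1={self.g1} outside [0, {spec.max_longevity}]")
        if not 0.0 <= self.g2 <= spec.max_plasticity:
            raise ValueError(f"g2={self.g2} outside [0, {spec.max_plasticity}]")
        if not 0.0 <= self.g3 <= 1.0:
            raise ValueError(f"g3={self.g3} outside [0, 1]")
        return self


@dataclass(frozen=True)
class EffectiveFrontier:
    """Trade-off frontier after paying the plasticity cost.

    ``scale`` multiplies both axes identically, so
    ``eff_longevity / max_longevity == eff_eggload / max_eggload`` exactly.
    """

    scale: float
    eff_longevity: float
    eff_eggload: float


def effective_frontier(spec: TradeoffSpec, g2: float, c: float) -> EffectiveFrontier:
    """Frontier scaled by the symmetric linear plasticity cost.

    A plastic range ``g2`` at cost fraction ``c`` shrinks both the maximal
    lifetime and the maximal egg load by the factor
    ``1 - c * g2 / max_plasticity``; with maximal plasticity and c = 0.5 a
    female is constrained to half of both axes.
    """
    if not 0.0 <= g2 <= spec.max_plasticity:
        raise ValueError(f"g2={g2} outside [0, {spec.max_plasticity}]")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"cost={c} outside [0, 1]")
    scale = 1.0 - c * (g2 / spec.max_plasticity)
    return EffectiveFrontier(
        scale=scale,
        eff_longevity=scale * spec.max_longevity,
        eff_eggload=scale * spec.max_eggload,
    )


def allocation_at(position: float, frontier: EffectiveFrontier) -> tuple[float, float]:
    """(lifespan, egg load) at ``position`` on the effective frontier.

    The frontier is the straight line from (0, eff_eggload) to
    (eff_longevity, 0); both endpoints are attainable.
    """
    if frontier.eff_longevity == 0.0:
        if position != 0.0:
            raise ValueError("position outside degenerate frontier")
        return 0.0, 0.0
    if not 0.0 <= position <= frontier.eff_longevity:
        raise ValueError(
            f"position={position} outside [0, {frontier.eff_longevity}]"
        )
    eggload = frontier.eff_eggload * (1.0 - position / frontier.eff_longevity)
    return position, eggload


def plasticity_bounds(
    g1: float,
    g2: float,
    frontier: EffectiveFrontier,
    mode: str = "centered",
) -> tuple[float, float]:
    """Reachable interval of allocation positions, in longevity units.

    The raw interval has width ``g2 * scale`` (the plastic range also pays
    the cost) and is placed around the cost-scaled ``g1``:

    - ``"centered"`` (default): symmetric around ``g1 * scale``;
    - ``"upward"``: extends from ``g1 * scale`` toward the longevity end.

    Clipping to ``[0, eff_longevity]`` shifts the interval rather than
    truncating it, so the width ``min(g2 * scale, eff_longevity)`` is
    preserved and the scaled ``g1`` stays inside.
    """
    eff_l = frontier.eff_longevity
    if eff_l <= 0.0:
        return 0.0, 0.0
    center = g1 * frontier.scale
    width = min(g2 * frontier.scale, eff_l)
    if mode == "centered":
        lo = center - width / 2.0
    elif mode == "upward":
        lo = center
    else:
        raise ValueError(f"unknown bounds mode {mode!r}")
    lo = min(max(lo, 0.0), eff_l - width)
    return lo, lo + width
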