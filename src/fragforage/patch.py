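"""Within-patch progeny gain and patch-leaving rules.

A host patch of initial quality ``n0`` depletes as it is exploited: the
cumulative number of progeny produced after ``t`` time steps on the patch
follows the saturating curve ``N(t) = n0 * (1 - exp(-alpha * t))``, so the
instantaneous production rate decays exponentially.  A female leaves at
the marginal-value-theorem (MVT) optimum — the first time step at which
her local rate drops to the long-run rate of the environment including
travel — unless her remaining lifespan is too short to survive the trip
to the next patch, in which case she stays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GainCurve",
    "cumulative_gain",
    "instantaneous_rate",
    "per_step_gain",
    "mvt_leaving_time",
    "dynamic_leave_decision",
    "time_to_first_host",
]

#: hard ceiling for the MVT search; far beyond any leaving time reachable
#: with the default depletion rate and the travel times studied
_MVT_SEARCH_CAP = 10_000_000


@dataclass(frozen=True)
class GainCurve:
    """Depletable-patch gain curve ``N(t) = n0 * (1 - exp(-alpha * t))``.

    n0 : initial number of hosts in the patch (the asymptote).
    alpha : depletion rate per time step; the initial production rate is
        ``n0 * alpha``.
    """

    n0: float
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def cumulative_gain(curve: GainCurve, t: float) -> float:
    """Cumulative progeny produced after ``t`` time steps on the patch."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return curve.n0 * (1.0 - math.exp(-curve.alpha * t))


def instantaneous_rate(curve: GainCurve, t: float) -> float:
    """Derivative of :func:`cumulative_gain`: ``n0*alpha*exp(-alpha*t)``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return curve.n0 * curve.alpha * math.exp(-curve.alpha * t)


def per_step_gain(curve: GainCurve, t: int) -> float:
    """Exact discrete gain increment ``N(t) - N(t-1)`` at integer ``t >= 1``.

    Using the discrete difference (rather than the continuous derivative)
    makes per-step increments sum exactly to the cumulative curve.
    """
    if t < 1:
        raise ValueError("t must be a positive integer step")
    return curve.n0 * (
        math.exp(-curve.alpha * (t - 1)) - math.exp(-curve.alpha * t)
    )


def mvt_leaving_time(curve: GainCurve, travel_time: float) -> int:
    """Optimal integer patch residence time under the MVT.

    Returns the smallest integer ``t`` at which the local production rate
    has fallen to the average rate of the environment as a whole,
    ``N(t) / (t + travel_time)``.  For the exponential gain curve the
    crossing condition ``alpha * exp(-alpha*t) * (t + T) <= 1 - exp(-alpha*t)``
    does not involve ``n0``, so patches of every quality share the same
    leaving time; it agrees with the argmax of ``N(t)/(t + T)`` over
    integers to within one step.
    """
    if travel_time <= 0:
        raise ValueError("travel_time must be positive")
    a = curve.alpha
    for t in range(1, _MVT_SEARCH_CAP):
        if a * math.exp(-a * t) * (t + travel_time) <= 1.0 - math.exp(-a * t):
            return t
    raise RuntimeError("MVT search did not converge")  # pragma: no cover


def dynamic_leave_decision(
    t_on_patch: float,
    t_star: float,
    remaining_lifespan: float,
    travel_time: float,
) -> bool:
    """Whether to leave the patch now (True) or stay (False).

    A female leaves once she has reached the MVT residence time *and* has
    enough remaining lifespan to survive the travel to the next patch;
    otherwise she remains on the (depleting) patch.  The rule is
    re-evaluated every time step once ``t_on_patch >= t_star``.
    """
    if min(t_on_patch, t_star, remaining_lifespan, travel_time) < 0:
        raise ValueError("arguments must be non-negative")
    return t_on_patch >= t_star and remaining_lifespan >= travel_time


def time_to_first_host(curve: GainCurve) -> int:
    """Smallest positive integer ``t`` with ``cumulative_gain(t) >= 1``.

    This is ``t1``, whose reciprocal is the highest instantaneous host
    encounter rate a female can experience (on a fresh patch).
    """
    if curve.n0 < 1.0:
        raise ValueError("patch can never yield a whole host (n0 < 1)")
    # analytic ceiling, then settle float boundary cases exactly
    t = max(1, math.ceil(-math.log(1.0 - 1.0 / curve.n0) / curve.alpha))
    while t > 1 and cumulative_gain(curve, t - 1) >= 1.0:
        t -= 1
    while cumulative_gain(curve, t) < 1.0:
        t += 1
    return t
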