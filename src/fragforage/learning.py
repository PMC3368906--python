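"""Linear-operator learning of the host-encounter rate.

Females track a running estimate ``mu`` of the overall host encounter
rate in their environment.  Each time step they observe an instantaneous
rate ``lambda`` — 0.0 while travelling between patches, the per-step
progeny increment while on a patch — and blend it into the estimate:

    mu_i = g3 * mu_{i-1} + (1 - g3) * lambda_i

where the memory factor ``g3`` in [0, 1] is the weight of the past.  The
prior ``mu_0`` is the midpoint of the lowest (0.0, travelling) and the
highest (``1/t1``, first host on a fresh patch) attainable rates.  The
estimate steers the allocation position within the plasticity bounds: the
higher ``mu``, the more a female invests in egg load at the expense of
longevity.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EncounterEstimator",
    "prior_estimate",
    "update_estimate",
    "current_lambda",
    "allocation_target",
]


def prior_estimate(t1: float) -> float:
    """Prior encounter-rate estimate: midpoint of 0 and ``1/t1``."""
    if t1 < 1:
        raise ValueError("t1 must be at least one time step")
    return 0.5 / t1


def update_estimate(mu_prev: float, lambda_now: float, g3: float) -> float:
    """One linear-operator update of the encounter-rate estimate."""
    if not 0.0 <= g3 <= 1.0:
        raise ValueError(f"memory factor g3={g3} outside [0, 1]")
    if lambda_now < 0.0:
        raise ValueError("instantaneous rate must be non-negative")
    return g3 * mu_prev + (1.0 - g3) * lambda_now


def current_lambda(on_patch: bool, per_step_gain: float, rate_max: float) -> float:
    """Instantaneous encounter rate observed this step.

    0.0 while travelling between patches; on a patch, the per-step gain
    increment capped at ``rate_max = 1/t1`` so the stated maximum is the
    top of the mapping domain.
    """
    if per_step_gain < 0.0:
        raise ValueError("per-step gain must be non-negative")
    if not on_patch:
        return 0.0
    return min(per_step_gain, rate_max)


def allocation_target(mu: float, rate_max: float, bounds: tuple[float, float]) -> float:
    """Map the estimate linearly onto the plasticity interval.

    ``mu = 0`` yields the longevity end (``hi``); ``mu = rate_max`` (or
    above, clamped) yields the egg end (``lo``).
    """
    lo, hi = bounds
    if lo > hi:
        raise ValueError("bounds must satisfy lo <= hi")
    if mu < 0.0:
        raise ValueError("mu must be non-negative")
    if rate_max <= 0.0:
        raise ValueError("rate_max must be positive")
    frac = min(mu / rate_max, 1.0)
    return hi + (lo - hi) * frac


@dataclass
class EncounterEstimator:
    """Running encounter-rate estimate of one female.

    mu : current overall estimate (hosts per time step).
    mu0 : the prior, ``rate_max / 2``.
    rate_max : ``1/t1``, the highest attainable instantaneous rate.
    g3 : memory factor.
    """

    mu: float
    mu0: float
    rate_max: float
    g3: float

    @classmethod
    def from_t1(cls, t1: float, g3: float) -> "EncounterEstimator":
        mu0 = prior_estimate(t1)
        return cls(mu=mu0, mu0=mu0, rate_max=1.0 / t1, g3=g3)

    def observe(self, on_patch: bool, per_step_gain: float) -> float:
        """Update with this step's observation; returns the new estimate."""
        lam = current_lambda(on_patch, per_step_gain, self.rate_max)
        self.mu = update_estimate(self.mu, lam, self.g3)
        return self.mu
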