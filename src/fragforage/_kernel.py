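"""Compiled inner loop of the lifetime simulation.

The per-step logic here mirrors :func:`fragforage.lifetime.step`
statement for statement; the test suite asserts that both paths produce
identical lifetime progeny.  Keeping the loop in a module of scalar
arithmetic lets numba compile it, which is what makes the genetic
algorithm affordable.  If numba is unavailable the same function runs as
plain Python.
"""

from __future__ import annotations

import math

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _reallocate(target, time_lived, progeny, eff_l, eff_e):
    """Re-split the unspent budget at allocation position ``target``.

    Time already lived and eggs already laid are irrevocable, so the
    feasible positions are ``[time_lived, eff_l*(1 - progeny/eff_e)]``.
    Returns (position, remaining_time, eggs_remaining).
    """
    feas_lo = time_lived
    feas_hi = eff_l * (1.0 - progeny / eff_e)
    x = target
    if x < feas_lo:
        x = feas_lo
    if x > feas_hi:
        x = feas_hi
    remaining = x - time_lived
    eggs = eff_e * (1.0 - x / eff_l) - progeny
    if eggs < 0.0:
        eggs = 0.0
    return x, remaining, eggs


@njit(cache=True)
def live_one_life(
    pos0,
    g3,
    n0,
    alpha,
    travel_time,
    eff_l,
    eff_e,
    lo,
    hi,
    t_star,
    rate_max,
    start_on_patch,
    update_during_travel,
    realloc_every_step,
    learned_threshold,
):
    """Simulate one female from birth to death; fully deterministic.

    Returns (progeny, time_lived, remaining_time, eggs_remaining,
    position, mu).
    """
    if eff_l <= 0.0:
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    position = pos0
    remaining = pos0
    eggs = eff_e * (1.0 - pos0 / eff_l)
    time_lived = 0.0
    progeny = 0
    acc = 0.0
    mu = 0.5 * rate_max
    foraging = start_on_patch
    patch_clock = 0
    travel_remaining = 0.0 if foraging else travel_time

    while remaining >= 1.0:
        time_lived += 1.0
        remaining -= 1.0
        gain_inc = 0.0
        on_patch = foraging
        if on_patch:
            patch_clock += 1
            gain_inc = n0 * (
                math.exp(-alpha * (patch_clock - 1)) - math.exp(-alpha * patch_clock)
            )
            acc += gain_inc
            while acc >= 1.0:
                acc -= 1.0
                if eggs >= 1.0:
                    eggs -= 1.0
                    progeny += 1
        else:
            travel_remaining -= 1.0
        lam = 0.0
        if on_patch:
            lam = gain_inc if gain_inc < rate_max else rate_max
        if on_patch or update_during_travel:
            mu = g3 * mu + (1.0 - g3) * lam
        if realloc_every_step:
            frac = mu / rate_max
            if frac > 1.0:
                frac = 1.0
            target = hi + (lo - hi) * frac
            position, remaining, eggs = _reallocate(
                target, time_lived, progeny, eff_l, eff_e
            )
        transitioned = False
        if on_patch:
            if learned_threshold:
                ready = gain_inc <= mu
            else:
                ready = patch_clock >= t_star
            if ready and remaining >= travel_time:
                foraging = False
                travel_remaining = travel_time
                patch_clock = 0
                acc = 0.0
                transitioned = True
        else:
            if travel_remaining <= 0.0:
                foraging = True
                patch_clock = 0
                transitioned = True
        if transitioned and not realloc_every_step:
            frac = mu / rate_max
            if frac > 1.0:
                frac = 1.0
            target = hi + (lo - hi) * frac
            position, remaining, eggs = _reallocate(
                target, time_lived, progeny, eff_l, eff_e
            )

    return progeny, time_lived, remaining, eggs, position, mu
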