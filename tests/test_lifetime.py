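"""Lifetime simulation: budget accounting, dynamics, and fitness."""

import math

import numpy as np
import pytest

from fragforage.lifetime import (
    Environment,
    budget_audit,
    female_context,
    fitness,
    init_female,
    simulate_generation,
    simulate_trajectory,
    step,
    _kernel_run,
)
from fragforage.patch import GainCurve, cumulative_gain
from fragforage.tradeoff import Strategy

ENV = Environment(n0=100, travel_time=100, p_natal=0.5, cost=0.2)


def run_life(strategy, env, start_on_patch):
    state = init_female(strategy, env, np.random.default_rng(0),
                        start_on_patch=start_on_patch)
    while state.alive:
        step(state, env)
    return state


class TestInitFemale:
    def test_certain_natal_patch(self, rng):
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.2)
        for _ in range(20):
            assert init_female(Strategy(500, 100, 0.5), env, rng).phase == "foraging"

    def test_certain_dispersal_start(self, rng):
        env = Environment(n0=100, travel_time=100, p_natal=0.0, cost=0.2)
        state = init_female(Strategy(500, 100, 0.5), env, rng)
        assert state.phase == "travelling"
        assert state.travel_remaining == 100

    def test_natal_draw_is_binomial(self, rng):
        n = 10_000
        hits = sum(
            init_female(Strategy(500, 0, 0.5), ENV, rng).phase == "foraging"
            for _ in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_initial_allocation_on_scaled_frontier(self, rng):
        s = Strategy(600, 500, 0.5)
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.2)
        state = init_female(s, env, rng)
        scale = 1 - 0.2 * 0.5
        assert state.position == pytest.approx(600 * scale)
        assert state.remaining_time == pytest.approx(600 * scale)
        assert state.mu == pytest.approx(0.5 * state.ctx.rate_max)


class TestStep:
    def test_stepping_dead_female_is_an_error(self, rng):
        state = init_female(Strategy(0.0, 0.0, 0.5), ENV, rng)
        assert not state.alive
        with pytest.raises(RuntimeError):
            step(state, ENV)

    def test_zero_plasticity_fixes_position_for_life(self, rng):
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.2)
        state = init_female(Strategy(400, 0.0, 0.7), env, rng)
        pos0 = state.position
        while state.alive:
            step(state, env)
            assert state.position == pos0

    def test_egg_exhausted_female_trades_time_back_into_eggs(self, rng):
        """With plasticity available and a high encounter-rate estimate,
        a female out of eggs converts remaining longevity into new eggs."""
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.1)
        state = init_female(Strategy(900, 400, 0.5), env, rng)
        ctx = state.ctx
        # force an egg-exhausted state mid-life at the longevity end
        state.time_lived = 100.0
        state.position = ctx.eff_longevity
        state.remaining_time = ctx.eff_longevity - state.time_lived
        state.eggs_remaining = 0.0
        state.mu = ctx.rate_max
        pos_before = state.position
        step(state, env)
        assert state.position < pos_before
        assert state.eggs_remaining > 0.0

    def test_budget_conservation_along_random_trajectories(self, rng):
        for _ in range(40):
            s = Strategy(rng.uniform(0, 1000), rng.uniform(0, 1000), rng.random())
            env = Environment(
                n0=float(rng.choice([25, 100, 1000])),
                travel_time=float(rng.choice([100, 300, 500])),
                p_natal=1.0,
                cost=float(rng.choice([0.1, 0.3, 0.5])),
            )
            state = init_female(s, env, rng, start_on_patch=bool(rng.random() < 0.5))
            while state.alive:
                step(state, env)
                spent, committed, unspent = budget_audit(state)
                assert spent + committed + unspent == pytest.approx(1.0, abs=1e-9)
            assert state.progeny <= state.ctx.eff_eggload
            assert state.time_lived <= state.ctx.eff_longevity + 1e-9


class TestSimulateGeneration:
    def test_zero_eggload_strategy_yields_nothing(self):
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.2)
        assert simulate_generation(
            Strategy(1000, 0, 0.5), env, start_on_patch=True, engine="reference"
        ) == 0

    def test_dying_mid_travel_yields_nothing(self):
        env = Environment(n0=100, travel_time=500, p_natal=0.0, cost=0.2)
        assert simulate_generation(
            Strategy(400, 0, 0.5), env, start_on_patch=False, engine="reference"
        ) == 0

    def test_egg_limited_progeny_equals_initial_eggload(self):
        # effectively unlimited hosts: progeny is capped by the egg load
        env = Environment(n0=1e6, travel_time=100, p_natal=1.0, cost=0.0)
        progeny = simulate_generation(
            Strategy(600, 0, 0.5), env, start_on_patch=True, engine="reference"
        )
        assert progeny == 400

    def test_time_limited_progeny_equals_cumulative_patch_gain(self):
        # lifespan too short ever to leave the first patch: progeny is the
        # whole-egg part of the gain curve at death
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.0)
        progeny = simulate_generation(
            Strategy(200, 0, 0.5), env, start_on_patch=True, engine="reference"
        )
        assert progeny == math.floor(cumulative_gain(GainCurve(100, 0.01), 200))

    @pytest.mark.parametrize("start", [True, False])
    @pytest.mark.parametrize(
        "update_travel, realloc_every, mvt_ref",
        [
            (True, True, "global"),
            (False, True, "global"),
            (True, False, "global"),
            (True, True, "learned"),
        ],
    )
    def test_fast_kernel_matches_reference_path(
        self, rng, start, update_travel, realloc_every, mvt_ref
    ):
        """The compiled kernel and the object-level step loop implement
        the same model: identical progeny, matching final accounting."""
        for _ in range(12):
            s = Strategy(rng.uniform(0, 1000), rng.uniform(0, 1000), rng.random())
            env = Environment(
                n0=float(rng.choice([25, 250, 1000])),
                travel_time=float(rng.choice([100, 500])),
                p_natal=0.5,
                cost=float(rng.choice([0.1, 0.5])),
                update_during_travel=update_travel,
                realloc_every_step=realloc_every,
                mvt_reference=mvt_ref,
            )
            ref = run_life(s, env, start)
            prog, time_lived, remaining, eggs, position, mu = _kernel_run(s, env, start)
            assert prog == ref.progeny
            assert time_lived == pytest.approx(ref.time_lived)
            assert remaining == pytest.approx(ref.remaining_time, abs=1e-9)
            assert eggs == pytest.approx(ref.eggs_remaining, abs=1e-9)
            assert mu == pytest.approx(ref.mu, abs=1e-12)


class TestFitness:
    def test_deterministic_environment_equals_single_generation(self, rng):
        env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.2)
        s = Strategy(400, 0, 0.5)
        single = simulate_generation(s, env, start_on_patch=True)
        assert fitness(s, env, rng) == pytest.approx(single)

    def test_fitness_never_exceeds_effective_eggload(self, rng):
        for _ in range(20):
            s = Strategy(rng.uniform(0, 1000), rng.uniform(0, 1000), rng.random())
            env = Environment(
                n0=1000, travel_time=100, p_natal=0.5, cost=0.3
            )
            eff_e = female_context(s, env).eff_eggload
            assert fitness(s, env, rng) <= eff_e + 1e-9

    def test_variance_shrinks_with_generations(self, rng):
        env = Environment(n0=500, travel_time=200, p_natal=0.5, cost=0.2)
        s = Strategy(500, 200, 0.8)
        var1 = np.var([fitness(s, env, rng, n_generations=1) for _ in range(300)])
        var20 = np.var([fitness(s, env, rng, n_generations=20) for _ in range(300)])
        assert var20 < var1 / 5  # expected ratio 1/20

    def test_identical_seeds_identical_results(self):
        env = Environment(n0=250, travel_time=300, p_natal=0.5, cost=0.3)
        s = Strategy(450, 350, 0.6)
        f1 = fitness(s, env, np.random.default_rng(42))
        f2 = fitness(s, env, np.random.default_rng(42))
        assert f1 == f2

    def test_fitness_monotone_in_environment_quality(self, rng):
        """Averaged over replicates, fitness rises with patch quality and
        falls with travel time."""
        s = Strategy(500, 200, 0.7)
        def mean_fit(env):
            return np.mean([fitness(s, env, rng) for _ in range(200)])

        base = dict(p_natal=0.5, cost=0.2)
        assert mean_fit(Environment(n0=1000, travel_time=300, **base)) > mean_fit(
            Environment(n0=25, travel_time=300, **base)
        )
        assert mean_fit(Environment(n0=250, travel_time=100, **base)) > mean_fit(
            Environment(n0=250, travel_time=500, **base)
        )


def test_trajectory_dump_schema():
    env = Environment(n0=100, travel_time=100, p_natal=1.0, cost=0.2)
    traj = simulate_trajectory(Strategy(400, 200, 0.8), env, start_on_patch=True)
    assert list(traj.columns) == [
        "time", "phase", "position", "mu", "eggs_remaining", "progeny",
    ]
    assert len(traj) > 0
    assert traj["progeny"].is_monotonic_increasing
    assert set(traj["phase"]) <= {"foraging", "travelling"}


def test_environment_validation():
    with pytest.raises(ValueError):
        Environment(n0=0, travel_time=100, p_natal=0.5, cost=0.2)
    with pytest.raises(ValueError):
        Environment(n0=100, travel_time=100, p_natal=1.5, cost=0.2)
    with pytest.raises(ValueError):
        Environment(n0=100, travel_time=100, p_natal=0.5, cost=0.2,
                    mvt_reference="psychic")
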