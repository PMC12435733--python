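import math

import numpy as np
import pytest
from scipy import stats

from petolag.engine import (
    SimulationConfig,
    candidate_rates,
    fixation_rate,
    gillespie_draw,
    run,
)
from petolag.lifehistory import optimal_defence
from petolag.mutation import apply_effect


class TestFixationRate:
    def test_neutral_limit_is_mutation_rate(self):
        assert fixation_rate(0.0, 1e4, 1e-3) == pytest.approx(1e-3, rel=1e-9)
        # series regime just off zero
        assert fixation_rate(1e-14, 1e4, 1e-3) == pytest.approx(1e-3, rel=1e-6)

    def test_strongly_beneficial_is_linear_in_s(self):
        ne, m = 1e4, 1e-3
        s = 50 / (4 * ne)
        assert fixation_rate(s, ne, m) == pytest.approx(
            50 * m / (1 - math.exp(-50)), rel=1e-12
        )

    def test_strongly_deleterious_suppressed(self):
        assert fixation_rate(-0.01, 1e6, 1e-3) == 0.0

    def test_monotone_in_s(self):
        s = np.linspace(-5e-4, 5e-4, 101)
        r = fixation_rate(s, 3e4, 1e-3)
        assert np.all(np.diff(r) > 0)


class TestCandidateRates:
    def test_neutral_effects_give_neutral_rates(self, small_env, small_table):
        effects = np.zeros(10)
        rates, d_primes, s = candidate_rates(
            0.4, effects, small_env, 3, 1.0, 1e-3, small_table
        )
        assert rates == pytest.approx(np.full(10, 1e-3), rel=1e-9)
        assert np.all(s == 0)
        assert np.all(d_primes == 0.4)

    def test_all_deleterious_at_optimum(self, small_env, small_table):
        cost = 10 ** -0.1
        d_star, _, _ = optimal_defence(small_env, 3, cost, small_table)
        effects = np.linspace(-0.5, 0.3, 21)
        rates, _, s = candidate_rates(
            d_star, effects, small_env, 3, cost, 1e-3, small_table
        )
        assert np.all(s <= 1e-9)
        assert np.all(rates <= 1e-3 * (1 + 1e-6))

    def test_step_toward_optimum_beats_equal_step_away(self, small_env, small_table):
        # brute-force check on a toy discretization around a suboptimal d
        cost = 10 ** -0.1
        d_star, _, _ = optimal_defence(small_env, 3, cost, small_table)
        d = d_star - 0.2
        for mag in (0.01, 0.05, 0.1):
            toward = apply_effect(d, +mag)  # raises d toward d_star
            away = apply_effect(d, -mag)
            effects = np.array([-mag, +mag])
            rates, dp, _ = candidate_rates(
                d, effects, small_env, 3, cost, 1e-3, small_table
            )
            assert dp[1] == pytest.approx(toward) and dp[0] == pytest.approx(away)
            assert rates[1] > rates[0]


class TestGillespieDraw:
    def test_no_positive_rates_is_sentinel(self, rng):
        winner, tau = gillespie_draw(np.zeros(5), rng)
        assert winner is None and math.isinf(tau)

    def test_single_clock_mean(self, rng):
        taus = []
        for _ in range(10_000):
            winner, tau = gillespie_draw(np.array([0.0, 2.0, 0.0]), rng)
            assert winner == 1
            taus.append(tau)
        mean = np.mean(taus)
        se = np.std(taus, ddof=1) / math.sqrt(len(taus))
        assert abs(mean - 0.5) < 3 * se

    def test_equal_clocks_split_evenly(self, rng):
        wins = np.zeros(2)
        for _ in range(10_000):
            winner, _ = gillespie_draw(np.array([1.0, 1.0]), rng)
            wins[winner] += 1
        se = math.sqrt(10_000 * 0.25)
        assert abs(wins[0] - 5000) < 3 * se

    @pytest.mark.parametrize("mode", ["sum", "literal"])
    def test_winner_frequencies_match_rates(self, rng, mode):
        # competing exponentials: P(win_i) = R_i / sum(R)
        rates = np.array([0.1, 0.5, 1.0, 2.0, 0.2])
        n = 10_000
        counts = np.zeros(len(rates))
        for _ in range(n):
            winner, _ = gillespie_draw(rates, rng, mode=mode)
            counts[winner] += 1
        expected = rates / rates.sum() * n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # dof = 4; 99.9% critical value ~ 18.5
        assert chi2 < stats.chi2.ppf(0.999, len(rates) - 1)

    def test_literal_mode_tau_is_minimum_clock(self, rng):
        rates = np.array([0.5, 0.0, 3.0])
        for _ in range(100):
            winner, tau = gillespie_draw(rates, rng, mode="literal")
            assert winner in (0, 2)
            assert tau > 0 and np.isfinite(tau)


def quick_config(**kw):
    defaults = dict(
        scenario="constant_small",
        mutation_rate=1e-3,
        log10_cost=-0.1,
        n_bins=40,
        seed=3,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestRun:
    def test_zero_mutation_rate_never_fixes(self):
        res = run(quick_config(mutation_rate=0.0))
        assert res.n_fixations == 0
        assert res.final_state.defence == res.d_initial

    def test_time_bookkeeping(self):
        res = run(quick_config())
        assert len(res.snapshots) == 41  # one per bin plus the final state
        assert res.snapshots["time_mya"].iloc[-1] == 0.0
        assert np.all(np.diff(res.snapshots["time_mya"]) < 0)

    def test_starts_at_current_optimum(self, small_env, small_table):
        res = run(quick_config())
        d_star, _, _ = optimal_defence(small_env, 3, 10 ** -0.1, small_table)
        assert res.d_initial == pytest.approx(d_star, abs=1e-9)

    def test_same_seed_identical_runs(self):
        r1 = run(quick_config(mutation_rate=0.1, seed=11))
        r2 = run(quick_config(mutation_rate=0.1, seed=11))
        assert r1.events.equals(r2.events)
        assert r1.snapshots.equals(r2.snapshots)

    def test_different_seeds_differ(self):
        r1 = run(quick_config(mutation_rate=0.1, seed=1))
        r2 = run(quick_config(mutation_rate=0.1, seed=2))
        assert not r1.events.equals(r2.events)

    def test_event_bookkeeping(self):
        res = run(quick_config(mutation_rate=0.1, seed=5))
        assert res.n_fixations > 0
        ev = res.events
        # every logged fixation applies its effect
        expected = apply_effect(ev["d_before"].to_numpy(), ev["delta"].to_numpy())
        assert ev["d_after"].to_numpy() == pytest.approx(expected, abs=1e-12)
        # times decrease and stay within the simulated span
        assert np.all(np.diff(ev["time_mya"]) <= 0)
        assert ev["time_mya"].max() <= res.snapshots["time_mya"].max()

    def test_literal_and_sum_modes_both_run(self):
        r_sum = run(quick_config(mutation_rate=0.05, seed=7, gillespie_mode="sum"))
        r_lit = run(quick_config(mutation_rate=0.05, seed=7, gillespie_mode="literal"))
        assert r_sum.n_fixations > 0 and r_lit.n_fixations > 0

    def test_flight_reduces_mortality_by_exactly_r(self):
        # miniaturisation run crossing the flight date: snapshots after the
        # switch carry mu multiplied by exactly r at the same (constant) mass
        n_bins = 200
        bin_width = 60000.0
        span = n_bins * bin_width  # 12 My, within the constant-mass era
        flight_time = span / 2
        res = run(
            SimulationConfig(
                scenario="miniaturisation",
                mutation_rate=0.0,
                log10_cost=-0.1,
                flighted=True,
                flight_time=flight_time,
                r=1 / 3,
                n_bins=n_bins,
                bin_width=bin_width,
                seed=0,
            )
        )
        snaps = res.snapshots
        before = snaps[snaps["time_mya"] * 1e6 > flight_time]
        after = snaps[snaps["time_mya"] * 1e6 <= flight_time]
        assert len(before) and len(after)
        mu_before = before["mu"].unique()
        mu_after = after["mu"].unique()
        assert len(mu_before) == 1 and len(mu_after) == 1
        assert mu_after[0] == pytest.approx(mu_before[0] / 3, rel=1e-12)

    def test_flight_rejected_outside_miniaturisation(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                scenario="constant_large",
                mutation_rate=0.0,
                log10_cost=-0.1,
                flighted=True,
            )

    def test_state_cache_coherence(self, small_env, small_table):
        # recomputing L and W from the snapshot defence levels reproduces the
        # cached values
        res = run(quick_config(mutation_rate=0.1, seed=9))
        cost = 10 ** -0.1
        for _, row in res.snapshots.iterrows():
            L = float(small_table(row["defence"]))
            W = float(small_table.fitness(row["defence"], cost))
            assert row["lifespan_y"] == pytest.approx(L, rel=1e-9)
            assert row["fitness"] == pytest.approx(W, rel=1e-9)

    def test_custom_effects_two_category(self):
        res = run(
            quick_config(
                mutation_rate=1e-4,
                custom_effects=(-1e-9, 1e-9),
                seed=21,
            )
        )
        # effectively neutral categories: substitutions occur, defence barely moves
        assert abs(res.final_state.defence - res.d_initial) < 1e-6
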