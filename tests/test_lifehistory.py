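import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petolag.allometry import make_environment
from petolag.lifehistory import (
    LifeHistoryParams,
    LifespanTable,
    age_at_cancerfree_quantile,
    cancer_death_cdf,
    expected_lifespan,
    extrinsic_death_cdf,
    fitness,
    optimal_defence,
    params_for,
    prob_cancer_death,
    selection_coefficient,
    simulate_death_times,
    survival,
)


def params(n_cells=3.72e13, n_steps=3, k=1e-4, d=0.9, mu=0.17, cost=1.0):
    return LifeHistoryParams(n_cells, n_steps, k, d, mu, cost)


class TestCancerDeathCdf:
    def test_full_defence_abolishes_cancer(self):
        p = params(d=1.0)
        assert cancer_death_cdf(123.0, p) == 0.0

    def test_zero_at_birth(self):
        assert cancer_death_cdf(0.0, params()) == 0.0

    def test_single_cell_single_step_reduction(self):
        # one cell, one step: C(t) = 1 - exp(-k t)
        p = params(n_cells=1, n_steps=1, d=0.0, k=1e-4)
        assert cancer_death_cdf(10000.0, p) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_monotone_in_age(self):
        p = params(d=0.5)
        t = np.linspace(0, 200, 100)
        c = cancer_death_cdf(t, p)
        assert np.all(np.diff(c) >= 0)
        assert np.all((c >= 0) & (c <= 1))

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            cancer_death_cdf(-1.0, params())


class TestSurvivalPieces:
    def test_extrinsic_cdf(self):
        p = params(mu=0.1653)
        assert extrinsic_death_cdf(0.0, p) == 0.0
        assert extrinsic_death_cdf(1 / 0.1653, p) == pytest.approx(1 - math.exp(-1))

    def test_survival_is_product_of_complements(self):
        p = params(d=0.5)
        t = np.linspace(0, 100, 50)
        expected = (1 - extrinsic_death_cdf(t, p)) * (1 - cancer_death_cdf(t, p))
        assert survival(t, p) == pytest.approx(expected, rel=1e-12)

    def test_survival_bounds(self):
        p = params(d=0.3)
        assert survival(0.0, p) == 1.0
        t = np.linspace(0.0, 60, 40)
        s = survival(t, p)
        assert np.all(np.diff(s) <= 0)
        assert np.all(s <= np.minimum(1 - extrinsic_death_cdf(t, p) + 1e-15,
                                      1 - cancer_death_cdf(t, p) + 1e-15))

    def test_full_defence_is_pure_exponential(self):
        p = params(d=1.0, mu=0.2)
        t = np.linspace(0, 40, 20)
        assert survival(t, p) == pytest.approx(np.exp(-0.2 * t), rel=1e-12)


class TestQuantileAge:
    @pytest.mark.parametrize("P", [0.1, 0.5, 0.9])
    def test_inverts_cancerfree_survival(self, P):
        p = params(d=0.7)
        t = age_at_cancerfree_quantile(P, p)
        assert 1.0 - cancer_death_cdf(t, p) == pytest.approx(P, abs=1e-9)

    def test_single_cell_single_step_closed_form(self):
        p = params(n_cells=1, n_steps=1, d=0.4, k=1e-3)
        lam = 0.6e-3
        for P in (0.2, 0.8):
            assert age_at_cancerfree_quantile(P, p) == pytest.approx(
                -math.log(P) / lam, rel=1e-12
            )

    def test_later_ages_have_lower_survival(self):
        p = params(d=0.5)
        assert age_at_cancerfree_quantile(0.9, p) < age_at_cancerfree_quantile(0.1, p)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            age_at_cancerfree_quantile(0.0, params())
        with pytest.raises(ValueError):
            age_at_cancerfree_quantile(0.5, params(d=1.0))


CLOSED_FORM_GRID = [
    (mu, d, k)
    for mu in (0.05, 0.17, 0.5)
    for d in (0.0, 0.5, 0.9, 0.99)
    for k in (1e-4, 1e-2, 1.0)
]


class TestLifespan:
    @pytest.mark.parametrize("mu,d,k", CLOSED_FORM_GRID)
    def test_single_cell_single_step_closed_form(self, mu, d, k):
        # two competing exponentials: L = 1/(mu + (1-d)k)
        p = params(n_cells=1, n_steps=1, d=d, k=k, mu=mu)
        lam = (1 - d) * k
        assert expected_lifespan(p) == pytest.approx(1 / (mu + lam), rel=1e-9)

    def test_full_defence_limit(self):
        p = params(d=1.0, mu=0.25)
        assert expected_lifespan(p) == pytest.approx(4.0, rel=1e-12)

    def test_quantile_and_time_domain_quadratures_agree(self, small_env, large_env):
        for env in (small_env, large_env):
            for n in (1, 3, 5):
                for d in (0.0, 0.5, 0.9, 0.99):
                    p = params_for(env, n, 1.0, d)
                    lq = expected_lifespan(p, "quantile")
                    lt = expected_lifespan(p, "time")
                    assert lq == pytest.approx(lt, rel=1e-6)

    def test_increasing_in_defence_and_bounded(self, small_env):
        ds = np.linspace(0.0, 0.999, 25)
        ls = [expected_lifespan(params_for(small_env, 3, 1.0, d)) for d in ds]
        assert np.all(np.diff(ls) > 0)
        assert max(ls) <= 1 / small_env.extrinsic_mortality + 1e-12


class TestProbCancerDeath:
    @pytest.mark.parametrize("mu,d,k", CLOSED_FORM_GRID)
    def test_single_cell_single_step_closed_form(self, mu, d, k):
        p = params(n_cells=1, n_steps=1, d=d, k=k, mu=mu)
        lam = (1 - d) * k
        assert prob_cancer_death(p) == pytest.approx(lam / (mu + lam), rel=1e-9)

    def test_full_defence_never_dies_of_cancer(self):
        assert prob_cancer_death(params(d=1.0)) == 0.0

    def test_complements_extrinsic_death_probability(self, small_env, large_env):
        # P(cancer death) + P(extrinsic death) = 1, and the extrinsic share
        # is mu * L for a constant extrinsic hazard
        for env in (small_env, large_env):
            for d in (0.0, 0.6, 0.95):
                p = params_for(env, 3, 1.0, d)
                pcel = prob_cancer_death(p)
                assert pcel == pytest.approx(
                    1 - env.extrinsic_mortality * expected_lifespan(p), abs=1e-7
                )

    def test_decreasing_in_defence(self, small_env):
        ds = np.linspace(0.0, 0.99, 15)
        ps = [prob_cancer_death(params_for(small_env, 3, 1.0, d)) for d in ds]
        assert np.all(np.diff(ps) < 0)


class TestFitness:
    def test_boundary_values(self, small_env):
        p0 = params_for(small_env, 3, 0.5, 0.0)
        assert fitness(p0) == pytest.approx(expected_lifespan(p0), rel=1e-12)
        assert fitness(params_for(small_env, 3, 0.5, 1.0)) == 0.0

    def test_vanishing_cost_makes_defence_free(self, small_env):
        # c -> 0+: d^(1/c) -> 0 for d < 1, so W -> L
        p = params_for(small_env, 3, 1e-6, 0.9)
        assert fitness(p) == pytest.approx(expected_lifespan(p), rel=1e-9)


class TestOptimalDefence:
    def test_low_cost_large_body_optimum_near_one(self, large_env):
        d_star, _, _ = optimal_defence(large_env, 3, 10 ** -4.1)
        assert d_star > 0.99

    def test_small_body_has_lower_optimum_at_high_cost(self, small_env, large_env):
        d_small, _, _ = optimal_defence(small_env, 3, 10 ** -0.1)
        d_large, _, _ = optimal_defence(large_env, 3, 10 ** -0.1)
        assert d_small < d_large

    def test_matches_brute_force_grid(self, small_env, small_table):
        cost = 10 ** -0.1
        d_star, w_max, _ = optimal_defence(small_env, 3, cost, small_table)
        grid = np.linspace(0.0, 1.0, 100001)
        w_grid = small_table.fitness(grid, cost)
        d_brute = grid[np.argmax(w_grid)]
        assert d_star == pytest.approx(d_brute, abs=1e-3)
        assert w_max >= w_grid.max() - 1e-12

    def test_weakly_decreasing_in_cost(self, small_env, small_table):
        costs = 10.0 ** np.linspace(-4.1, -0.1, 9)
        d_stars = [optimal_defence(small_env, 3, c, small_table)[0] for c in costs]
        assert np.all(np.diff(d_stars) <= 1e-9)


class TestSelectionCoefficient:
    def test_same_level_is_neutral(self, small_env):
        assert selection_coefficient(0.5, 0.5, small_env, 3, 1.0) == 0.0

    def test_moving_to_optimum_is_beneficial(self, small_env, small_table):
        cost = 10 ** -0.1
        d_star, _, _ = optimal_defence(small_env, 3, cost, small_table)
        s = selection_coefficient(0.9, d_star, small_env, 3, cost, lifespan_fn=small_table)
        assert s > 0

    def test_reverse_coefficient_identity(self, small_env, small_table):
        # s(a->b) = -s(b->a) * W(b)/W(a)
        cost, a, b = 0.5, 0.3, 0.6
        s_ab = selection_coefficient(a, b, small_env, 3, cost, lifespan_fn=small_table)
        s_ba = selection_coefficient(b, a, small_env, 3, cost, lifespan_fn=small_table)
        w_a = small_table.fitness(a, cost)
        w_b = small_table.fitness(b, cost)
        assert s_ab == pytest.approx(-s_ba * w_b / w_a, rel=1e-9)

    def test_zero_fitness_resident_rejected(self, small_env):
        with pytest.raises(ValueError):
            selection_coefficient(1.0, 0.5, small_env, 3, 1.0)


class TestLifespanTable:
    def test_matches_adaptive_quadrature(self, small_env, small_table):
        for d in (0.0, 0.37, 0.9, 0.999, 0.999999):
            p = params_for(small_env, 3, 1.0, d)
            assert small_table(d) == pytest.approx(expected_lifespan(p), rel=1e-6)

    def test_saturates_at_extrinsic_limit(self, small_env, small_table):
        assert small_table(1.0) == pytest.approx(
            1 / small_env.extrinsic_mortality, rel=1e-9
        )


class TestMonteCarloOracle:
    N_DRAWS = 100_000

    def test_full_defence_only_extrinsic_deaths(self, small_env):
        p = params_for(small_env, 3, 1.0, 1.0)
        ages, is_cancer = simulate_death_times(p, 2000, seed=5)
        assert not np.any(is_cancer)

    def test_mean_age_matches_expected_lifespan(self, large_env):
        p = params_for(large_env, 3, 1.0, 0.9)
        ages, _ = simulate_death_times(p, self.N_DRAWS, seed=11)
        se = ages.std(ddof=1) / math.sqrt(self.N_DRAWS)
        assert abs(ages.mean() - expected_lifespan(p)) < 3 * se

    def test_cancer_fraction_matches_pcel(self, large_env):
        p = params_for(large_env, 3, 1.0, 0.9)
        _, is_cancer = simulate_death_times(p, self.N_DRAWS, seed=12)
        pcel = prob_cancer_death(p)
        se = math.sqrt(pcel * (1 - pcel) / self.N_DRAWS)
        assert abs(is_cancer.mean() - pcel) < 3 * se

    def test_survival_curve_sup_norm(self, large_env):
        # empirical CDF vs model: DKW-style bound at 1e5 draws
        p = params_for(large_env, 3, 1.0, 0.9)
        ages, _ = simulate_death_times(p, self.N_DRAWS, seed=13)
        ages_sorted = np.sort(ages)
        ecdf = np.arange(1, len(ages) + 1) / len(ages)
        model = 1.0 - survival(ages_sorted, p)
        assert np.max(np.abs(ecdf - model)) < 0.01

    def test_reproducible_under_fixed_seed(self, small_env):
        p = params_for(small_env, 3, 1.0, 0.5)
        a1, c1 = simulate_death_times(p, 100, seed=42)
        a2, c2 = simulate_death_times(p, 100, seed=42)
        assert np.array_equal(a1, a2) and np.array_equal(c1, c2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    d=st.floats(0.0, 0.99),
    n=st.integers(1, 5),
    log_mu=st.floats(-2.0, 0.0),
)
def test_lifespan_between_cancer_only_and_extrinsic_only(d, n, log_mu):
    """L always lies below the extrinsic-only bound 1/mu."""
    mu = 10.0**log_mu
    p = LifeHistoryParams(1e10, n, 1e-4, d, mu, 1.0)
    L = expected_lifespan(p)
    assert 0 < L <= 1 / mu + 1e-9
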