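"""Deterministic life-history core: cancer risk, lifespan, fitness, optima.

The model couples two independent ways to die:

* **Cancer** follows a multistage (Armitage–Doll style) process: each of the
  body's ``N`` cells must complete ``n`` oncogenic steps, each step occurring
  at an effective rate ``(1-d)*k`` per year, where ``d`` in [0, 1] is the
  evolvable level of cancer defences.  The probability of having died from
  cancer by age ``t`` is

      C(t) = 1 - (1 - (1 - exp(-(1-d) k t))^n)^N.

* **Extrinsic mortality** is a constant hazard ``mu`` per year,
  ``E(t) = 1 - exp(-mu t)``.

Being alive at age ``t`` requires escaping both: ``P(t) = (1-E(t))(1-C(t))``.
The expected lifespan is ``L(d) = E[min(T_cancer, T_ext)] = int_0^inf P(t) dt``,
evaluated either directly in the time domain or in the quantile domain through
the cancer-free survival quantile function

      t(P, d) = -ln(1 - (1 - P^(1/N))^(1/n)) / ((1-d) k),

the age at which the probability of still being cancer-free equals ``P``.

Fitness is lifetime reproductive success under a defence-fecundity trade-off,
``W(d) = L(d) * (1 - d^(1/c))`` with cost parameter ``c > 0``: stronger
defences lengthen life but depress reproduction per unit time.  The
probability that cancer (rather than extrinsic mortality) ends life,
``pCEL = int_0^inf (1-E(t)) dC(t)``, is the competing-risks integral, which in
the quantile domain is exactly ``int_0^1 (1-E(t(P,d))) dP``.

Numerical safety at N ~ 3.7e13 requires log1p/expm1 throughout: ``(1-x)^N``
is computed as ``exp(N*log1p(-x))`` and ``1 - P^(1/N)`` as
``-expm1(log(P)/N)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.interpolate import CubicSpline

from .allometry import Environment

__all__ = [
    "LifeHistoryParams",
    "LifeHistorySummary",
    "LifespanTable",
    "cancer_death_cdf",
    "extrinsic_death_cdf",
    "survival",
    "age_at_cancerfree_quantile",
    "expected_lifespan",
    "fecundity_factor",
    "fitness",
    "optimal_defence",
    "selection_coefficient",
    "prob_cancer_death",
    "simulate_death_times",
    "params_for",
]


@dataclass(frozen=True)
class LifeHistoryParams:
    """Arguments of the survival model plus the trade-off cost.

    n_cells
        Number of cells N at risk (>= 1).
    n_steps
        Number of oncogenic steps n a cell lineage must complete (>= 1).
    onco_rate
        Baseline per-step rate k (per year) before defences scale it down.
    defence
        Cancer defence level d in [0, 1]; the effective step rate is (1-d)k.
    extrinsic_mortality
        Constant extrinsic hazard mu (per year).
    cost
        Trade-off strength c > 0 in the fecundity factor 1 - d^(1/c).
    """

    n_cells: float
    n_steps: int
    onco_rate: float
    defence: float
    extrinsic_mortality: float
    cost: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ValueError("n_steps must be an integer >= 1")
        if not 0.0 <= self.defence <= 1.0:
            raise ValueError("defence must lie in [0, 1]")
        if self.onco_rate <= 0:
            raise ValueError("onco_rate must be positive")
        if self.extrinsic_mortality <= 0:
            raise ValueError("extrinsic_mortality must be positive")
        if self.cost <= 0:
            raise ValueError("cost must be positive")

    @property
    def effective_rate(self) -> float:
        """Effective per-step oncogenic rate (1-d)k."""
        return (1.0 - self.defence) * self.onco_rate


@dataclass(frozen=True)
class LifeHistorySummary:
    """Derived life-history quantities for one parameter set."""

    lifespan: float
    fitness: float
    p_cancer_death: float


def params_for(
    env: Environment, n_steps: int, cost: float, defence: float
) -> LifeHistoryParams:
    """Life-history parameters for a defence level in a given environment."""
    return LifeHistoryParams(
        n_cells=env.n_cells,
        n_steps=n_steps,
        onco_rate=env.onco_rate,
        defence=defence,
        extrinsic_mortality=env.extrinsic_mortality,
        cost=cost,
    )


def _check_nonneg_time(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("age t must be non-negative")
    return arr


def _log_cancerfree_survival(t, lam: float, n_cells: float, n_steps: int):
    """log of (1 - C(t)) = N * log1p(-q^n) with q = 1 - exp(-lam t)."""
    q = -np.expm1(-lam * np.asarray(t, dtype=float))
    with np.errstate(divide="ignore"):
        return n_cells * np.log1p(-(q**n_steps))


def cancer_death_cdf(t, params: LifeHistoryParams):
    """Probability of having died from cancer by age ``t``."""
    arr = _check_nonneg_time(t)
    lam = params.effective_rate
    if lam == 0.0:
        out = np.zeros_like(arr)
    else:
        out = -np.expm1(
            _log_cancerfree_survival(arr, lam, params.n_cells, params.n_steps)
        )
    return float(out) if np.isscalar(t) else out


def extrinsic_death_cdf(t, params: LifeHistoryParams):
    """Probability of having died from extrinsic causes by age ``t``."""
    arr = _check_nonneg_time(t)
    out = -np.expm1(-params.extrinsic_mortality * arr)
    return float(out) if np.isscalar(t) else out


def survival(t, params: LifeHistoryParams):
    """Probability of being alive at age ``t``: (1-E(t)) (1-C(t))."""
    arr = _check_nonneg_time(t)
    lam = params.effective_rate
    log_sc = (
        0.0
        if lam == 0.0
        else _log_cancerfree_survival(arr, lam, params.n_cells, params.n_steps)
    )
    out = np.exp(-params.extrinsic_mortality * arr + log_sc)
    return float(out) if np.isscalar(t) else out


def age_at_cancerfree_quantile(P, params: LifeHistoryParams):
    """Age at which the probability of still being cancer-free equals ``P``.

    Inverts the cancer-free part of the survival model:
    ``1 - cancer_death_cdf(t(P, d)) = P``.
    """
    arr = np.asarray(P, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("quantile level P must lie strictly inside (0, 1)")
    lam = params.effective_rate
    if lam == 0.0:
        raise ValueError("defence = 1 makes every cancer-free age infinite")
    one_m_a = -np.expm1(np.log(arr) / params.n_cells)  # 1 - P^(1/N)
    q = one_m_a ** (1.0 / params.n_steps)
    out = -np.log1p(-q) / lam
    return float(out) if np.isscalar(P) else out


# ---------------------------------------------------------------------------
# Lifespan quadratures
# ---------------------------------------------------------------------------


def _neg_log1m_root(c: float, n_cells: float, n_steps: int) -> float:
    """-ln(1-q) for q = (-expm1(-c/N))^(1/n), stable when q is close to 1."""
    z = c / n_cells
    if z > 30.0:  # 1-q ~ exp(-z)/n underflows the direct route
        return z + math.log(n_steps)
    q = (-math.expm1(-z)) ** (1.0 / n_steps)
    return -math.log1p(-q)


def _time_scales(lam: float, mu: float, n_cells: float, n_steps: int):
    """Characteristic onset scale and an upper cutoff for the survival integrand."""
    # age at which the expected number of fully transformed cells is ~1
    t_cancer = _neg_log1m_root(1.0, n_cells, n_steps) / lam
    t_scale = min(1.0 / mu, t_cancer)
    # age by which the cancer-free survival has fallen below e^-45
    t_hi = min(46.0 / mu, _neg_log1m_root(45.0, n_cells, n_steps) / lam)
    return t_scale, t_hi


def _lifespan_integrand_time(t, lam, mu, n_cells, n_steps):
    return np.exp(-mu * t + _log_cancerfree_survival(t, lam, n_cells, n_steps))


def _lifespan_quad_time(params: LifeHistoryParams) -> float:
    lam, mu = params.effective_rate, params.extrinsic_mortality
    t_scale, t_hi = _time_scales(lam, mu, params.n_cells, params.n_steps)
    pts = sorted({min(t_scale, t_hi), min(10.0 * t_scale, t_hi)})
    val, _ = integrate.quad(
        _lifespan_integrand_time,
        0.0,
        t_hi,
        args=(lam, mu, params.n_cells, params.n_steps),
        points=pts,
        limit=300,
        epsabs=1e-300,
        epsrel=1e-11,
    )
    return val


_V_HI = 60.0  # log-survival cutoff: cancer-free survival below e^-60 is negligible


def _quantile_age_from_v(v, lam, n_cells, n_steps):
    """Cancer-free quantile age t at survival level u = exp(-v)."""
    z = np.asarray(v, dtype=float) / n_cells
    one_m_a = -np.expm1(-z)  # 1 - u^(1/N)
    q = one_m_a ** (1.0 / n_steps)
    with np.errstate(divide="ignore"):
        neg_log1m_q = -np.log1p(-q)
    # when q has rounded to 1, use 1 - q ~ exp(-z)/n
    neg_log1m_q = np.where(z > 30.0, z + math.log(n_steps), neg_log1m_q)
    return neg_log1m_q / lam, one_m_a


def _lifespan_integrand_quantile(v, lam, mu, n_cells, n_steps):
    """Integrand of L over the log cancer-free-survival level v = -ln(u).

    L = int_0^1 (1 - E(t(u))) * u * |t'(u)| du with t(u) the cancer-free
    quantile age; the Jacobian collapses to
    exp((lam-mu) t) * u^(1/N) * (1 - u^(1/N))^(1/n - 1) / (lam n N),
    and the log-level substitution u = exp(-v) keeps the near-u=1 region
    (where almost all mass sits when cancer is rare) representable.
    """
    v = np.asarray(v, dtype=float)
    t, one_m_a = _quantile_age_from_v(v, lam, n_cells, n_steps)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h = (
            (lam - mu) * t
            - v / n_cells
            - v
            + (1.0 / n_steps - 1.0) * np.log(one_m_a)
            - math.log(lam * n_steps * n_cells)
        )
    return np.exp(log_h)


def _quantile_points(lam, mu, n_cells, n_steps):
    """Interior quadrature breakpoints bracketing the concentration scales.

    The integrand mass sits near the log-survival level reached at the
    extrinsic timescale 1/mu (and near 1, the level at the cancer onset
    scale); a geometric ladder of breakpoints around both keeps QUADPACK from
    overlooking mass concentrated many orders of magnitude below the
    integration range.
    """
    v_mu = -float(_log_cancerfree_survival(1.0 / mu, lam, n_cells, n_steps))
    v_mu = min(max(v_mu, 1e-280), _V_HI)
    pts = {1.0, 0.1, 10.0}
    # the age->level map compresses by the power n_steps, so cover a wide ladder
    pts.update(v_mu * 10.0 ** np.arange(-3.0 * n_steps, 2.0 * n_steps + 1.0))
    return sorted(p for p in pts if 0.0 < p < _V_HI)


def _lifespan_quad_quantile(params: LifeHistoryParams) -> float:
    lam, mu = params.effective_rate, params.extrinsic_mortality
    n_cells, n_steps = params.n_cells, params.n_steps
    # substitute v = y^n: the v^(1/n - 1) endpoint singularity of the
    # Jacobian becomes regular, restoring full adaptive-quadrature accuracy
    root = 1.0 / n_steps

    def integrand(y):
        v = y**n_steps
        return (
            _lifespan_integrand_quantile(v, lam, mu, n_cells, n_steps)
            * n_steps
            * y ** (n_steps - 1)
        )

    pts = [p**root for p in _quantile_points(lam, mu, n_cells, n_steps)]
    val, _ = integrate.quad(
        integrand,
        0.0,
        _V_HI**root,
        points=pts,
        limit=400,
        epsabs=1e-300,
        epsrel=1e-10,
    )
    return val


def expected_lifespan(params: LifeHistoryParams, method: str = "quantile") -> float:
    """Expected lifespan L(d) in years, by adaptive quadrature.

    ``method="quantile"`` integrates over the cancer-free survival level using
    the quantile age t(P, d); ``method="time"`` integrates P(t) over age.  The
    two agree to ~1e-9 relative and both reduce to 1/(mu + (1-d)k) when
    N = n = 1.  At d = 1 the limit 1/mu (extrinsic mortality only) is returned.
    """
    if params.defence == 1.0 or params.effective_rate == 0.0:
        return 1.0 / params.extrinsic_mortality
    if method == "time":
        return _lifespan_quad_time(params)
    if method == "quantile":
        return _lifespan_quad_quantile(params)
    raise ValueError(f"unknown method {method!r}")


def prob_cancer_death(params: LifeHistoryParams, method: str = "quantile") -> float:
    """Probability that cancer (not extrinsic mortality) ends life (pCEL).

    Competing-risks integral ``int_0^inf (1-E(t)) dC(t)``; in the quantile
    domain this is exactly ``int_0^1 exp(-mu * t(u, d)) du``.
    """
    if params.defence == 1.0 or params.effective_rate == 0.0:
        return 0.0
    lam, mu = params.effective_rate, params.extrinsic_mortality
    n_cells, n_steps = params.n_cells, params.n_steps
    if method == "quantile":

        def integrand(v):
            t, _ = _quantile_age_from_v(v, lam, n_cells, n_steps)
            return np.exp(-mu * t - v)

        val, _ = integrate.quad(
            integrand,
            0.0,
            _V_HI,
            points=_quantile_points(lam, mu, n_cells, n_steps),
            limit=300,
            epsabs=1e-300,
            epsrel=1e-11,
        )
        return val
    if method == "time":
        t_scale, t_hi = _time_scales(lam, mu, n_cells, n_steps)

        def integrand(t):
            # (1-E(t)) * C'(t) in log space
            q = -np.expm1(-lam * t)
            with np.errstate(divide="ignore"):
                log_f = -mu * t + np.log(n_cells * n_steps * lam) + np.log1p(-q)
                if n_cells > 1:  # avoid 0 * log(0) when the factor vanishes
                    log_f = log_f + (n_cells - 1.0) * np.log1p(-(q**n_steps))
                if n_steps > 1:
                    log_f = log_f + (n_steps - 1.0) * np.log(q)
            return np.exp(log_f)

        val, _ = integrate.quad(
            integrand,
            0.0,
            t_hi,
            points=sorted({min(t_scale, t_hi), min(10 * t_scale, t_hi)}),
            limit=300,
            epsabs=1e-300,
            epsrel=1e-11,
        )
        return val
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Fitness and optima
# ---------------------------------------------------------------------------


def fecundity_factor(defence: float, cost: float):
    """Reproductive-success factor 1 - d^(1/c) of the defence trade-off."""
    d = np.asarray(defence, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(d == 0.0, 1.0, -np.expm1(np.log(np.maximum(d, 1e-320)) / cost))
    out = np.where(d == 1.0, 0.0, out)
    return float(out) if np.isscalar(defence) else out


def fitness(params: LifeHistoryParams) -> float:
    """Lifetime reproductive success W(d) = L(d) * (1 - d^(1/c))."""
    factor = fecundity_factor(params.defence, params.cost)
    if factor == 0.0:
        return 0.0
    return expected_lifespan(params) * factor


def selection_coefficient(
    d_from: float,
    d_to: float,
    env: Environment,
    n_steps: int,
    cost: float,
    lifespan_fn=None,
) -> float:
    """Selection coefficient s = (W(d') - W(d)) / W(d) of a defence change."""

    def w_of(d: float) -> float:
        if lifespan_fn is not None:
            return float(lifespan_fn(d)) * float(fecundity_factor(d, cost))
        return fitness(params_for(env, n_steps, cost, d))

    w_from = w_of(d_from)
    if w_from <= 0.0:
        raise ValueError("selection coefficient undefined where resident fitness is zero")
    return (w_of(d_to) - w_from) / w_from


class LifespanTable:
    """Fast L(d) evaluator for a fixed environment.

    Backed by a fixed composite Gauss-Legendre quadrature of
    ``int_0^inf exp(-mu t) (1-C(t)) dt`` in log-age, tabulated on a grid of
    ``log10(1-d)`` and interpolated with a cubic spline.  Relative accuracy
    against the adaptive quadrature is ~1e-9, at ~10^4 x the speed for
    vectorised queries; this is what the substitution engine and the optimum
    search use.  For ``1-d`` below the grid floor, L has saturated at the
    extrinsic-only limit 1/mu to well below the interpolation error.
    """

    #: grid resolution in log10(1-d); 601 points over 12 decades
    N_GRID = 601
    X_MIN = -12.0
    N_PANELS = 28
    GL_NODES = 8

    def __init__(
        self,
        env: Environment,
        n_steps: int,
        n_grid: int | None = None,
    ) -> None:
        self.env = env
        self.n_steps = int(n_steps)
        self.mu = env.extrinsic_mortality
        self.k = env.onco_rate
        n_grid = n_grid or self.N_GRID
        x = np.linspace(self.X_MIN, 0.0, n_grid)  # log10(1-d), ascending
        lam = self.k * 10.0**x
        L = self._quad_vectorised(lam)
        self._spline = CubicSpline(x, L, bc_type="natural")
        self._l_max = 1.0 / self.mu

    def _quad_vectorised(self, lam: np.ndarray) -> np.ndarray:
        mu, N, n = self.mu, self.env.n_cells, self.n_steps
        lam = np.asarray(lam, dtype=float)
        nlq1 = _neg_log1m_root(1.0, N, n)
        nlq45 = _neg_log1m_root(45.0, N, n)
        t_scale = np.minimum(1.0 / mu, nlq1 / lam)
        t_hi = np.minimum(46.0 / mu, nlq45 / lam)
        t_lo = 1e-7 * t_scale
        # per-lam geometric panels in age, Gauss-Legendre within each
        edges = np.exp(
            np.linspace(np.log(t_lo), np.log(t_hi), self.N_PANELS + 1, axis=-1)
        )  # (n_lam, P+1)
        xg, wg = np.polynomial.legendre.leggauss(self.GL_NODES)
        mid = 0.5 * (edges[:, 1:] + edges[:, :-1])  # (n_lam, P)
        half = 0.5 * (edges[:, 1:] - edges[:, :-1])
        t = mid[:, :, None] + half[:, :, None] * xg  # (n_lam, P, G)
        q = -np.expm1(-lam[:, None, None] * t)
        f = np.exp(-mu * t + N * np.log1p(-(q**n)))
        integral = np.einsum("ijk,k,ij->i", f, wg, half)
        # the [0, t_lo] sliver where the integrand is 1 to within ~1e-7
        return integral + t_lo

    def __call__(self, d):
        """Lifespan at defence level(s) ``d`` (scalar or array)."""
        darr = np.asarray(d, dtype=float)
        one_m_d = 1.0 - darr
        with np.errstate(divide="ignore"):
            x = np.where(one_m_d > 0, np.log10(np.maximum(one_m_d, 1e-320)), -np.inf)
        out = np.where(x < self.X_MIN, self._l_max, self._spline(np.maximum(x, self.X_MIN)))
        return float(out) if np.isscalar(d) else out

    def fitness(self, d, cost: float):
        """W(d) from the tabulated lifespan and the exact fecundity factor."""
        return self(d) * fecundity_factor(d, cost)

    def fitness_batch(self, d: np.ndarray, cost: float) -> np.ndarray:
        """W over an array of defence levels, assuming every d < 1.

        Lean inner-loop path for the substitution engine (skips the d = 1
        special-casing of the public methods).
        """
        x = np.log10(1.0 - d)
        np.maximum(x, self.X_MIN, out=x)
        L = self._spline(x)
        with np.errstate(divide="ignore"):
            f = -np.expm1(np.log(d) / cost)  # d = 0 gives exactly 1
        return L * f


def optimal_defence(
    env: Environment,
    n_steps: int,
    cost: float,
    table: LifespanTable | None = None,
) -> tuple[float, float, float]:
    """Fitness-maximising defence level.

    Returns ``(d_star, w_max, l_star)``.  Coarse scan first (uniform grid on
    [0, 1] plus a geometric tail resolving 1-d down to 1e-9, since W can be
    extremely flat near 1 at small cost), then bounded scalar refinement in
    the bracketing interval; ties break toward the smaller d.
    """
    if table is None:
        table = LifespanTable(env, n_steps)
    d_grid = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, 1.0, 2001),
                1.0 - 10.0 ** np.linspace(-9.0, -0.31, 200),
            ]
        )
    )
    w = table.fitness(d_grid, cost)
    i = int(np.argmax(w))  # first (= smallest d) maximiser on ties
    lo = d_grid[max(i - 1, 0)]
    hi = d_grid[min(i + 1, len(d_grid) - 1)]
    res = optimize.minimize_scalar(
        lambda d: -table.fitness(d, cost),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    d_star = float(res.x) if -res.fun >= w[i] else float(d_grid[i])
    w_max = float(table.fitness(d_star, cost))
    l_star = float(table(d_star))
    return d_star, w_max, l_star


def simulate_death_times(
    params: LifeHistoryParams, n_draws: int, seed: int | np.random.Generator = 0
):
    """Monte-Carlo oracle: draw death ages and causes for ``n_draws`` individuals.

    Cancer ages are drawn by inverting the cancer-free survival at a uniform
    variate; extrinsic ages are exponential with rate mu.  Returns
    ``(ages, is_cancer)`` arrays.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = rng.uniform(size=n_draws)
    if params.effective_rate == 0.0:
        t_cancer = np.full(n_draws, np.inf)
    else:
        t_cancer = age_at_cancerfree_quantile(u, params)
    t_ext = rng.exponential(scale=1.0 / params.extrinsic_mortality, size=n_draws)
    ages = np.minimum(t_cancer, t_ext)
    return ages, t_cancer < t_ext


def summarize(params: LifeHistoryParams) -> LifeHistorySummary:
    """Lifespan, fitness and cancer-death probability for one parameter set."""
    return LifeHistorySummary(
        lifespan=expected_lifespan(params),
        fitness=fitness(params),
        p_cancer_death=prob_cancer_death(params),
    )
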