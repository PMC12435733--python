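"""Numba-compiled inner loop of the substitution engine.

Implements exactly the per-category mathematics of
:func:`petolag.engine.candidate_rates` — W(d') through the environment's
lifespan spline, the fecundity trade-off factor, and Kimura's
origin-fixation rate — inside the within-bin Gillespie loop, with two
purely numerical accelerations:

* **rate cutoff**: categories with 4*Ne*s below ``X_CUT`` (= -40) carry
  relative fixation rates under e^-40 ~ 4e-18 and are treated as zero;
* **active window**: category effects are sorted, so the candidate defence
  levels d'_i are monotone in the category index and the above-cutoff set is
  (for a single-peaked fitness profile) a contiguous index window.  The
  window is re-derived by a full 1000-category scan on every bin entry and
  every ``RESCAN_EVERY`` fixations, and updated incrementally in between by
  recomputing a margin around the previous window and expanding outward
  while the edge categories remain above the cutoff.

Clamp-atom categories (delta = -1, all mapping to d' = 0) are lumped into a
single rate block.  Randomness uses numba's global MT19937 state, seeded
once per run; given a seed the event sequence is fully reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

X_CUT = -40.0  # cutoff on 4 Ne s below which fixation rates are treated as 0
RESCAN_EVERY = 64  # full-category rescan cadence (in fixations)
MARGIN = 8  # window margin recomputed on incremental updates


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _lifespan(x, x0, dx, c0, c1, c2, c3, n_int):
    """Uniform-knot cubic spline for L at x = log10(1 - d), clipped at x0."""
    if x < x0:
        x = x0
    i = int((x - x0) / dx)
    if i > n_int - 1:
        i = n_int - 1
    t = x - (x0 + i * dx)
    return ((c0[i] * t + c1[i]) * t + c2[i]) * t + c3[i]


@njit(cache=False)
def _fitness(d, cost, x0, dx, c0, c1, c2, c3, n_int):
    """W(d) = L(d) (1 - d^(1/c)) for d < 1."""
    L = _lifespan(math.log10(1.0 - d), x0, dx, c0, c1, c2, c3, n_int)
    if d == 0.0:
        return L
    return L * -math.expm1(math.log(d) / cost)


@njit(cache=False)
def _kimura(x, m_cat):
    """R = m x / (1 - exp(-x)) with x = 4 Ne s; series in the neutral zone."""
    if abs(x) < 0.02:  # x/(1-e^-x) Taylor series, error < 2e-9 here
        return m_cat * (1.0 + 0.5 * x + x * x / 12.0)
    em = -math.expm1(-x)  # overflows to -inf for very negative x -> R = 0
    r = m_cat * x / em
    return r if r > 0.0 else 0.0


@njit(cache=False)
def _category(
    i, d, log10_1m_d, ln_d, w_res, effects, pre_log10, pre_log1p,
    cost, four_ne, m_cat, x0, dx, c0, c1, c2, c3, n_int,
):
    """(rate, s, d', 4 Ne s) of category ``i`` at resident defence ``d``.

    Uses the factorizations log10(1-d') = log10(1-d) + log10(1-delta) for
    positive effects and ln d' = ln d + log1p(delta) for negative ones, with
    the per-category terms precomputed once per run.
    """
    delta = effects[i]
    if delta >= 0.0:
        dp = d + delta * (1.0 - d)
        x_spl = log10_1m_d + pre_log10[i]
        ln_dp = math.log(dp) if dp > 0.0 else -np.inf
    else:
        dp = d * (1.0 + delta)
        if dp < 0.0:
            dp = 0.0
        x_spl = math.log10(1.0 - dp)
        ln_dp = ln_d + pre_log1p[i]
    L = _lifespan(x_spl, x0, dx, c0, c1, c2, c3, n_int)
    z = ln_dp / cost
    if z < -37.0:  # d'^(1/c) underflows: the fecundity factor is 1
        w = L
    else:
        w = L * -math.expm1(z)
    s = w / w_res - 1.0
    x = four_ne * s
    if x <= X_CUT:
        return 0.0, s, dp, x
    return _kimura(x, m_cat), s, dp, x


@njit(cache=False)
def run_bin(
    d,
    T,
    bin_end,
    effects,
    pre_log10,
    pre_log1p,
    n_atom,
    cost,
    four_ne,
    m_cat,
    x0,
    dx,
    c0,
    c1,
    c2,
    c3,
):
    """Advance one time bin; returns the new defence level and the event log.

    Event log arrays: (times, deltas, d_before, d_after, s, tau), trimmed to
    the number of fixations in the bin.
    """
    n = effects.shape[0]
    n_int = c0.shape[0]
    rates = np.zeros(n)
    s_arr = np.zeros(n)
    dp_arr = np.zeros(n)

    cap = 128
    ev_t = np.empty(cap)
    ev_delta = np.empty(cap)
    ev_db = np.empty(cap)
    ev_da = np.empty(cap)
    ev_s = np.empty(cap)
    ev_tau = np.empty(cap)
    n_ev = 0

    log10_1m_d = math.log10(1.0 - d)
    ln_d = math.log(d) if d > 0.0 else -np.inf
    L_res = _lifespan(log10_1m_d, x0, dx, c0, c1, c2, c3, n_int)
    w_res = _fitness(d, cost, x0, dx, c0, c1, c2, c3, n_int)
    w_atom = _fitness(0.0, cost, x0, dx, c0, c1, c2, c3, n_int)

    need_full = True
    lo = n
    hi = n - 1
    events_since_scan = 0
    atom_total = 0.0
    s_atom = 0.0

    while True:
        if need_full:
            lo = n
            hi = n - 1
            for i in range(n_atom, n):
                rate, s, dp, x = _category(
                    i, d, log10_1m_d, ln_d, w_res, effects, pre_log10, pre_log1p,
                    cost, four_ne, m_cat, x0, dx, c0, c1, c2, c3, n_int,
                )
                rates[i] = rate
                s_arr[i] = s
                dp_arr[i] = dp
                if x > X_CUT:
                    if lo == n:
                        lo = i
                    hi = i
            need_full = False
            events_since_scan = 0
        if n_atom > 0:
            s_atom = w_atom / w_res - 1.0
            x_atom = four_ne * s_atom
            atom_total = 0.0 if x_atom <= X_CUT else n_atom * _kimura(x_atom, m_cat)
        total = atom_total
        for i in range(lo, hi + 1):
            total += rates[i]
        if not total > 0.0:
            return d, bin_end, ev_t[:n_ev], ev_delta[:n_ev], ev_db[:n_ev], ev_da[:n_ev], ev_s[:n_ev], ev_tau[:n_ev]
        tau = np.random.exponential(1.0 / total)
        dT = tau * L_res
        if T - dT <= bin_end:  # would cross the bin boundary: discard
            return d, bin_end, ev_t[:n_ev], ev_delta[:n_ev], ev_db[:n_ev], ev_da[:n_ev], ev_s[:n_ev], ev_tau[:n_ev]
        # fixation inside the bin: pick the winner proportionally to its rate
        T -= dT
        u = np.random.random() * total
        if n_atom > 0 and u < atom_total:
            winner = 0  # all clamp atoms are interchangeable (delta = -1)
            s_win = s_atom
            d_new = 0.0
        else:
            u -= atom_total
            winner = hi
            for i in range(lo, hi + 1):
                u -= rates[i]
                if u <= 0.0:
                    winner = i
                    break
            s_win = s_arr[winner]
            d_new = dp_arr[winner]
        if n_ev == cap:  # grow the event buffers
            cap *= 2
            new_t = np.empty(cap); new_t[:n_ev] = ev_t; ev_t = new_t
            new_d = np.empty(cap); new_d[:n_ev] = ev_delta; ev_delta = new_d
            new_b = np.empty(cap); new_b[:n_ev] = ev_db; ev_db = new_b
            new_a = np.empty(cap); new_a[:n_ev] = ev_da; ev_da = new_a
            new_s = np.empty(cap); new_s[:n_ev] = ev_s; ev_s = new_s
            new_u = np.empty(cap); new_u[:n_ev] = ev_tau; ev_tau = new_u
        ev_t[n_ev] = T
        ev_delta[n_ev] = effects[winner]
        ev_db[n_ev] = d
        ev_da[n_ev] = d_new
        ev_s[n_ev] = s_win
        ev_tau[n_ev] = tau
        n_ev += 1

        d = d_new
        log10_1m_d = math.log10(1.0 - d)
        ln_d = math.log(d) if d > 0.0 else -np.inf
        L_res = _lifespan(log10_1m_d, x0, dx, c0, c1, c2, c3, n_int)
        w_res = _fitness(d, cost, x0, dx, c0, c1, c2, c3, n_int)
        events_since_scan += 1
        if events_since_scan >= RESCAN_EVERY:
            need_full = True
            continue
        # incremental window update: recompute a margin around the previous
        # window, then expand outward while the edges stay above the cutoff
        lo2 = lo - MARGIN
        if lo2 < n_atom:
            lo2 = n_atom
        hi2 = hi + MARGIN
        if hi2 > n - 1:
            hi2 = n - 1
        if lo2 > hi2:  # window was empty: rescan
            need_full = True
            continue
        for i in range(lo2, hi2 + 1):
            rate, s, dp, x = _category(
                i, d, log10_1m_d, ln_d, w_res, effects, pre_log10, pre_log1p,
                cost, four_ne, m_cat, x0, dx, c0, c1, c2, c3, n_int,
            )
            rates[i] = rate
            s_arr[i] = s
            dp_arr[i] = dp
        while lo2 > n_atom:
            rate, s, dp, x = _category(
                lo2 - 1, d, log10_1m_d, ln_d, w_res, effects, pre_log10, pre_log1p,
                cost, four_ne, m_cat, x0, dx, c0, c1, c2, c3, n_int,
            )
            rates[lo2 - 1] = rate
            s_arr[lo2 - 1] = s
            dp_arr[lo2 - 1] = dp
            if x <= X_CUT:
                break
            lo2 -= 1
        while hi2 < n - 1:
            rate, s, dp, x = _category(
                hi2 + 1, d, log10_1m_d, ln_d, w_res, effects, pre_log10, pre_log1p,
                cost, four_ne, m_cat, x0, dx, c0, c1, c2, c3, n_int,
            )
            rates[hi2 + 1] = rate
            s_arr[hi2 + 1] = s
            dp_arr[hi2 + 1] = dp
            if x <= X_CUT:
                break
            hi2 += 1
        # trim dead edges so the window tracks the active set
        while lo2 < hi2 and rates[lo2] == 0.0:
            lo2 += 1
        while hi2 > lo2 and rates[hi2] == 0.0:
            hi2 -= 1
        lo = lo2
        hi = hi2
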