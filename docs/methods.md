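# Model and methods

`petolag` simulates the evolution of a single quantitative trait — the level
of cancer defences `d ∈ [0, 1]` — in a lineage whose body size changes over
macroevolutionary time, by origin-fixation substitution dynamics.  This note
records the model's assumptions, the numerical design, and the choices made
where the design was genuinely open.

## Life-history core

An individual of body mass `M` (kg) carries `N = M/70 × 3.72e13` cells.  Two
independent processes can end its life:

* **Cancer.**  Multistage carcinogenesis: each cell must complete `n`
  sequential oncogenic steps, each occurring at rate `(1−d)·k` per year, so
  the probability of having died from cancer by age `t` is

      C(t) = 1 − (1 − (1 − e^{−(1−d)k t})^n)^N.

  Defences scale the step rate down; `d = 1` abolishes cancer.
* **Extrinsic mortality.**  A constant hazard `μ = e^{−1.8} M^{−0.21}` per
  year, `E(t) = 1 − e^{−μt}`.  Flight, once acquired, multiplies `μ` by a
  coefficient `r ∈ (0,1]` (default 1/3).

Survival is `P(t) = (1−E(t))(1−C(t))` and the expected lifespan is
`L(d) = E[min(T_cancer, T_ext)] = ∫₀^∞ P(t) dt`.  `L` can equivalently be
computed in the quantile domain through the cancer-free survival quantile age

    t(P, d) = −ln(1 − (1 − P^{1/N})^{1/n}) / ((1−d)k),

(the age at which the probability of still being cancer-free equals `P`),
with the Jacobian `P·|t'(P)|` of the change of variables; both routes are
implemented and agree to better than 1e−9 relative (`expected_lifespan`,
methods `"quantile"` and `"time"`).  In the single-cell single-step limit
(`N = n = 1`) both death processes are exponential and
`L = 1/(μ + (1−d)k)` exactly; this closed form anchors the test suite.

The probability that cancer rather than extrinsic mortality ends life is the
competing-risks integral

    pCEL = ∫₀^∞ (1−E(t)) dC(t) = ∫₀¹ (1 − E(t(P,d))) dP,

which satisfies `pCEL = 1 − μ·L(d)` for a constant extrinsic hazard (an
identity used as an internal cross-check) and reduces to
`(1−d)k / (μ + (1−d)k)` at `N = n = 1`.

Fitness is lifetime reproductive success under a defence–fecundity
trade-off:

    W(d) = L(d) · (1 − d^{1/c}),

with cost parameter `c > 0` (configured as `log10 c`; the interesting range
is `log10 c ∈ [−4.1, −0.1]`).  Small `c` makes defences nearly free until
`d` approaches 1; large `c` penalises them strongly.

### Allometric inputs

| quantity | map | units / default |
|---|---|---|
| cells | `N = M/70 × 3.72e13` | linear in mass, human anchor |
| extrinsic mortality | `μ = e^{−1.8} M^{−0.21}` | per year |
| effective population size | `Ne = 10^{4 − 0.49(log10 M + 3) + 1.96}` | the `+3` converts kg to g; the `10^4` factor encodes the assumed species range and is configurable |
| oncogenic step rate | constant `k` (default 1e−4/y), or `k = κ M^{−0.3}` with `κ` normalised so `k` equals the baseline at the start-of-miniaturisation mass | per year |

`Ne` is kept continuous (no integer rounding): it only enters smooth
expressions, and rounding would introduce artificial steps along the mass
trajectory.

### Body-size trajectory

The miniaturisation scenario interpolates piecewise-linearly between three
anchors — 220.7 kg at 240 Mya, 163 kg at 198 Mya, 0.8 kg at 163 Mya — and
holds 0.8 kg to the present.  The full node list of the underlying
femur-length compilation is not bundled; users who have it can supply a
`time_mya,mass_kg` CSV, and results between the anchors may differ
quantitatively from runs using the full node set.  Control scenarios hold
mass constant at 220.7 kg ("dinosaur-like") or 0.8 kg ("small-mammal-like").

## Mutational input

Effect sizes `δ` follow a generalized extreme value distribution with shape
−0.75, scale 1, location −1 (MATLAB/Coles sign convention; scipy's
`genextreme` shape is the negative, +0.75).  Under this convention the
support is unbounded below and capped at location + scale/0.75 = +1/3; draws
below −1 are clamped to exactly −1 (≈37% of the mass collapses onto this
atom), so every effect lies in [−1, +1].  Clamping rather than rejection is
the default because a total defence loss (`δ = −1 → d' = 0`) is a meaningful
model event; rejection sampling is available via
`MutationEffectDistribution(truncation="reject")`, and any alternative law
can be injected through `SimulationConfig.custom_effects`.

Effects apply multiplicatively toward the nearer boundary:
`d' = d + δ(1−d)` for `δ > 0`, `d' = d(1+δ)` for `δ < 0`.

For the substitution engine the law is discretized into 1000
equal-probability categories at percentile midpoints 0.05%, 0.15%, …,
99.95%, each carrying mutation rate `m/1000`.  (A uniform midpoint grid is
the only self-consistent reading of an equal-probability 1000-category
discretization.)

## Substitution dynamics

Evolution is origin–fixation: no standing variation, no clonal
interference.  Category `i` fixes at Kimura's rate

    R_i = 4 Ne s_i m_i / (1 − e^{−4 Ne s_i}),

with `s_i = (W(d'_i) − W(d))/W(d)` and `m_i = m/1000`; the neutral limit is
`R = m_i`.  Candidate fixations race as independent exponential clocks; the
engine draws the winning time from `Exponential(ΣR)` and the winner with
probability `R_i/ΣR` (equal in law to drawing all 1000 clocks; the literal
per-clock mode is kept for equivalence testing via
`gillespie_mode="literal"`).

Time runs from 240 Mya to the present in 4000 bins of 60 000 years.  Within
a bin the environment is frozen.  Waiting times in generations convert to
years through the **pre-mutation** lifespan `L(d)` as the generation-time
proxy.  A candidate fixation whose waiting time would cross the bin
boundary is discarded (memorylessness makes this exact); time jumps to the
next bin start, where mass, `μ`, `Ne`, `k` — and hence `L` and `W` at the
unchanged `d` — are refreshed.  Flight switches on at the first bin whose
start time is at or past the flight date (default 170 Mya; 180 and 160 Mya
are the other canonical choices).  A fixation landing exactly on a boundary
(measure zero) counts as crossing.  Runs start with no lag: `d` is
initialised at the optimum for the starting environment.

## Evolutionary lags and the sweep

At the end of a run the final defence is compared with the optimum for the
final environment: `Δd = d_final − d*`, `ΔL = L_final/L(d*)`,
`ΔW = W_final/W_max ≤ 1`, plus `pCEL` at `d_final`.  The parameter sweep
runs one simulation per (scenario variant, `log10 c`, `log10 m`) cell — a
gradient design with dense unreplicated grids — with per-cell seeds spawned
from the master seed via `numpy.random.SeedSequence`, so enlarging the grid
never perturbs existing cells.  The default grid is 41 cost × 31 mutation
values over `log10 c ∈ [−4.1, −0.1]`, `log10 m ∈ [−15, 0]` (the grid
density itself is a package choice).  The *mutational boundary* of a cost
column is operationalized as the smallest `log10 m` with at least one
fixation.

## Numerical design

* **Huge-N arithmetic.**  `(1−x)^N` at `N ≈ 3.7e13` is computed as
  `exp(N·log1p(−x))` and `1 − P^{1/N}` as `−expm1(ln P / N)`; naive
  evaluation underflows catastrophically.  The quantile-domain lifespan
  integral is evaluated in the log-survival coordinate `v = −ln P`, because
  when cancer is rare the integrand's mass sits closer to `P = 1` than one
  part in 1e16 — unrepresentable in the direct coordinate.  The `v = y^n`
  substitution removes the integrable endpoint singularity of the Jacobian.
  Adaptive quadrature (QUADPACK) gets a geometric ladder of breakpoints
  around the two characteristic survival levels so that mass concentrated
  many orders of magnitude below the integration range is never overlooked.
* **Lifespan tables.**  The engine evaluates `L(d)` through a cubic spline
  over a 601-point grid in `log10(1−d)` spanning 12 decades (resolving the
  near-`d=1` region where `L` saturates at `1/μ`), built per environment
  from a fixed composite Gauss–Legendre quadrature in log-age (28 geometric
  panels, 8 nodes each).  Table values agree with the adaptive quadrature to
  ~1e−9 relative.  Because the environment sequence depends only on the
  scenario — not on cost or mutation rate — sweeps share one table sequence
  across all cells of a variant.
* **Optimum search.**  `W` can be extremely flat near `d = 1` at small
  cost, so the optimiser scans a 2001-point uniform grid *plus* a geometric
  tail resolving `1−d` down to 1e−9, then refines by bounded scalar
  minimisation in the bracketing interval; ties break toward the smaller
  `d`.  `d = 1` itself is handled as the limit `L = 1/μ`, `pCEL = 0`,
  `W = 0`.
* **Compiled inner loop.**  High-mutation-rate runs fix millions of
  substitutions, so the within-bin loop is numba-compiled with two purely
  numerical cutoffs: fixation rates with `4 Ne s < −40` (relative size
  `< e^{−40} ≈ 4e−18`) are treated as zero, and the above-cutoff categories
  — contiguous in the effect-sorted category order for a single-peaked
  fitness profile — are tracked as an index window, re-derived by a full
  scan at every bin entry and every 64 fixations and expanded incrementally
  at the edges in between.  The ~370 clamp-atom categories share one rate
  block.  The Kimura ratio uses a Taylor series below `|4 Ne s| = 0.02`
  (error < 2e−9).  The `gillespie_mode="literal"` path and the public
  `candidate_rates` function retain the uncompiled reference
  implementation; the compiled path reproduces it to float precision.
* **Randomness.**  The compiled loop uses numba's MT19937 state, seeded per
  run; the reference path uses `numpy.random.Generator`.  Each path is
  exactly reproducible under a fixed seed (the two paths consume different
  streams and are compared statistically, not event-by-event).

## What the built-in scenarios do and do not emulate

The bundled trajectories emulate the documented 240→163 Mya body-size
decline of the bird stem lineage and its constant-size controls.  The model
deliberately omits: age structure and explicit fecundity schedules
(reproduction enters only through the multiplicative trade-off factor),
standing genetic variation and diploid dominance, any feedback from cancer
risk onto the body-size trajectory (mass is exogenous), and the selective
causes of miniaturisation itself.  Passing tests therefore demonstrate the
internal consistency of the substitution model under these idealisations,
not the realism of any particular parameter combination for extant birds.

## Known limitations

* The quantile-domain and time-domain lifespan quadratures disagree at up to
  ~1e−7 relative only in regimes where cancer deaths are rarer than ~1e−20 —
  irrelevant to any simulated dynamics.
* The spline-table error (~1e−9 relative in `L`) enters selection
  coefficients near neutrality as noise of order `4 Ne · 1e−9 ≈ 1e−4` in
  the exponent of the fixation rate; this is far below the stochastic
  variation between seeds.
* The full-rate cutoff `4 Ne s > −40` makes hopeless categories exactly
  unfixable; their true aggregate probability of ever fixing in a run is
  below 1e−10.
* Sweep cells at the highest mutation rates (`m ≈ 1`) fix millions of
  near-neutral substitutions and dominate sweep wall time (minutes per cell
  on one CPU); the boundary region itself is cheap.
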