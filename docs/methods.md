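# Methods

## Model

`kiwipol` simulates pollination of a dioecious orchard crop as a
mean-field compartment system: every flower of a sex-and-cohort class
and every bee of a pollen-load class is treated as identical and
well-mixed, with no spatial structure. The field is one hectare by
convention, so all counts are per-hectare quantities.

### Bloom phenology

Opening rates are Gaussian in time. Integration starts at $t=0$ with all
buds closed, so cumulative openings are
$M(t)=B\,[\Phi((t-t_0)/\sigma)-\Phi(-t_0/\sigma)]$ and the total that
ever opens is $B\,[1-\Phi(-t_0/\sigma)]$, slightly below the bud count
$B$ (about 0.8% below at the base male parameters). Fruit-set
*proportions* still divide by $B$, the bud count, matching how the
quantity is defined in the field. Each flower stays open exactly
$\tau$ days; the open count is a difference of two CDF evaluations, so
the flower side of the model is closed-form and the pollinator side
becomes a non-autonomous ODE with closed-form forcing. This is
mathematically identical to the delay-differential formulation in which
the delayed cumulative counts $M(t-\tau_m)$, $F(t-\tau_f)$ appear as
state history; the test suite holds the closed-form route against a
literal fixed-step method-of-steps delay integration (numerically
integrated phenology, delayed terms from interpolated history) and the
two agree to well under 0.1% in total yield.

A zero bloom spread (all buds opening at one instant) is rejected by
validation rather than treated as a limiting pulse.

### Foraging and pollen transport

Bees carry high, medium, low or no pollen loads. The per-bee visitation
rate is Holling type II in the total open flower count; the sex of the
next flower follows the preference rule
$\Pr(\text{stay on sex }s) = (\text{share}_s)^{\text{pref}}$. When no
flowers are open the visitation rate is zero, so the stay probability at
an empty field is set to 1 by convention without affecting the dynamics;
likewise per-flower visit accrual is defined as 0 whenever fewer than
10⁻⁶ female flowers are open, which removes the 0/0 at the bloom edges
while the affected cohorts carry negligible closing mass.

Total bee count is conserved identically (every movement term enters
once as inflow, once as outflow); the integrator is required to preserve
it to 10⁻⁶ relative and errors out otherwise.

### Parameters

Base values and sampled ranges (units: days, flowers/ha unless noted):

| name | meaning | base | range |
|---|---|---|---|
| alpha | search rate, 1/(day·flower) | 480 | 120–3600 |
| beta | handling time per visit, days | 0.0011 | 0.00013–0.0094 |
| delta | stay-preference exponent, male | 0.0634 | 0–1 |
| epsilon | stay-preference exponent, female | 0.0725 | 0–1 |
| B_m, B_f | male/female buds | 600,000 | 300,000–900,000 |
| t_m, t_f | bloom peak day | 6 | 2–9 |
| sigma_m | male bloom spread | 2.5 | 0.5–5.5 |
| sigma_f | female bloom spread | 2 | 1–4 |
| tau_m | male flower lifespan | 4 | 3–5 |
| tau_f | female flower lifespan | 5 | 3–7 |
| rho | bees per 1000 female buds | 6 | 1–20 |
| p1, p2, p3 | per-visit fruit-set chance | 0.66/0.55/0.22 | see table |

Two conventions deserve emphasis:

- **Time is measured in days of active foraging.** Bees forage about
  4 h/day, and that window is folded into the rate parameters: the
  observed 16 s flower visit corresponds to the base handling time
  16/14400 ≈ 0.0011 days. Handling times given in seconds (config key
  `beta_seconds`, the handling-time sweep) therefore convert with a
  14,400 s "day", not 86,400 s. The source literature's own base value
  is only consistent with this convention, and the handling-time sweep
  endpoints (fruit set ≈100% at 10 s falling to ≈50% at 60 s) only
  reproduce under it.
- **The preference exponents are calibrated from 1:1 observations**:
  bees on male flowers stay on males with observed probability 0.957 at
  an even flower split, giving δ = ln(0.957)/ln(0.5) ≈ 0.0634, and
  ε = ln(0.951)/ln(0.5) ≈ 0.0725.

The flower-lifespan pair is reported inconsistently in the source
literature (τ_m = 4, τ_f = 5 in the parameter table; swapped in prose).
The table values are the defaults — they are the ones consistent with
the quoted ranges — and the swapped ordering runs fine through the
config layer.

### Cohort yield accounting

Every female flower closing during day $d$ opened $\tau_f$ days earlier
and, by the mean-field assumption, accumulated the same expected visit
exposure: $v_n(d) = A_n(t_c) - A_n(t_c - \tau_f)$, where
$A_n(t) = \int_0^t \text{rate}_n(s)/f(s)\,ds$ is the cumulative type-n
visits per open female flower. Visit counts are continuous expectations
(the model has no per-flower stochasticity), and the fruit-set formula
is evaluated with real exponents.

Where within day $d$ to read the exposure off is a genuine convention
choice. The default (`cohort_convention="weighted"`) averages
$A_n(t)-A_n(t-\tau_f)$ over the day weighted by the instantaneous
closing rate, using 5-point Gauss–Legendre quadrature; this is the only
convention under which the bookkeeping identity
$\sum_d \mathrm{DFC}(d)\,v_n(d) = \int \text{rate}_n\,dt$ holds tightly
(observed ≈0.1%; single-time-point conventions leave an irreducible ~3%
daily-quadrature residual). `"midpoint"` and `"end"` sampling are
available; all three agree on the base-orchard yield to 0.2%
(548,191 / 547,606 / 548,615 fruit/ha — the published prediction,
presumably computed under yet another private convention, is 545,120,
within 0.6% of all of them).

### Numerics

- Solver: `scipy.integrate.solve_ivp`, default **LSODA**, rtol 10⁻⁸,
  atol 10⁻⁶ per bee (10⁻¹⁰ on the accrual integrals). The mid/low-load
  compartments relax at up to the visitation ceiling 1/β (~10³–10⁴ per
  day), which makes the system stiff on the three-week bloom; explicit
  RK45 is step-limited to ~10× the cost at small β and is kept available
  (`Scenario.method="RK45"`) and cross-checked rather than used by
  default.
- Horizon rule: $T = \max(t_m,t_f) + 4\max(\sigma_m,\sigma_f) +
  \max(\tau_m,\tau_f) + 1$, covering >99.99% of openings and the last
  closing cohort; a horizon that leaves flowers open raises an error.
- Output grid 0.01 day; day $d$ aggregates the half-open interval
  $[d, d+1)$.
- The fixed-step cross-check integrator uses classical RK4 at
  h = 0.001 day (explicit stability needs $h \lesssim 2.8\beta$).

### Stocking bases and composition sweeps

The bee population is ρ per 1000 *female* buds by default
(`rho_basis="per_female"`, matching how the base simulations define the
initial condition P_f = ρ·B_f/1000); per-1000-total-buds is available.
In the composition sweeps (female fraction of a fixed 1.2 M bud total)
the bee population is anchored at the base scenario's 3600 bees rather
than re-derived from each point's female count: re-deriving would shrink
the hive stocking together with the female share, conflating two
separate interventions, and only the anchored rule reproduces the
published composition behaviour (≈98% fruit set at very low female
fractions, yield peaking near two-thirds female). Both behaviours are
exposed (`bee_anchor="reference" | "per_point"`).

## Sensitivity analysis

Latin hypercube sampling (scipy's `qmc.LatinHypercube`, exactly one draw
per equiprobable stratum per parameter, uniform marginals — no other
distribution is justified by the data) over the ranges above; one model
run per sample; PRCC of total yield against each parameter. PRCC is
computed as the correlation of rank-regression residuals and verified
in the tests against the textbook partial correlation obtained by
inverting the full Spearman matrix. Significance uses
$t = r\sqrt{(n-2-k)/(1-r^2)}$ with $k$ the number of covariates
adjusted for, against Student's t (normal-reference p-values are
reported alongside). No multiple-testing correction is applied by
default, matching how such analyses are conventionally reported; the
per-parameter p-values are all emitted so any correction can be applied
downstream.

Bud composition can be parameterized two ways: sampling B_m and B_f
independently (`"raw"`), or sampling total buds (0.6–1.8 M) and the
female percentage (5–96%) directly (`"derived"`). The derived
parameterization is the default for sensitivity work because the female
share is the agronomically meaningful lever and spans 5–96% there,
whereas independent bud counts confine it to 25–75%.

PRCC assumes monotonicity, so a decile-bin diagnostic is provided: the
linear influence of the other parameters is regressed out of the output
(the same adjustment PRCC itself makes), bin means are smoothed with a
3-point moving average, and successive differences larger than twice
their propagated standard error count as signed moves; both signs
present flags the parameter nonmonotone, with a split proposed at the
extremum bin's boundary. At n = 1000 the female share is flagged with a
split near 76–78%, and re-running the pipeline on the two sub-windows
(fresh hypercube, same seed) yields a strongly positive PRCC below the
split and a negative one above it — saturating the orchard with female
flowers eventually starves it of pollen. Detection power at n ≈ 200 is
marginal for the weaker curvatures (bloom timing and spreads), which is
why the shipped analyses use n = 1000.

## What the experiments assume, and limitations

The sweeps are the study conditions themselves (fixed 1.2 M buds,
1:1 ratio except where composition is the axis, base values elsewhere);
no synthetic data beyond the model's own forward runs is involved, so
passing tests demonstrate internal consistency and faithfulness to the
published predictions, not field validity. Known model limitations:

- no spatial heterogeneity, weather, or per-vine structure;
- a single pollinator taxon; no nectar/reward dynamics or bee-bee
  interference;
- male pollen availability assumed non-limiting;
- fixed flower lifespans and deterministic phenology;
- fruit quality (size, seed count) is out of scope — the output is the
  count of fully pollinated flowers.
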