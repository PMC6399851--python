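# Methods

This note documents the models implemented in `bystander_tgi`, the
assumptions behind them, the default parameter set, and the numerical
and design choices a user should know before trusting — or extending —
the results.

## Biological setting

An antibody-drug conjugate (ADC) binds a surface antigen on tumor
cells, is internalised, and releases its cytotoxic payload (e.g. MMAE)
in the lysosome.  Only antigen-positive (Ag+) cells receive payload
directly.  A membrane-permeable payload, however, leaks into the
extracellular space and re-enters neighbouring cells — including
antigen-negative (Ag−) cells — producing the *bystander-killing
effect*.  The package asks three questions: how the payload partitions
between Ag+ cells, Ag− cells and the extracellular space; how that
partition translates into tumor growth inhibition (TGI) of the two
subpopulations; and why the observed inhibition lags the dose by a few
days.

## Payload exchange (`payload_kinetics`)

Three well-mixed compartments exchange payload by first-order influx
(`k_in`, per day) and efflux (`k_out`, per day); `beta ∈ (0, 1]` is the
Ag+ fraction of the tumor and splits the influx between the two cell
populations:

    dC_int_p/dt = beta·k_in·C_ext − k_out·C_int_p
    dC_int_n/dt = (1−beta)·k_in·C_ext − k_out·C_int_n
    dC_ext/dt   = −k_in·C_ext + k_out·(C_int_p + C_int_n)

from the single-administration initial state `(C0, 0, 0)`.

Assumptions worth stating explicitly:

- **Closed system.** No extracellular clearance or volume terms (an
  in-vitro-like setting), so total payload is conserved.  This is also
  what makes the `beta ↔ 1−beta` near-symmetry of the tumor model hold.
- **No ADC dynamics.** Binding, internalisation, drug–antibody ratio
  and diffusion from capillaries are all outside the model; the dose
  enters only through `C0`.
- **One-way coupling.** The concentrations contain no tumor terms, so
  payload dynamics are independent of tumor size.
- `beta = 0` is rejected at construction: the initial payload is
  defined per Ag+ cell and is meaningless without Ag+ cells.

Because the system is linear it is solved in closed form: the sum
`S = C_int_p + C_int_n` and `C_ext` form a beta-free 2-D system with
eigenvalues `0` and `−(k_in+k_out)`, and the remainders
`C_int_p − beta·S` decay at `k_out`.  The closed form is exact to
floating precision and serves as ground truth for the numerical
integrator (adaptive RK, rtol 1e−8, atol 1e−10; negative undershoots
beyond atol are errors, smaller ones are clamped to zero on output).

Consequences used throughout:

- equilibrium (for `k_out > 0`):
  `(beta·C0/(1+k), (1−beta)·C0/(1+k), C0·k/(1+k))` with
  `k = k_out/k_in`;
- `C_int_p + C_int_n` is independent of `beta` — which is why the TGI
  model must couple each population to *its own* concentration to say
  anything about the Ag+/Ag− mix;
- when `k_out ≥ k_in`, the intracellular total never exceeds `C0`.

One subtlety: `C_int_p(t)` is non-increasing in `k_out` at every time,
but `C_int_n(t)` is **not** — faster efflux fills the Ag− cells faster
during the first day or so, even though the level they converge to is
lower.  Monotonicity claims about the Ag− compartment therefore only
hold after the transient, and the tests assert them from day 2 on.

### Units and rate conventions

All simulation rates are per day; `convert_rate_minutes_to_days`
(×1440) brings literature per-minute rates to that scale (the measured
auristatin influx rate, 8.46e−2/min, is 121.824/day).  Simulations use
the convention `k_in = 1/day` with `k` on a unit grid {1, 2, 3},
because the measured influx is far too fast to resolve the early
payload dynamics on a day grid.  The source material quotes a
day-scale efflux of 5.9357e4 (a value inconsistent with the ×1440
arithmetic by three orders of magnitude) and a ratio `k = 2.0442`
(inconsistent with the quoted per-minute rates, which give k < 1); the
package keeps the simulation convention, exposes the per-minute
literature constants, and does not attempt to resolve that
discrepancy.

## Dose response and regimes (`dose_response`)

The inhibitory Emax (Hill) function

    E(c) = E0·(1 − Emax·c^γ / (IC50^γ + c^γ))

maps a payload concentration to a response, decreasing from `E0` at
zero payload to `E0·(1−Emax)` at saturation, with `E(IC50) =
E0·(1−Emax/2)`.  `E0` carries nM units so that `c·E` is a per-day rate
(`c` is per nM per day).  `Emax` is treated as a dimensionless
fraction in (0, 1].  Defaults: `E0 = 120 nM`, `Emax = 0.6931`,
`IC50 = 300 nM`, `γ = 1`.

Under exponential growth the tumor obeys `dT/dt = (c·E − λ)T`, so the
sign of `c·E(conc) − λ` classifies the regime (a configurable
dead-band ε, default 1e−9/day, labels the knife edge "critical").
Substituting the equilibrium payload `C0/(1+k)` makes the regime a
monotone function of `k`; `critical_efflux_ratio` locates the unique
switching ratio by bracketed root finding (Brent, xtol 1e−10).  At the
default parameters the boundary is k̃ ≈ 3.24: retention-dominated
exchange (k below it) shrinks the tumor, efflux-dominated exchange
lets it grow.

## Two-population TGI (`tgi_dynamics`)

Each subpopulation grows independently, inhibited by its own payload:

    dT1/dt = c·E(C_int_p)·F(T1)·T1 − λ·T1        T1(0) = beta·T0
    dT2/dt = c·E(C_int_n)·F(T2)·T2 − λ·T2        T2(0) = (1−beta)·T0

with `F = 1` (exponential) or `F = 1 − T/Tmax` (logistic).  Defaults:
`c = 4.6e−3 /(nM·day)` (chosen so the drug-free growth rate is
`c·E0 = 0.552/day` against `λ = 0.5/day`), `T0 = 1000 mm³`,
`Tmax = 2e4 mm³`, logistic.

Design choices that were genuinely open:

- **Capacity sharing.** Under logistic growth each population sees the
  full `Tmax` (`F_i = 1 − T_i/Tmax`); the populations "grow
  independently" but how they share a capacity is not specified.  A
  per-population option (`beta·Tmax` / `(1−beta)·Tmax`) is available
  behind a flag.
- **Bystander switch.** Bystander-off is `k_out = 0`: the payload is
  trapped in Ag+ cells (maximally effective there) and the Ag− cells
  see none and grow drug-free.  This mirrors the MMAE (permeable) vs
  MMAF (poorly permeable) contrast and is deliberately all-or-nothing;
  no partial-permeability mode exists.
- **Coupling concentration.** Driving both populations by the total
  `C_int_p + C_int_n` is implemented only as a diagnostic
  (`drive="total"`): since the total is beta-independent, that variant
  provably cannot distinguish Ag+/Ag− mixes, which is the negative
  result motivating independent coupling.

Comparison metrics: `normalized_percent_change` (`100·(T/T0 − 1)`) and
`bystander_gap` (`100·((T3+T4) − (T1+T2))/T0`, off-minus-on as a
percent of the initial burden).  At the defaults the gap is negative
early — a permeable payload *dilutes* the direct kill — and turns
positive after roughly a month, when the accumulated killing of Ag−
cells wins.

**Near-symmetry, quantified.**  Swapping `beta ↔ 1−beta` swaps the
roles of the two populations with (after the ~1-day payload transient)
swapped concentrations, so the total burdens nearly coincide.  They do
not coincide exactly: the larger population briefly sees the full
`C0 → C0/(1+k)` transient in one run and a payload-free start in the
other, and that imprint persists.  Measured at the defaults the
sup-norm relative difference over days 5–60 is ≈1.1% for (0.4, 0.6),
≈2.3% for (0.3, 0.7) and ≈5.2% for (0.1, 0.9), largest at day 5 and
decaying.  The symmetry test therefore uses a 6% tolerance across all
pairs together with the ordering "gap shrinks as the split balances";
treating the symmetry as tighter than a few percent would misread the
model.

## Erlang age-structured TGI (`age_structured_tgi`)

Memoryless TGI responds to the payload instantly; in reality a hit
cell traverses several stages before dying.  Exponential stage
durations give an Erlang(n, θ) total lag (density
`a^{n−1}e^{−a/θ}/(Γ(n)θ^n)`, mean `n·θ`, hazard `ϕ/Φ` rising from 0 to
`1/θ` for n ≥ 2), and the renewal equation

    dT/dt = ∫₀^∞ c·ϕ(a)·E(t−a)·F(t−a)·T(t−a) da − λ·T

reduces exactly, by the linear chain trick, to `n` auxiliary ODE
states (the `θ^{n−1}` normalisation of the auxiliary states is kept as
printed in the source material even though it is dimensionally
inconsistent with the stated stage-1 initial value; the states are
treated as numeric).  Each tumor subpopulation carries its own chain;
the payload subsystem stays memoryless (the lag models drug–tumor
interaction stages, not payload transport).

**Defaults: θ = 0.1 day, n = 20.**  The shape is an inference, not a
sourced fact: the reference delay is "about 2 days", and `n·θ = 2`
days reproduces it.  `n` is a first-class configuration key.

**Initial conditions.**  Two conventions:

- `"steady"` (default): every stage holds the pre-treatment
  quasi-steady load `θ·c·E0·F(T0)·T0`.  At t = 0 the outflux equals
  the drug-free drive, so the tumor initially grows at its drug-free
  rate and inhibition arrives only after the Erlang lag — the delay
  behaviour the model exists to capture (peak ≈ 1037 mm³ at ≈ 1.6 days
  at the defaults, despite 200 nM of payload present from t = 0).
- `"impulse"`: all mass in stage 1, `F₁(0) = c·E0·T0`, later stages
  empty — the printed convention.  With n = 20 the outflux is starved
  for ≈ n·θ days and the tumor *shrinks* at rate λ first, i.e. the
  delay phenomenology is lost; the convention is retained because it
  is exact when the interaction machinery is switched on at dosing
  time, and because the renewal solver can match it exactly.

**Renewal reference solver.**  `renewal_integral_reference` integrates
the convolution equation directly on a uniform grid (step ≤ θ/10
enforced; θ/40 used in the equivalence tests): trapezoidal history
convolution plus a Heun predictor–corrector step (globally second
order), with the pre-t = 0 history folded into an explicit boundary
term — `c·E0·F(T0)·T0·Φ(t)` for the steady history,
`c·E0·T0·ϕ(t)` for the impulse — so that each history convention
matches its chain counterpart exactly.  The payload concentrations
entering `E` come from the closed-form payload solution.  The solver
shares no code with the chain reduction and is its independent
cross-check: agreement at the defaults is ≤ 6×10⁻⁴ sup-norm relative
over 30 days for n ∈ {1, 2, 5, 10} at step θ/40 (the error scales as
the square of the step).  Only the Erlang kernel is provided; the
kernel interface is the natural extension point for Weibull or
Mittag-Leffler lags, which are deliberately not implemented.

## Scenarios, fixtures and determinism (`scenario_cli`)

`ScenarioConfig` bundles all parameters, validates every nested
invariant, rejects unknown keys by name, and round-trips losslessly
through YAML or JSON.  `run_scenario` dispatches on the presence of an
`age_structure` section; `run_figure` provides four named sweeps
(payload dynamics over k × beta; TGI over beta; bystander on/off pairs
with gap series; the age-structured delay pair), each finishing in
well under a minute.  The pipeline contains no randomness — identical
configurations produce byte-identical CSV exports; an optional seeded
lognormal noise helper exists solely to fabricate noisy pseudo-data
for downstream testing and is off by default.  Figures are rendered
deterministically (fixed size, sorted legends) but numeric claims are
always made on the exported tables, not the images.

## What the defaults do and do not show

Everything above is simulated at the printed reference parameter set;
no parameter was fit to data.  The defaults emulate an idealised
in-vitro setting: direct intracellular dosing, no clearance, two
homogeneous well-mixed subpopulations, no spatial structure, no
ADC-target binding kinetics and no cell-cycle effects.  Passing tests
demonstrate internal consistency (conservation, closed-form and
renewal oracles, regime classification) and the qualitative orderings
of the reference figures — not predictive accuracy for any in-vivo
system.  Parameter estimation, additional subpopulations and
extracellular clearance are explicit non-goals.
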