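# Methods

## Scope and state

The package simulates nitrogen-limited growth of flood-irrigated rice at
daily resolution and optimizes the fertilization schedule against it. The
only state variable is the per-field soil nitrogen stock N (gN m⁻²).
Radiation (DTR, MJ m⁻² d⁻¹) and leaf area index (LAI, m² m⁻²) are
exogenous daily inputs: the crop's canopy is not fed back from its own
growth, there is no water limitation, no phenology, and no soil organic
matter pool. These are deliberate boundaries — the artifact is about the
scheduling decision, not about a complete crop model.

## Daily recursion

Within a day, in order:

1. the day's dose u is added to the stock: A = N + u;
2. the nitrogen nutrition index is computed from the dosed stock,
   NNI = A / NCR(LAI) with NCR = 3.7·LAI^−0.35. Counting the dose into
   the same day's NNI is a deliberate ordering choice: it makes a day-1
   application able to lift a depleted soil (n0 = 0) over the stress
   floor on day 1 itself, without which any empty-soil scenario would be
   trivially infeasible. The alternative (dose effective next day) would
   shift every application one day earlier and exclude n0 = 0 fields;
3. growth is the light-limited potential G* = ½·η_LUE·DTR·(1−e^(−k·LAI))
   times the stress factor e^(−ε·(1−min(NNI,1))). The cap at NNI = 1
   prevents surplus nitrogen from pushing growth beyond the potential;
4. uptake is NU = min(A, s·35.7·LAI^0.63) — the crop takes its
   LAI-driven demand, but never more than the soil holds, so the stock
   cannot be driven negative by uptake alone;
5. the next-day stock is (A)·η − NU − γ·N − Σₖ ζ[k→i]·Nₖ, clamped at
   zero. η ∈ [0,1] is the daily retention factor (denitrification +
   leaching losses of flooded paddies); γ is an extra self-loss used in
   the multi-field setting; ζ[k→i] is donor-driven exchange: field i's
   balance loses an amount proportional to the *donor* field k's stock.
   The exchange sign is configurable (`LeakageNetwork(sign=...)`);
   the default subtracts, and a zero ζ matrix reduces the multi-field
   step exactly (bitwise) to the single-field step.

The clamp at zero is the chosen behaviour for the undefined corner where
losses exceed stock; it only engages outside the optimizer's feasible
region (see below).

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| η_LUE | 3.0 | g MJ⁻¹ | typical rice light-use efficiency |
| k | 0.6 | — | common canopy attenuation value |
| ε | 0.6 | — | moderate stress sensitivity; growth at NNI=0 is e^(−0.6) ≈ 55 % of potential |
| η | 0.9 | d⁻¹ | 10 %/day loss, the high-loss regime of flooded paddies |
| δ | 0.1 | — | stress floor NNI ≥ 0.9 |
| u_min, u_max | 10, 25 | gN m⁻² | smallest worthwhile and largest single application |
| α, β | 0.2, 0.8 | € kg⁻¹ | labor and fertilizer prices |
| ω₁, ω₂ | 100, 1 | — | cost-aware weighting |
| HI | 0.5 | — | rice harvest index (0.46–0.50 range) |
| candidate gap | 10 | d | re-application spacing; day 1 always a candidate |
| uptake scale s | 0.005 (presets) | — | see below |

The uptake-capacity curve 35.7·LAI^0.63 is implemented exactly as
parameterised, with a dimensionless scale s defaulting to 1 in
`CropParams`. At s = 1 the daily capacity (≥ 8 gN m⁻² even at LAI = 0.1,
~110 at LAI = 6) exceeds any plausible soil stock, so the pool empties
every single day and **no** schedule restricted to spaced candidate days
can hold NNI ≥ 1−δ: the model is structurally infeasible at the printed
scale. The scenario presets therefore set s = 0.005, giving a peak
uptake of ~0.55 gN m⁻² d⁻¹ at full canopy — the order of magnitude of
measured daily rice nitrogen uptake — and making every preset (including
the three-field leakage chain, whose fields bear the extra γ and ζ
losses) feasible under the 10-day candidate rule. The calibration is a
property of the scenario fixtures, not of the model code.

## Scenario generator

`default_single_field()` is a 100-day season: constant DTR of
20 MJ m⁻² d⁻¹, logistic canopy closure LAI(d) = 6/(1+59·e^(−0.12 d))
(0.11 → 6), initial soil N of 5 gN m⁻². `default_three_field_chain()`
adds two downslope neighbours — ζ[1→2] = 0.01, ζ[2→3] = 0.015, γ =
(0.015, 0.015, 0.010) — with initial stocks (5, 5, 0). (The published
subscripts for these exchange coefficients are internally inconsistent;
the chain encoding — each field receiving from its uphill neighbour —
is the reading consistent with the stated field-1 → field-2 → field-3
influence structure.) `random_tiny_instance(seed)` draws short
(≤ 20-day) single- or two-field instances for solver validation.

What the generator does **not** emulate: weather variability beyond
optional sinusoidal/lognormal radiation, canopy response to nitrogen
(LAI is exogenous even under severe stress, so a starved crop keeps its
leaf area), within-season price changes, and measurement noise. Tests
passing on these scenarios therefore demonstrate correctness of the
balance/optimization machinery, not predictive skill on real fields.

## The optimization problems

Decision variables: b ∈ {0,1} and u ≥ 0 per field per candidate day,
coupled by b·u_min ≤ u ≤ b·u_max; all other days are fixed OFF. The
stress floor NNI ≥ 1−δ is enforced on **every** day including day 1; if
it is unreachable even at u_max the solve raises an infeasibility error
naming the first unreachable day.

Objectives: max-growth minimizes Σ (G* − G); since G ≤ G* by
construction the absolute value in the gap is dropped inside the solver
and asserted afterwards. Cost-aware minimizes ω₁·(α+β)·u/1000 + ω₂·(G*−G)
summed over fields and days. A standard exchange argument guarantees
that adding the cost term can only reduce total nitrogen supplied and
season biomass relative to the pure max-growth optimum — the test suite
checks this dominance on the reference scenario and on random instances.

## MILP reformulation

Three nonlinearities are handled:

* **Stress exponential.** f(m) = e^(−ε(1−m)) with m = min(NNI, 1) is
  convex and increasing. Because every feasible day has NNI ≥ 1−δ, m
  lives in [1−δ, 1]; f is interpolated there at n_breakpoints+1 evenly
  spaced points (default 16 segments) with a lambda (convex-combination)
  encoding plus one binary per segment enforcing SOS2-style adjacency
  (`scipy.optimize.milp` has no native SOS2). m enters as a free
  variable with m ≤ NNI and m ≤ 1; the objective pushes m up, so
  m = min(NNI, 1) at the optimum. For ε = 0.6 and 16 segments the
  maximal chordal error is < 5·10⁻⁴ on [0,1] and far smaller on
  [0.9, 1]; the documented solver error bound is ω₂ · (max chordal
  error) · Σ G*, and chords of a convex function overestimate, so the
  linearized optimum never exceeds the true optimum.
* **Uptake min().** Interval propagation of the dynamics (using the
  stress floor as a valid lower bound on available N) classifies each
  day: if the floor already guarantees A ≥ cap the uptake is the
  constant cap; if the reachable stock cannot exceed cap the uptake is
  the affine N+u; only genuinely ambiguous days get an indicator binary
  with big-M constants taken from the propagated bounds. For the preset
  parameterisations every day resolves to the constant-cap branch.
* **Nonnegativity clamp.** The solver writes the balance as an equality
  with N ≥ 0. On days whose next state provably cannot go negative —
  or where a zero stock would violate the next day's floor anyway, so
  no feasible schedule is lost — the equality stands; elsewhere a clamp
  indicator binary is added. In the feasible region of realistic
  instances the clamp never engages, and the re-simulation check below
  would flag any discrepancy.

A deterministic tie-break (weight 10⁻⁶ on later application days, and a
far smaller weight on total dose) selects, among equal-objective
schedules, the one with earliest/fewest applications and least nitrogen;
it perturbs the objective below the solver's MIP gap (10⁻⁶ relative).

Every schedule returned by the solver is **re-simulated through the
exact nonlinear recursion**; the report carries the exact objective next
to the linearized one, verifies the b/u coupling (after rounding the
binaries and clipping doses within solver tolerance), and flags any
stress-floor violation beyond 10⁻⁶.

## Validation oracle and receding horizon

`brute_force_oracle` enumerates every (b, u) combination on a dose grid
(default 0.5 gN m⁻²) over the candidate days, simulates each exactly,
discards floor violators and returns the best feasible schedule; it
refuses beyond 10⁶ combinations. It shares no code with the MILP path
beyond the simulator, making it an independent reference: on tiny
instances the MILP's exact-simulated objective must not exceed the
enumeration optimum by more than the linearization bound, and matches it
exactly when the optimum lands on the grid.

`run_dss` is the daily loop: observe the state (optionally perturbed via
a caller hook — the entry point for sensor feedback), re-solve the
remaining season from the current stock, commit today's decision, step
one day. On a deterministic scenario the committed schedule coincides
with the one-shot optimum (principle of optimality for an additively
separable deterministic problem, with uniqueness supplied by the
tie-break); the loop re-solves only on candidate days by default since
nothing can change in between, with `resolve_daily=True` available.

## Reporting conventions

Doses are kept in gN m⁻² everywhere; monetary operations convert with a
fixed 1/1000 to match €/kg prices. Tabled cost cells are truncated
toward zero at four decimals (0.0069602 € m⁻² prints as 0.0069), the
convention the reference cost tables follow. Grain yield is HI × season
biomass.

## Problem sizes used in the shipped checks

The reference solves use the 100-day presets (≈ 1 600 segment binaries,
solved by HiGHS in well under a second each). Oracle-equivalence checks
use 24 randomized instances of 12–20 days with at most two application
slots, so the 0.5-g enumeration stays around 10³ combinations per
instance. These sizes were chosen to keep the full validation loop
essentially instantaneous while still exercising every branch of the
formulation (stress-active optima, infeasible instances, two-field
coupling).

## Known limitations

* Exogenous LAI decouples canopy from nitrogen status; severe-stress
  trajectories are therefore optimistic about light interception.
* The donor-driven, subtract-only default for inter-field exchange
  conserves no mass (nitrogen leaving field k's neighbours is not added
  anywhere); the `sign="add"` option lets receivers gain it instead,
  but a fully conservative routing is out of scope.
* Prices and weather are deterministic; there is no robust or
  stochastic variant of the schedule.
* With ample dose bounds the max-growth solution saturates NNI at 1 and
  the growth gap reaches exactly zero, at the price of large nitrogen
  totals under high daily losses (η = 0.9); the cost-aware objective is
  the practically relevant one in that regime.
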