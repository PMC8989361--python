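# Methods

`extrigger` decides, year by year, whether the manager of a single-population
threatened species (SPTS) should keep working in the wild or trigger the
irreversible *ex situ, in toto* capture of the entire remaining population.
This note documents the model, its assumptions, the numerical choices, and
what the packaged tests do and do not demonstrate.

## The model

**Decline and extinction forecast.** The observed abundance is assumed to
decline linearly, with year-to-year variation attributed to environmental and
demographic stochasticity (not sampling error). Ordinary least squares on
(year, abundance) gives the decline rate r (individuals/year) with sampling
distribution p(r) — Normal(r̂, se(r̂)) by default, Student-t with n−2 degrees
of freedom behind the `slope_dist = t` switch. Pushing p(r) through the
linear extrapolation N(t) = N₀ + r·t gives the distribution of the first year
the population crosses zero: for each rate r < 0 the crossing year is
⌈N₀/|r|⌉; rates r ≥ 0 never cross and their mass is reported separately. The
planning horizon τ is the smallest year whose cumulative extinction
probability reaches the configured percentile (default the 99th), beyond
which extinction is treated as certain.

**Belief about in situ success.** Each year of in situ management is a
Bernoulli trial with unknown constant success probability q. Starting from a
uniform prior, n_u failures give the conjugate posterior Beta(1, n_u+1) with
mean E[q|n_u] = 1/(n_u+2): every failure makes the manager more pessimistic.
The capture success probability p_x is a fixed input — with a single tiny
population there is no opportunity to learn it.

**State space.** A state is {n_u, a_e, a_s}: failures so far (0..τ), whether
capture has been taken, whether in situ action has succeeded. The canonical
1-based index is i = a_s + 2a_e + 4n_u + 1, giving R = 4(τ+1) states; the
last state S_R = {τ,1,1} doubles as the complete-extinction sink. Elapsed
project time equals n_u + a_e + a_s. Two row-stochastic matrices give the
dynamics: continuing in situ succeeds with E[q|n_u] (→ {n_u,0,1}) or fails
(→ {n_u+1,0,0}); capturing establishes with p_x (→ {n_u,1,0}) or extinguishes
the species (→ S_R). States with a_e = 1 or a_s = 1 are absorbing, as is
{τ,0,0} under in situ action.

**Value.** Ending the horizon in a state with projected abundance N is worth
w₂^{a_e} · E_r[1 − exp(−w₁·max(0, N₀ + r·elapsed))]: satisfaction saturates
with abundance at rate w₁, and a captive population is worth only the
fraction w₂ of a wild one. The optimal policy comes from backward induction
of V(S_i, t) = max_a Σ_j T(a)_ij V(S_j, t+1).

**Receding-horizon replay.** The case-study workflow refits everything each
year on the data observed so far, then reads the optimal action at the
current state {n_u,0,0} and stage n_u, where n_u is the number of calendar
years since management (assumed to start with the first observation) — every
pre-trigger year counts as a failure, because no in situ success is ever
declared by the default success detector. The first decision year is the
first with `fit_window` (default 3) observations. Replay stops at the first
`ex_situ` recommendation (the trigger year) or at observed extinction.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| w₁ | satisfaction saturation rate | ln(20)/N(first year) | 1/individuals |
| w₂ | captive-population discount | 2/3 | — |
| p_x | capture establishment probability | 0.75 | — |
| horizon_percentile | extinction percentile defining τ | 0.99 | — |
| horizon_cap | upper bound on τ | max(5·span, 100) | years |
| n_rate_nodes | quantile nodes discretizing p(r) | 201 | — |
| fit_window | min. observations before deciding | 3 | years |

The w₁ default encodes "managers were 95% satisfied with the pre-decline
abundance": 1 − exp(−w₁N) = 0.95 at N = N(first observed year). w₂ = 2/3 and
p_x = 0.75 are plausible placeholder preferences; for a real species all
three should come from stakeholders and expert elicitation.

## Numerical choices

- **p(r) discretization.** 201 nodes at the mid-quantiles (k−½)/201 with
  uniform weights. Deterministic (no Monte-Carlo noise in the value
  integrals); by symmetry the node mean reproduces the fitted slope exactly,
  and 201 nodes resolve the 99th-percentile tail of the forecast.
- **Extinction year of a rate path** is the first *integer* year with
  N₀ + r·t ≤ 0, matching the model's annual decision clock.
- **Flooring inside the value integral** (`clamp = floor`, default). The raw
  value expression diverges to −∞ along extinct linear paths, making the
  failure penalty depend on how far past zero an extrapolation runs — an
  artifact with no biological meaning. Flooring projected abundance at zero
  anchors every extinct path at the species-lost value 0. `clamp = raw`
  preserves the literal expression for comparison.
- **The sink S_R is worth exactly 0**, overriding any evaluation at that
  bookkeeping state.
- **Tie-breaking prefers in situ** (absolute tolerance 1e-12 on value
  comparisons): delaying preserves the option value of an irreversible
  action, and deterministic ties make outputs reproducible. Consequence: in
  degenerate regions where both actions are exactly equal-valued (e.g. at the
  final decision stage, where an unresolved live state is valued at the same
  elapsed time as a fresh capture), the tool recommends continuing.
- **Horizon cap.** τ is capped at max(5 × observed span, 100) years — wide
  slope distributions put mass near r = 0⁻ whose crossing times are
  astronomically large, and R = 4(τ+1) states must stay tractable. The cap
  also applies when the percentile is unreachable (mass at r ≥ 0 exceeds
  1 − percentile); both cases warn loudly.
- **Replay degenerate regime.** If elapsed failures n_u have overtaken the
  current forecast τ, the SDP horizon is extended to n_u + 1 so the query
  stays well-posed; projected abundances there floor to zero, so both actions
  are worthless and the replay continues until observed extinction.
- **Reference abundance.** N₀ is the raw last observation (`reference =
  last_observed`); `fitted` uses the regression prediction at the last year,
  which is steadier for noisy series.

## The synthetic generator

`ScenarioSpec` draws N_t = max(0, N₀ + slope·t + ε_t), ε_t ~ N(0, σ), with an
optional sign flip of the slope from `recovery_year` onward. The four
packaged fixtures emulate the two regimes seen in real SPTS declines:
consistent near-linear slides (`steady_long`, `steady_to_zero`) and noisy
declines with transient increases (`noisy_upturn`, `noisy_shallow`). They are
synthetic stand-ins shaped like published case-study series, not historical
observations. The generator reproduces exactly per seed.

What it does *not* emulate: observation error distinct from process noise,
density dependence or Allee effects, non-annual survey gaps with varying
effort, and autocorrelated environments. Tests passing on these fixtures
show the machinery is correct under the model's own assumptions — linear
decline, Gaussian noise, Bernoulli in situ years — not that those assumptions
fit any particular species.

## Problem sizes used in the packaged checks

The solver is verified against a brute-force enumerator of all deterministic
state-and-stage policies at τ ≤ 3 (4096 policies, agreement to 1e-10 on 50
random instances); statistical calibration uses 100–200 simulated series of
15 years. Replays run on 10–25-year fixtures with τ up to the cap. These
sizes make the whole suite run in seconds while exercising every code path.

## Known limitations

- The linear-decline model is deliberately simple; exponential or
  density-dependent declines, or a species-specific population viability
  model, would slot into the same decision framework.
- The forecast band quantifies decline-*rate* uncertainty only: it is the
  envelope of linear declines through the current anchor N₀, not a predictive
  interval for future noisy observations, so its coverage statement concerns
  the true decline path, not individual surveys.
- Expected project time enters the state valuation as n_u + a_e + a_s, so a
  re-analysis late in a decline values the current state as if the fitted
  slope had also operated over the already-elapsed failure years; this
  follows the model's bookkeeping of elapsed time from the last observed
  anchor.
- If in situ success takes years to manifest, or managers cannot detect it
  within a year, the problem stops being Markovian and this tool's
  recommendation is no longer optimal. The success detector is pluggable but
  defaults to "no success observed".
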