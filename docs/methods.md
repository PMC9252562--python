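# Methods

## Model structure

The population is closed (no births, deaths or reinfection) and measured in
fractions. Eight compartments: S₁, S₂, E₁, E₂, A₁, A₂ by risk group, plus a
single symptomatic class I and a single recovered class R shared by both
groups — symptomatic individuals behave identically regardless of group, so
splitting them adds nothing. Exposed individuals are already infectious at
relative rate ρ, asymptomatic at α; a fraction σ of infections never
develops symptoms. Risk-evaders' precautionary habits scale their
per-contact infection likelihood by ε.

Mixing is frequency-dependent and activity-weighted: the chance that a
contact is with an infectious person is Φ/Θ where Φ weights each infectious
class by its contact rate and relative infectiousness and Θ = Σ C^h·h is
the total activity. If Θ = 0 the configuration is degenerate and the kernel
raises rather than returning 0.

## Time discretization

Dynamics advance in daily steps with exponential transition probabilities:
S→E with 1 − e^{−λ}, E→{A, I} with 1 − e^{−κ} (split σ / 1−σ), A/I→R with
1 − e^{−γ}. All flows within a day are computed simultaneously from the
morning state. The same transition law drives the decision problem, so the
dynamics the agents reason about are exactly the dynamics they live in.

Two reproduction-number conventions are exposed because they answer
different questions. The continuous kernel

    R0 = β C* (ρ/κ + (σα + 1 − σ)/γ)

is the conventional ODE next-generation value used for calibration: a new
infection transmits at rate βC*ρ for a mean latent period 1/κ, then at
βC*α (probability σ) or βC* (probability 1−σ) for a mean infectious period
1/γ; the spectral radius of the next-generation matrix reduces to this sum
because the model has a single infection cycle. The discrete kernel
replaces the exponential mean residence times with their geometric
counterparts 1/(1 − e^{−κ}) and 1/(1 − e^{−γ}); it is the value consistent
with the daily update, and the one that satisfies the implicit final-size
equation z = 1 − e^{−R₀z} of the simulated homogeneous epidemic (verified
to <1% relative error for R₀ in [1.5, 3]). With baseline parameters the two
read 2.399 and 2.553.

## Decision model

Utility per day is u(C) = (bC − C²)^ν: single-peaked, zero at C = 0 and
C = b, maximized at C* = b/2. Perceived infection risk per day at contact
rate C is 1 − exp(−βᵢ C φ Φ/Θ). Three deliberate perception rules:

- **Constant-prevalence projection.** The hazard uses today's state and the
  latest realized contact profile, held fixed over the whole planning
  horizon. Agents do not forecast the epidemic curve.
- **Atomistic agents.** The decision variable C multiplies the hazard but
  does not enter Θ; individuals ignore their own effect on population
  activity, and the two groups decouple by assuming each other's latest
  observed contacts (simultaneous best response against yesterday, not a
  within-day fixed point).
- **Reporting scales Φ only.** Others' activity is observable; their
  infection status is only as visible as surveillance makes it, so φ
  multiplies the perceived infectious pool but not total activity. Actual
  transmission never sees φ.

Backward induction runs k = τ..0 with terminal value 0 for every state. A
state-independent terminal constant provably leaves every argmax unchanged
(it adds the same discounted constant to all continuation values), so 0 is
the canonical choice; it is configurable for sensitivity runs. The horizon
τ therefore yields τ+1 decision steps (today plus τ projected days).

Symptomatic individuals earn zero utility while infectious
(`symptomatic_utility="zero"`, the default); the alternative convention in
which they earn u(C*) is implemented as `"full"` but eliminates the
incentive to avoid infection almost entirely (V(E) ≥ V(S), no contact
reduction) — the two conventions circulate in the literature and the model
only produces behavioral responses under the first. Exposed and
asymptomatic individuals, lacking symptoms, choose the same contact rate as
susceptibles of their group; their values V(E), V(A) matter only through
the infection penalty inside V(S).

### Optimizer

Contacts above C* are dominated (less utility, more risk), so the search
domain is (0, b/2]. Each backward step maximizes
u(C) − δ(V_S − V_E)(1 − e^{−aC}) by a dense 1024-point vector grid argmax
followed by golden-section refinement of the bracketing interval to an
absolute tolerance of 1e-6 contacts. The grid stage makes bracketing
failure impossible and keeps a full adaptive run (two groups × ~15 backward
steps × ~500 days) under half a second; ties are broken toward the larger
contact rate (the disease-free optimum), and a perceived hazard of exactly
zero short-circuits to C* = b/2. The solver is tested against an
independent plain 2000-point grid backward induction on 100 randomized
environments.

## Defaults and units

| symbol | meaning | default |
|---|---|---|
| β | per-contact transmission likelihood | 0.01324 |
| κ | incubation rate (1/day) | 1/5 |
| γ | recovery rate (1/day) | 1/9 |
| ρ, α | exposed / asymptomatic relative infectiousness | 0.25, 0.4 |
| σ | asymptomatic fraction | 0.5 |
| ε | risk-evader infection-risk scalar | 0.7 |
| b | maximum contacts/day (C* = b/2 = 24) | 48 |
| ν₁, ν₂ | utility shape, risk-takers / evaders | 0.1, 0.05 |
| τ₁, τ₂ | planning horizons (days) | 14, 14 |
| δ | daily discount factor (5%/year) | 0.99986 |
| φ | reporting level | 1.0 |
| i0 | initial exposed seed | 1e-4 |
| t_max, stop_tol | horizon and extinction threshold | 1000 d, 1e-7 |

β = 0.01324 with b = 48 reproduces R₀ = 2.4 under the continuous kernel
(0.01324 · 24 · 7.55 ≈ 2.399); a nearby published table rounds β to
0.01325, which the config accepts. δ = 0.99986 equals (1 − 0.05)^{1/365};
`annual_to_daily_discount` documents the convention. The seed is placed in
the exposed compartments proportionally to group size (configurable to
all-risk-taker or all-risk-evader seeding); initial conditions are
otherwise disease-free and day-0 contacts are C* for every class, since the
first generations of spread occur before anyone perceives risk.

## Scenario presets and sweeps

Presets encode the standard experiment layouts: single scenarios at
p = 0.33 / 0.66 with ε = 0.7; the (p, ε) attack-rate surface (step 0.05);
the same surface at σ ∈ {0.25, 0.5, 0.75}; contact trajectories at
φ ∈ {0.25, 0.5, 1.0}; the (φ, p) surface; and 1..30 × 1..30
planning-horizon grids at p ∈ {0.33, 0.5, 0.75} (grid extents are a
choice, overridable). The iso-attack routine bisects on φ at each p until
the attack rate matches a reference within 1e-3 absolute, flagging points
whose reference is unreachable within φ ∈ [0, 1]. The horizon search
breaks ties toward smaller τ₁+τ₂, then smaller τ₁. Everything is
deterministic — a `seed` config key exists for forward compatibility and
is logged as unused. Tests exercise the sweep machinery on coarse grids
(3–4 points per axis, t_max 700) — enough to establish the qualitative
surface properties; the full-resolution presets produce the same surfaces
at proportionally higher cost.

## What the model does and does not capture

The simulator generates the study conditions itself (no external data): a
naïve closed population, parameters as above, behavior driven purely by
infection-risk aversion. Passing tests therefore demonstrate internal
consistency of the coupled dynamics — conservation, the collapse of the
adaptive model onto constant contacts when nothing is perceived (φ = 0),
exchangeability of the groups when ε = 1 and shapes/horizons coincide,
behavioral damping of the final size, monotone responses to prevalence and
reporting, and the trade-off surface crossing its homogeneous baseline —
not fidelity to any real surveillance stream. Real populations add
demography, reinfection, time-varying risk attitudes, reporting biased
toward symptomatic cases, network structure and policy interventions, all
deliberately out of scope.

Known quantitative sensitivity: the depth of the peak contact reductions
(tens of percent) depends on reconstruction choices the underlying
formulation leaves open — daily-step vs within-day-continuous integration,
the horizon-step convention, and which contact profile agents assume for
others. Across those readings the peak cuts vary by roughly five
percentage points, and the ratio of the two groups' responses stays near
1.4 (set by ν₂ = ν₁/2 against ε = 0.7). Orderings and qualitative
conclusions are stable across all of them.
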