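# epibehave

Coupled simulation of an epidemic and the adaptive behavior it provokes, for
a population split into two risk groups. Built for epidemiological modelers
who want to study how privately optimal contact decisions — driven by risk
perception, surveillance quality and planning horizons — reshape the final
size of an epidemic.

## The model

**Disease.** A closed population follows SEIAR progression — susceptible
(S), exposed and already mildly infectious (E), symptomatic (I) or
asymptomatic (A) infectious, recovered (R) — and is split into a fraction
*p* of *risk-takers* (subscript 1) and 1−*p* of *risk-evaders* (subscript
2). Risk-evaders face a per-contact infection likelihood reduced by a
factor ε ∈ [0, 1]. Symptomatic and recovered individuals form single shared
compartments (behavior there is homogeneous). With class-specific daily
contact rates *C*ᵗʰ, the force of infection on S₁ is

```
λ₁ = β C^{S₁} · Φ/Θ,      λ₂ = ε β C^{S₂} · Φ/Θ,
Φ  = ρ(C^{E₁}E₁ + C^{E₂}E₂) + α(C^{A₁}A₁ + C^{A₂}A₂) + C^{I}I,
Θ  = Σ_h C^h h            (total population activity)
```

with ρ and α the relative infectiousness of exposed and asymptomatic
individuals. The kernel steps one day at a time with exponential daily
transition probabilities (1 − e^{−λ}, 1 − e^{−κ}, 1 − e^{−γ}).

**Behavior.** Each day, individuals who believe themselves healthy
(susceptible — and, lacking symptoms, also exposed and asymptomatic) pick a
contact rate maximizing expected utility over their group's planning
horizon τᵢ via a finite-horizon Bellman equation solved by backward
induction:

```
V_k(Sᵢ) = max_C { u(C) + δ [ (1 − P^{SᵢEᵢ}(C)) V_{k+1}(Sᵢ) + P^{SᵢEᵢ}(C) V_{k+1}(Eᵢ) ] },
u(C)    = (bC − C²)^νᵢ,        P^{SᵢEᵢ}(C) = 1 − exp(−βᵢ C φ Φ/Θ)
```

where *b* is the maximum feasible daily contacts (disease-free optimum
C\* = b/2), νᵢ the group's utility shape, δ the daily discount factor, and
φ ∈ [0, 1] the *reporting level* — the fraction of the infectious
population visible to decision-makers. φ distorts perception only; actual
transmission always uses the full prevalence. Decision-makers project the
current prevalence unchanged over their horizon, treat the rest of the
population's contacts as frozen at the latest observed profile, and ignore
their own effect on Θ (atomistic agents). Symptomatic individuals earn no
utility while infectious; recovered individuals contact at C\*.

**Coupling.** Each day both groups solve their decision problems against
the current state (simultaneously, each holding the other at yesterday's
contacts), the chosen rates are applied by that group's S/E/A classes, and
the epidemic advances one day — a feedback loop iterated to extinction.

Baseline parameters (β = 0.01324, C\* = 24, ρ = 0.25, α = 0.4, σ = 0.5,
κ = 1/5, γ = 1/9) calibrate the homogeneous constant-contacts model to a
basic reproduction number R₀ = 2.4 (next-generation matrix).

## Worked example

```python
import epibehave as eb

cfg = eb.ScenarioConfig(p=0.66, epsilon=0.7)   # 66% risk-takers
res = eb.simulate_adaptive(cfg)
overall, rt, re = eb.group_attack_rates(res, cfg.p)
print(f"attack rate: overall {overall:.3f}, risk-takers {rt:.3f}, risk-evaders {re:.3f}")
print(f"risk-taker peak contact cut:  {eb.contact_reduction_at_peak(res, 1):.1f}%")
print(f"risk-evader peak contact cut: {eb.contact_reduction_at_peak(res, 2):.1f}%")
```

prints

```
attack rate: overall 0.743, risk-takers 0.798, risk-evaders 0.635
risk-taker peak contact cut:  31.5%
risk-evader peak contact cut: 42.4%
```

Risk-evaders (smaller ν, i.e. cheaper contact cuts, and lower perceived
risk through ε) reduce contacts more deeply around the epidemic peak, yet
risk-takers end up infected at the higher rate: they keep more contacts and
face the full per-contact risk. Without any behavioral response the same
scenario reaches an attack rate of 0.899.

The `examples/` directory has one short script per capability: calibration
and final size, the adaptive response, reporting levels, the (p, ε)
trade-off surface, and optimal planning horizons. A thin CLI mirrors them:

```bash
epibehave r0                      # both kernel conventions
epibehave simulate --out runs/    # trajectory CSV + summary JSON
epibehave preset 3B --out runs/   # packaged experiment layouts
epibehave horizons --tau-max 30 --workers 4 --out runs/
```

## Layout

- `src/epibehave/params.py` — domain types and validation
- `src/epibehave/kernel.py` — SEIAR daily kernel, R₀, final-size utilities
- `src/epibehave/mdp.py` — utility, perceived risk, backward induction
- `src/epibehave/coupled.py` — the daily feedback loop and summaries
- `src/epibehave/experiments.py` — sweeps, presets, iso-attack curves, horizon search
- `src/epibehave/cli.py` — the `epibehave` command
- `docs/methods.md` — modeling assumptions, numerical choices, limitations
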