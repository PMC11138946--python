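# epibehave

Coupled behavior–disease SEIR dynamics with delayed risk information,
in-group pressure, epidemic wave detection and severity analysis.

## The problem

During an outbreak, people adjust protective behavior (mask wearing,
distancing) in response to the risk information available to them — and
that behavioral response feeds back on transmission, producing plateaus,
oscillations and secondary waves that a fixed-parameter epidemic model
cannot generate.  `epibehave` implements a deterministic two-group
behavior–SEIR model for exploring this feedback loop: how the *kind* of
risk information a group attends to (current prevalence vs. incidence
trend), the strength of in-group pressure, the protection level of the
behavior, and reporting delays shape epidemic peak size, the number of
waves and the final size.  It is aimed at infectious-disease modellers
studying behavior–disease coupling and at anyone needing a standalone
epidemic-wave detector for daily incidence series.

## The model

A population of constant size N₀ is split into susceptibles S₋₁, S₊₁
(two "standards of evidence"), exposed E, asymptomatic Iₐ, symptomatic
Iₛ, detected-and-isolated I_d and removed R:

    Ṡᵢ  = −λᵢ Sᵢ
    Ė   = λ₋₁S₋₁ + λ₁S₁ − θE
    İₐ  = (1−σ)(1−π)θE − (γₐ+ρₐ)Iₐ
    İₛ  = σ(1−π)θE − (γₛ+ρₛ)Iₛ
    İ_d = πθE + γₐIₐ + γₛIₛ − ρ_d I_d
    Ṙ   = ρₐIₐ + ρₛIₛ + ρ_d I_d

with quarantine-adjusted force of infection
λᵢ = β₀(1 − κ mᵢ)(φₐIₐ + φₛIₛ)/(N − I_d).  The prophylactic proportion
mᵢ of each susceptible group is a generalized-logistic (Richards)
function of an information aggregate built from the *delayed* perceived
prevalence P(t) = I_d(t−τ)/N and incidence trend Q(t) = Ċ(t−τ)/C(t−τ),
where C = πθE + γₐIₐ + γₛIₛ is the daily flow of new detected cases:

    ηᵢ = aᵢP + bᵢP² + cᵢPQ + dᵢQ² + eᵢQ
    mᵢ = (1 + exp(δᵢ − ηᵢ))^(−1/αᵢ),    δᵢ = log(m_{i0}^{−αᵢ} − 1)

The in-group parameter αᵢ > 0 tunes how strongly the non-engaging
majority drags on uptake; m_{i0} is the disease-free baseline.  Because
Q involves the *derivative* of the state at t−τ, the system is a neutral
delay differential system; it is integrated by a method-of-steps
Dormand–Prince 5(4) scheme with cubic-Hermite dense history (compiled
with numba).

On top of the solver the package provides:

- **wave detection** on daily incidence (prominence-based peak
  nomination plus trough rules on depth, spacing and duration),
- **severity measures**: wave count, peak height/time, time to curb
  (first down-crossing of the effective reproduction number
  ℛ(t) = Σᵢ Sᵢ/S · ℛ₀ S/(N₀−I_d) (1−κmᵢ) through 1), final size
  F_T = 1 − S(T)/N₀,
- a deterministic **34,560-run experiment grid** over response profiles,
  in-group pairs, β₀, π, τ and κ, with descriptive tables and summary
  regressions (Poisson secondary waves, gamma peak size, one-inflated
  beta final size).

## Worked example

A population in which half the people respond to prevalence only
(profile 0, a=20) and half additionally track the incidence trend
(profile D, a=20, e=10), both under strong pro-prophylactic in-group
pressure (α = 0.1):

```python
>>> from epibehave import BehaviorSEIR
>>> model = BehaviorSEIR.from_presets("0", "D", alpha=0.1)
>>> round(model.R0, 3)
6.685
>>> traj = model.solve(horizon=1000)
>>> print(f"peak {traj.peak_incidence:.0f} cases/day on day {traj.peak_time:.1f}")
peak 1377 cases/day on day 59.0
>>> model.severity()
SeveritySummary(epidemic=True, n_waves=2, n_secondary=1,
                peak_height=1376.88..., peak_time=59.0,
                time_to_curb=63.15, final_size=0.894)
```

The basic reproduction number at outbreak is 6.685 (the behavior-free
value 7 discounted by the 5% baseline mask-wearers and the 4 initially
infected).  The mixed population peaks at ~1,377 detected cases/day —
*below both* homogeneous populations (profile 0 alone peaks at ~1,815,
profile D alone at ~1,486): heterogeneity in what information people
attend to can reduce peak burden.  The behavioral relaxation after the
first peak triggers one secondary wave, and 89.4% of the population is
eventually infected.

`traj.to_frame()` returns the tidy trajectory (compartments, C(t),
m_i(t), ℛ(t)); the `epibehave` CLI exposes `simulate`, `waves`, `grid`,
`summarize` and `fixtures` subcommands over the same library.

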