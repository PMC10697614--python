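# eldercare-game

A differential-game model of how a government should organise medical care
for an elderly population during an epidemic, and when the extra cost of
special care stops being worth it.

Two players interact in continuous time over an infinite horizon. The
elderly choose a medical-service level `M` and an infection level `I`; the
government chooses a resource input `F`. Care is delivered in one of three
modes:

* **N — no special care**: baseline efficacy; queueing erodes the
  credibility gained per unit of government resource,
* **H — home medical care**: clinicians visit the elderly at home, cutting
  cross-infection harm by `α₁` and raising treatment efficacy by `β_H`, at
  an extra cost `c_H` on both players' quadratic cost terms,
* **G — "green channel"**: a priority in-hospital track that raises the
  per-unit service benefit by `b_G` and efficacy by `β_G` at extra cost
  `c_G`, without reducing cross-infection.

Each player maximises a discounted welfare stream, e.g. for the elderly in
mode N

```
J₁ = ∫₀^∞ [ b·M − c_I·I − (c_M/2)·M² + l₁·x₁ ] e^(−ρt) dt,
ẋ₁ = −λ₁·I² + ln(β+1)·M − δ₁·x₁,
```

with an analogous credibility state `x₂` for the government. Because the
Hamilton–Jacobi–Bellman (HJB) equations admit affine value functions
`V(x) = a·x + k` with `a = l/(ρ+δ)`, the feedback Nash equilibrium is
available in closed form and the strategies are constants:

```
M* = (b_eff + a₁·ln(efficacy+1)) / c_treat,   I* = −c_inf / (2λ₁a₁),
F* = κ·a₂ / c_gov.
```

Viewed as a function of the extra cost `c` of special care, each value
function is affine in the reciprocal cost, `V(c) = K0 + K1/(base + c)`
with `K1 > 0`, so special care always pays for itself at low extra cost
and always stops paying beyond a closed-form **crossover cost**.

The package provides the closed forms, an independent numeric HJB
verification (pointwise Hamiltonian maximisation and residual checks),
state trajectories with the discounted-welfare quadrature that must
reproduce the value functions, the cost-curve/threshold analysis, a
seeded scenario generator, and a CLI.

## Worked example

```python
from eldercare_game import (
    baseline_scenario, optimal_controls, value_function, crossover_cost,
    affine_in_inverse_cost, Mode, Agent, StatePoint,
)
import dataclasses

p = baseline_scenario()          # pinned reference parameter set
x0 = StatePoint(x1=1.0, x2=1.0)

c = optimal_controls(p, Mode.N)
print(round(c.M, 4), round(c.I, 4), round(c.F, 4))
# 2.2509 -0.75 0.5

v2 = value_function(p, Mode.N, Agent.GOVERNMENT)
print(round(v2.slope * x0.x2 + v2.intercept, 3))
# 1.278

d = affine_in_inverse_cost(dataclasses.replace(p, alpha1=0.5),
                           Mode.H, Agent.ELDERLY, x0)
print(round(d.K0, 2), round(d.K1, 2))
# 1.28 23.49

print(round(crossover_cost(p, Mode.H, Agent.ELDERLY, x0), 2))
# 1.93
```

Reading: under no special care the elderly receive `M* ≈ 2.25` units of
service and the government invests `F* = 0.5`; the government's lifetime
value starting from unit credibility is `1.278`. The elderly value of home
care is `1.28 + 23.49/(2 + c_H)`: decreasing in the extra cost `c_H`, and
it falls below the no-special-care value once `c_H` exceeds the crossover
`≈ 1.93`. The negative `I* = −0.75` is the model's unconstrained optimum
for the infection control; see `docs/methods.md` for discussion.

The same analyses run from the shell:

```
eldercare-game equilibrium          # closed-form controls and values
eldercare-game verify               # HJB residuals per (mode, agent)
eldercare-game thresholds           # crossover extra costs
eldercare-game report --out-dir out # full run: CSV curves, JSON, summary
```

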