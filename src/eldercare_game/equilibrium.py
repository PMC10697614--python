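"""Closed-form feedback Nash equilibrium of the three-mode care game.

With affine value functions ``V(x) = a*x + k`` the stationary HJB equation

    rho * V(x) = max over controls of [ utility rate + V'(x) * drift ]

decouples: matching the terms linear in the state gives the slope
``a = l / (rho + delta)``, and the first-order conditions in the controls —
which no longer involve the state — give constant equilibrium strategies

    M* = (b_eff + a1 * log_efficacy) / c_treat_eff
    I* = - c_inf_eff / (2 * lambda1 * a1)
    F* = kappa * a2 / c_gov_eff

with ``a1 = l1/(rho+delta1)`` (elderly) and ``a2 = l2/(rho+delta2)``
(government).  Matching the state-independent terms then yields the
intercepts.  Stationarity of the controls is a consequence of the affine
ansatz, not an extra assumption: each agent's Hamiltonian is strictly
concave and separable in its own controls, so the feedback strategies
degenerate to constants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    Agent,
    Controls,
    EffectiveParams,
    GameParameters,
    Mode,
    StatePoint,
    effective_params,
    validate_parameters,
)

__all__ = [
    "ValueFunction",
    "equilibrium_record",
    "evaluate_value",
    "optimal_controls",
    "optimal_controls_effective",
    "value_function",
    "value_function_effective",
]


@dataclass(frozen=True)
class ValueFunction:
    """An affine value function ``V(x) = slope * x + intercept`` for one
    (mode, agent) pair, in the agent's own state coordinate."""

    mode: Mode
    agent: Agent
    slope: float
    intercept: float

    def __call__(self, x: float) -> float:
        return self.slope * x + self.intercept


def _slopes(eff: EffectiveParams) -> tuple[float, float]:
    """Marginal state values a1 (elderly) and a2 (government)."""
    return (
        eff.l1 / (eff.rho + eff.delta1),
        eff.l2 / (eff.rho + eff.delta2),
    )


def optimal_controls_effective(eff: EffectiveParams) -> Controls:
    """Equilibrium controls from mode-collapsed coefficients.

    ``I*`` is negative whenever the effective infection harm is positive;
    it is returned unclipped (the model prices infection linearly in the
    utility but quadratically in the health drift, so the unconstrained
    optimum sits below zero)."""
    a1, a2 = _slopes(eff)
    M = (eff.b_eff + a1 * eff.log_efficacy) / eff.c_treat_eff
    I = -eff.c_inf_eff / (2.0 * eff.lambda1 * a1)
    F = eff.kappa * a2 / eff.c_gov_eff
    return Controls(M=M, I=I, F=F)


def optimal_controls(params: GameParameters, mode: Mode) -> Controls:
    """Equilibrium controls for one mode of a validated scenario."""
    validate_parameters(params, allow_degenerate=True)
    return optimal_controls_effective(effective_params(params, mode))


def value_function_effective(eff: EffectiveParams, agent: Agent) -> ValueFunction:
    """Affine value function from mode-collapsed coefficients.

    The intercept is the discounted state-independent part of the
    equilibrium flow: ``k = (1/rho) * [u0 + a * d0]`` where ``u0`` is the
    instantaneous utility at the optimal controls with the state term
    removed and ``d0`` the state-independent part of the drift.  This is the
    generic formula for the whole mode family; mode-specific transcriptions
    are used only as cross-checks in the test suite.
    """
    agent = Agent(agent)
    a1, a2 = _slopes(eff)
    c = optimal_controls_effective(eff)
    if agent is Agent.ELDERLY:
        u0 = eff.b_eff * c.M - eff.c_inf_eff * c.I - 0.5 * eff.c_treat_eff * c.M**2
        d0 = -eff.lambda1 * c.I**2 + eff.log_efficacy * c.M
        slope, k = a1, (u0 + a1 * d0) / eff.rho
    else:
        u0 = -0.5 * eff.c_gov_eff * c.F**2
        d0 = eff.kappa * c.F
        slope, k = a2, (u0 + a2 * d0) / eff.rho
    return ValueFunction(mode=eff.mode, agent=agent, slope=slope, intercept=k)


def value_function(params: GameParameters, mode: Mode, agent: Agent) -> ValueFunction:
    """Affine value function for one (mode, agent) pair of a validated scenario."""
    validate_parameters(params, allow_degenerate=True)
    return value_function_effective(effective_params(params, mode), agent)


def evaluate_value(vf: ValueFunction, s: StatePoint) -> float:
    """Evaluate a value function at the agent-appropriate state coordinate."""
    x = s.x1 if vf.agent is Agent.ELDERLY else s.x2
    return vf(x)


def equilibrium_record(
    params: GameParameters, mode: Mode, *, ndigits: int = 2
) -> dict:
    """JSON-serialisable summary of one mode's equilibrium.

    Contains the controls, both value functions and a half-even-rounded
    view (``ndigits`` decimals) for report parity alongside full precision.
    """
    mode = Mode(mode)
    c = optimal_controls(params, mode)
    v1 = value_function(params, mode, Agent.ELDERLY)
    v2 = value_function(params, mode, Agent.GOVERNMENT)
    record = {
        "mode": mode.value,
        "controls": {"M": c.M, "I": c.I, "F": c.F},
        "elderly": {"slope": v1.slope, "intercept": v1.intercept},
        "government": {"slope": v2.slope, "intercept": v2.intercept},
    }
    record["rounded"] = {
        "M": round(c.M, ndigits),
        "I": round(c.I, ndigits),
        "F": round(c.F, ndigits),
        "elderly_slope": round(v1.slope, ndigits),
        "elderly_intercept": round(v1.intercept, ndigits),
        "government_slope": round(v2.slope, ndigits),
        "government_intercept": round(v2.intercept, ndigits),
    }
    return record
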