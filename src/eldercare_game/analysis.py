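"""Cost–benefit analysis of the special-care modes.

The central object is the affine-in-inverse-cost decomposition: for the
home-care and green-channel modes the equilibrium value of either agent,
viewed as a function of the extra cost ``c`` (``c_H`` or ``c_G``), is

    V(c) = K0 + K1 / (base + c)

where ``base`` is the agent's own baseline quadratic-cost coefficient
(``c_M`` for the elderly, ``c_F`` for the government).  For the elderly,

    K0 = a1*x1 + c_inf_eff^2 / (4*lambda1*a1*rho),   K1 = S^2 / (2*rho)

with ``S = b_eff + a1*log_efficacy``; for the government,

    K0 = a2*x2,   K1 = a2^2 * kappa^2 / (2*rho).

``K1 > 0`` makes the curve strictly decreasing in ``c``, so the value of
special care eventually falls below the no-special-care value, and the
crossover cost solves ``K0 + K1/(base + c) = V_N`` in closed form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    Agent,
    GameParameters,
    Mode,
    StatePoint,
    effective_params,
    validate_parameters,
)
from .equilibrium import evaluate_value, value_function

__all__ = [
    "AffineCostDecomposition",
    "CostCurve",
    "affine_in_inverse_cost",
    "cost_curve",
    "crossover_cost",
    "recommend_mode",
    "sensitivity_table",
    "with_extra_cost",
]

_SWEEPABLE = ("alpha1", "lambda_H", "lambda_G", "b_G")


@dataclass(frozen=True)
class AffineCostDecomposition:
    """``V(extra) = K0 + K1 / (base_cost + extra)`` for one (mode, agent)."""

    mode: Mode
    agent: Agent
    K0: float
    K1: float
    base_cost: float

    def __call__(self, extra: float) -> float:
        return self.K0 + self.K1 / (self.base_cost + extra)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "agent": self.agent.value,
            "K0": self.K0,
            "K1": self.K1,
            "base_cost": self.base_cost,
        }


@dataclass(frozen=True)
class CostCurve:
    """Value of a special-care mode along a grid of extra costs, with the
    no-special-care value as the horizontal baseline."""

    mode: Mode
    agent: Agent
    grid: np.ndarray
    values: np.ndarray
    baseline: float
    crossover: float | None


def with_extra_cost(params: GameParameters, mode: Mode, extra: float) -> GameParameters:
    """A copy of ``params`` with the mode's extra cost set to ``extra``."""
    mode = Mode(mode)
    if mode is Mode.H:
        return dataclasses.replace(params, c_H=extra)
    if mode is Mode.G:
        return dataclasses.replace(params, c_G=extra)
    raise ValueError("mode N has no extra cost to set")


def affine_in_inverse_cost(
    params: GameParameters, mode: Mode, agent: Agent, x0: StatePoint
) -> AffineCostDecomposition:
    """Closed-form (K0, K1, base) of the value as a function of extra cost."""
    mode, agent = Mode(mode), Agent(agent)
    if mode is Mode.N:
        raise ValueError("mode N has no extra-cost decomposition")
    validate_parameters(params, allow_degenerate=True)
    eff = effective_params(params, mode)
    rho = params.rho
    if agent is Agent.ELDERLY:
        a1 = eff.l1 / (rho + eff.delta1)
        S = eff.b_eff + a1 * eff.log_efficacy
        K0 = a1 * x0.x1 + eff.c_inf_eff**2 / (4.0 * eff.lambda1 * a1 * rho)
        K1 = S**2 / (2.0 * rho)
        base = params.c_M
    else:
        a2 = eff.l2 / (rho + eff.delta2)
        K0 = a2 * x0.x2
        K1 = a2**2 * eff.kappa**2 / (2.0 * rho)
        base = params.c_F
    return AffineCostDecomposition(mode=mode, agent=agent, K0=K0, K1=K1, base_cost=base)


def _value_at_extra(
    params: GameParameters, mode: Mode, agent: Agent, x0: StatePoint, extra: float
) -> float:
    vf = value_function(with_extra_cost(params, mode, extra), mode, agent)
    return evaluate_value(vf, x0)


def baseline_value(params: GameParameters, agent: Agent, x0: StatePoint) -> float:
    """No-special-care value at the same state — the horizontal reference."""
    return evaluate_value(value_function(params, Mode.N, agent), x0)


def cost_curve(
    params: GameParameters, mode: Mode, agent: Agent, grid, x0: StatePoint
) -> CostCurve:
    """Evaluate the value function along a grid of extra costs."""
    mode, agent = Mode(mode), Agent(agent)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("extra-cost grid must be non-empty")
    if np.any(grid < 0.0):
        raise ValueError("extra costs must be nonnegative")
    values = np.array(
        [_value_at_extra(params, mode, agent, x0, float(c)) for c in grid]
    )
    return CostCurve(
        mode=mode,
        agent=agent,
        grid=grid,
        values=values,
        baseline=baseline_value(params, agent, x0),
        crossover=crossover_cost(params, mode, agent, x0),
    )


def crossover_cost(
    params: GameParameters,
    mode: Mode,
    agent: Agent,
    x0: StatePoint,
    *,
    method: str = "closed_form",
) -> float | None:
    """Extra cost at which the special-care value meets the N-mode value.

    Returns ``None`` when the curve never crosses (``V_N <= K0``, the
    horizontal asymptote).  A negative return means special care is worse
    than no special care even at zero extra cost.  ``method="bisect"``
    solves the same root by bracketing — the independent cross-check.
    """
    dec = affine_in_inverse_cost(params, mode, agent, x0)
    v_n = baseline_value(params, agent, x0)
    if v_n <= dec.K0:
        return None
    root = dec.K1 / (v_n - dec.K0) - dec.base_cost
    if method == "closed_form":
        return float(root)
    if method != "bisect":
        raise ValueError(f"unknown method {method!r}")
    f = lambda c: dec(c) - v_n
    lo = -dec.base_cost * (1.0 - 1e-12)
    hi = max(1.0, 2.0 * abs(root) + 1.0)
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 1e12:
            return None
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def sensitivity_table(
    params: GameParameters,
    mode: Mode,
    agent: Agent,
    parameter_name: str,
    values,
    x0: StatePoint,
) -> pd.DataFrame:
    """One affine decomposition per value of a swept mode parameter.

    ``parameter_name`` is one of ``alpha1``, ``lambda_H``, ``lambda_G``,
    ``b_G``.  The returned frame has columns ``[parameter_name, K0, K1,
    value]`` (``value`` at the scenario's own extra cost) and carries the
    signed trend of each column in ``df.attrs['trend']`` (+1 increasing,
    -1 decreasing, 0 flat/non-monotone).
    """
    if parameter_name not in _SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {parameter_name!r}; expected one of {_SWEEPABLE}"
        )
    mode, agent = Mode(mode), Agent(agent)
    rows = []
    for v in values:
        p = dataclasses.replace(params, **{parameter_name: float(v)})
        dec = affine_in_inverse_cost(p, mode, agent, x0)
        extra = p.c_H if mode is Mode.H else p.c_G
        rows.append(
            {
                parameter_name: float(v),
                "K0": dec.K0,
                "K1": dec.K1,
                "value": dec(extra),
            }
        )
    df = pd.DataFrame(rows)

    def trend(col: pd.Series) -> int:
        d = np.diff(col.to_numpy())
        if np.all(d > 0):
            return 1
        if np.all(d < 0):
            return -1
        return 0

    df.attrs["trend"] = {c: trend(df[c]) for c in ("K0", "K1", "value")}
    return df


def recommend_mode(
    params: GameParameters, c_H: float, c_G: float, x0: StatePoint
) -> dict[Agent, list[Mode]]:
    """Rank the three modes by value for each agent at given extra costs.

    Ties are broken by the fixed reporting order N < H < G.
    """
    p = dataclasses.replace(params, c_H=c_H, c_G=c_G)
    validate_parameters(p, allow_degenerate=True)
    ranking: dict[Agent, list[Mode]] = {}
    for agent in Agent:
        scored = [
            (evaluate_value(value_function(p, mode, agent), x0), mode)
            for mode in Mode
        ]
        scored.sort(key=lambda pair: (-pair[0], pair[1].order))
        ranking[agent] = [mode for _, mode in scored]
    return ranking
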