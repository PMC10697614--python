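"""State trajectories and discounted welfare under equilibrium play.

Because the equilibrium controls are constant, each state obeys a linear
ODE ``x' = d0 - delta * x`` whose solution relaxes exponentially to the
steady state ``x_ss = d0 / delta``:

    x(t) = x_ss + (x0 - x_ss) * exp(-delta * t)

:func:`simulate` integrates the ODE numerically (adaptive stepping,
relative tolerance 1e-9) and the exact exponential is available as the
fast path; both must agree, which the test suite enforces.

:func:`discounted_welfare` evaluates each agent's objective
``integral of e^{-rho t} * utility rate dt`` by adaptive quadrature along
the exact trajectory, truncated at a horizon ``T`` where the discount
factor has fallen below a tenth of the requested tolerance, with the tail
added back analytically (the integrand beyond ``T`` is an explicit mix of
two exponentials).  The result must reproduce the affine value function at
the initial state — the headline internal-consistency check of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp

from .model import (
    Agent,
    Controls,
    GameParameters,
    Mode,
    StatePoint,
    credibility_drift,
    effective_params,
    elderly_utility_rate,
    government_utility_rate,
    health_drift,
    validate_parameters,
)
from .equilibrium import optimal_controls_effective

__all__ = ["Trajectory", "discounted_welfare", "exact_path", "simulate", "steady_states"]


@dataclass(frozen=True)
class Trajectory:
    """Simulated state paths under constant equilibrium controls."""

    mode: Mode
    times: np.ndarray
    x1_path: np.ndarray
    x2_path: np.ndarray
    controls: Controls


def steady_states(params: GameParameters, mode: Mode) -> tuple[float, float]:
    """Long-run states under equilibrium controls: drift zero in each ODE."""
    validate_parameters(params, allow_degenerate=True)
    eff = effective_params(params, mode)
    c = optimal_controls_effective(eff)
    x1_ss = (-eff.lambda1 * c.I**2 + eff.log_efficacy * c.M) / eff.delta1
    x2_ss = eff.kappa * c.F / eff.delta2
    return x1_ss, x2_ss


def exact_path(
    params: GameParameters, mode: Mode, x0: StatePoint, times
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form exponential relaxation of both states on a time grid."""
    times = np.asarray(times, dtype=float)
    x1_ss, x2_ss = steady_states(params, mode)
    x1 = x1_ss + (x0.x1 - x1_ss) * np.exp(-params.delta1 * times)
    x2 = x2_ss + (x0.x2 - x2_ss) * np.exp(-params.delta2 * times)
    return x1, x2


def simulate(
    params: GameParameters,
    mode: Mode,
    x0: StatePoint,
    horizon: float,
    step: float,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the state ODEs under equilibrium controls.

    ``step`` is the output-grid spacing; the integrator steps adaptively.
    """
    if horizon <= 0.0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if step <= 0.0 or step > horizon:
        raise ValueError(f"step must lie in (0, horizon], got {step}")
    validate_parameters(params, allow_degenerate=True)
    mode = Mode(mode)
    eff = effective_params(params, mode)
    c = optimal_controls_effective(eff)

    def rhs(_t, y):
        s = StatePoint(x1=y[0], x2=y[1])
        return [health_drift(eff, c, s), credibility_drift(eff, c, s)]

    times = np.arange(0.0, horizon + 0.5 * step, step)
    times[-1] = min(times[-1], horizon)
    sol = solve_ivp(
        rhs, (0.0, horizon), [x0.x1, x0.x2], t_eval=times, rtol=rtol, atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"state integration failed: {sol.message}")
    return Trajectory(
        mode=mode, times=sol.t, x1_path=sol.y[0], x2_path=sol.y[1], controls=c
    )


def discounted_welfare(
    params: GameParameters,
    mode: Mode,
    x0: StatePoint,
    tolerance: float = 1e-9,
) -> tuple[float, float]:
    """Discounted lifetime welfare (W1 elderly, W2 government) from ``x0``.

    Adaptive quadrature of ``e^{-rho t} * utility rate`` along the exact
    trajectory on ``[0, T]`` with ``e^{-rho T} < tolerance / 10``, plus the
    analytic tail of the truncated integral.
    """
    if tolerance <= 0.0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    validate_parameters(params, allow_degenerate=True)
    mode = Mode(mode)
    eff = effective_params(params, mode)
    c = optimal_controls_effective(eff)
    x1_ss, x2_ss = steady_states(params, mode)
    rho = params.rho
    T = math.log(10.0 / tolerance) / rho

    def x_at(t: float) -> StatePoint:
        return StatePoint(
            x1=x1_ss + (x0.x1 - x1_ss) * math.exp(-params.delta1 * t),
            x2=x2_ss + (x0.x2 - x2_ss) * math.exp(-params.delta2 * t),
            t=t,
        )

    def integrand(rate_fn):
        return lambda t: math.exp(-rho * t) * rate_fn(eff, c, x_at(t))

    quad_opts = dict(epsabs=tolerance / 10.0, epsrel=tolerance / 10.0, limit=500)
    w1, err1 = quad(integrand(elderly_utility_rate), 0.0, T, **quad_opts)
    w2, err2 = quad(integrand(government_utility_rate), 0.0, T, **quad_opts)
    if err1 > tolerance * max(1.0, abs(w1)) or err2 > tolerance * max(1.0, abs(w2)):
        raise RuntimeError(
            f"welfare quadrature did not converge: error estimates {err1}, {err2} "
            f"exceed tolerance {tolerance}"
        )

    # analytic tail on [T, inf): the utility rate is u_ss + (l*(x0-x_ss)) e^{-delta t}
    def tail(u_ss: float, l: float, x_start: float, x_ss: float, delta: float) -> float:
        return u_ss * math.exp(-rho * T) / rho + l * (x_start - x_ss) * math.exp(
            -(rho + delta) * T
        ) / (rho + delta)

    u1_ss = elderly_utility_rate(eff, c, StatePoint(x1=x1_ss, x2=x2_ss))
    u2_ss = government_utility_rate(eff, c, StatePoint(x1=x1_ss, x2=x2_ss))
    w1 += tail(u1_ss, eff.l1, x0.x1, x1_ss, params.delta1)
    w2 += tail(u2_ss, eff.l2, x0.x2, x2_ss, params.delta2)
    return float(w1), float(w2)
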