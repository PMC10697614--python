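"""Scenario generation: the pinned baseline parameter set and seeded random
admissible scenarios for property-based testing.

The baseline is the reference numerical configuration of the model: the
discount rate, decay rates, costs, benefits and efficacy gains used in all
worked examples and reference checks.  Random scenarios sample each
parameter uniformly within [0.5x, 2x] of its baseline value (the discount
rate capped at 1) and reject draws that violate any admissibility
constraint, so every emitted scenario is valid by construction and the
stream is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GameParameters, ParameterError, validate_parameters

__all__ = ["ScenarioSpec", "baseline_scenario", "default_ranges", "random_scenarios"]

# Baseline values for the sweep parameters (alpha1, lambda_H, lambda_G, b_G,
# c_H, c_G) are the first value of each reference sweep; the remaining
# parameters are the reference configuration.
_BASELINE = dict(
    rho=0.9,
    delta1=0.1,
    delta2=0.1,
    b=3.0,
    b_G=1.0,
    l1=1.0,
    l2=1.0,
    c_I=1.5,
    c_M=2.0,
    c_F=2.0,
    c_H=1.0,
    c_G=1.0,
    alpha1=0.5,
    lambda1=1.0,
    lambda2=1.0,
    lambda3=2.0,
    lambda4=2.0,
    lambda_H=0.3,
    lambda_G=0.3,
    beta=3.49,
    beta_H=28.7,
    beta_G=7.71,
)

#: Default initial states (elderly health, government credibility).
BASELINE_X0 = (1.0, 1.0)


def baseline_scenario() -> GameParameters:
    """The pinned reference parameter set (validated)."""
    return validate_parameters(GameParameters(**_BASELINE))


def default_ranges() -> dict[str, tuple[float, float]]:
    """Uniform sampling intervals: [0.5x, 2x] baseline, rho capped at 1."""
    ranges = {k: (0.5 * v, 2.0 * v) for k, v in _BASELINE.items()}
    ranges["rho"] = (0.45, 1.0)
    return ranges


@dataclass(frozen=True)
class ScenarioSpec:
    """Reproducible recipe for a batch of random admissible scenarios."""

    seed: int
    count: int
    ranges: dict[str, tuple[float, float]] = field(default_factory=default_ranges)
    allow_degenerate: bool = False
    max_tries_per_scenario: int = 1000

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be nonnegative, got {self.count}")
        unknown = set(self.ranges) - set(_BASELINE)
        if unknown:
            raise ValueError(f"unknown parameters in ranges: {sorted(unknown)}")
        missing = set(_BASELINE) - set(self.ranges)
        if missing:
            raise ValueError(f"ranges missing parameters: {sorted(missing)}")


def random_scenarios(spec: ScenarioSpec) -> list[GameParameters]:
    """Draw ``spec.count`` validated parameter sets by rejection sampling.

    Raises ``RuntimeError`` if the ranges are so constrained that a single
    scenario needs more than ``spec.max_tries_per_scenario`` draws.
    """
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.ranges)
    out: list[GameParameters] = []
    while len(out) < spec.count:
        for attempt in range(spec.max_tries_per_scenario):
            draw = {
                name: float(rng.uniform(*spec.ranges[name])) for name in names
            }
            try:
                params = validate_parameters(
                    GameParameters(**draw), allow_degenerate=spec.allow_degenerate
                )
            except ParameterError:
                continue
            out.append(params)
            break
        else:
            raise RuntimeError(
                f"rejection sampling failed: no admissible scenario in "
                f"{spec.max_tries_per_scenario} draws; widen the ranges"
            )
    return out
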