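"""Core domain types and model primitives for the elderly-care differential game.

Two players interact in continuous time over an infinite horizon: the elderly
population (choosing a medical-service level ``M`` and an infection level
``I``) and the government (choosing a resource input ``F``).  The government
can organise medical care for the elderly in one of three modes:

* ``N`` — no special care: baseline treatment efficacy, credibility gain per
  unit resource reduced by queueing losses,
* ``H`` — home medical care: clinicians visit the elderly at home, which
  lowers cross-infection harm by ``alpha1`` and raises efficacy by ``beta_H``
  at an extra cost ``c_H`` on both agents' quadratic cost terms,
* ``G`` — "green channel": a priority in-hospital track that raises the
  per-unit service benefit by ``b_G`` and efficacy by ``beta_G`` at an extra
  cost ``c_G``, without reducing cross-infection.

Each agent maximises a discounted stream of instantaneous utility subject to
a scalar state that relaxes exponentially: elderly health/satisfaction ``x1``
and government credibility ``x2``.  All three modes share a single parametric
family once the mode-specific coefficients are collapsed into
:class:`EffectiveParams`; the rest of the package (equilibrium, verification,
trajectories, analysis) is written against that family.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = [
    "Agent",
    "Controls",
    "EffectiveParams",
    "GameParameters",
    "Mode",
    "ParameterError",
    "StatePoint",
    "credibility_drift",
    "effective_params",
    "elderly_utility_rate",
    "government_utility_rate",
    "health_drift",
    "validate_parameters",
]


class ParameterError(ValueError):
    """A parameter set violates one of the model's admissibility constraints."""


class Mode(str, enum.Enum):
    """The three medical-service modes, in fixed reporting order N < H < G."""

    N = "N"
    H = "H"
    G = "G"

    @property
    def order(self) -> int:
        return "NHG".index(self.value)

    def __lt__(self, other: "Mode") -> bool:  # type: ignore[override]
        return self.order < other.order

    @property
    def label(self) -> str:
        return {
            "N": "no special care",
            "H": "home medical care",
            "G": "green channel",
        }[self.value]


class Agent(str, enum.Enum):
    """The two players of the game."""

    ELDERLY = "elderly"
    GOVERNMENT = "government"


@dataclass(frozen=True)
class GameParameters:
    """Complete parameterisation of one game scenario.

    Every field is a strictly positive rate, cost or benefit except ``rho``,
    which is a discount rate in (0, 1].  The elderly and government state
    decay rates ``delta1`` and ``delta2`` are carried separately (they are
    often set equal); every formula uses the agent-appropriate one.
    """

    rho: float        # discount rate, 0 < rho <= 1
    delta1: float     # decay rate of elderly satisfaction
    delta2: float     # decay rate of government credibility
    b: float          # benefit per unit medical service
    b_G: float        # extra per-unit benefit under the green channel
    l1: float         # welfare weight of the elderly health state
    l2: float         # welfare weight of the credibility state
    c_I: float        # bodily damage per unit infection
    c_M: float        # cost per unit medical service
    c_F: float        # cost per unit government resource
    c_H: float        # extra cost of home care
    c_G: float        # extra cost of the green channel
    alpha1: float     # cross-infection reduction under home care
    lambda1: float    # health damage rate from squared infection
    lambda2: float    # credibility per unit resource
    lambda3: float    # extra credibility-channel rate without special care
    lambda4: float    # queue-induced credibility-loss rate
    lambda_H: float   # extra credibility rate for home care
    lambda_G: float   # extra credibility rate for the green channel
    beta: float       # baseline treatment efficacy
    beta_H: float     # extra efficacy of home care
    beta_G: float     # extra efficacy of the green channel

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "GameParameters":
        """Build from a mapping whose keys exactly match the field names.

        Unknown keys raise :class:`ParameterError`; so do missing ones.
        """
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        missing = known - set(data)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "GameParameters":
        """Load a parameter set from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: expected a mapping of parameter names")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass(frozen=True)
class EffectiveParams:
    """Mode-collapsed coefficients that make all three modes one family.

    ============  =======================  =======================  =======================
    coefficient   N                        H                        G
    ============  =======================  =======================  =======================
    b_eff         b                        b                        b + b_G
    c_inf_eff     c_I                      c_I - alpha1             c_I
    c_treat_eff   c_M                      c_M + c_H                c_M + c_G
    c_gov_eff     c_F                      c_F + c_H                c_F + c_G
    kappa         l2+l3-l4 rates           lambda2 + lambda_H       lambda2 + lambda_G
    log_efficacy  ln(beta + 1)             ln(beta + beta_H + 1)    ln(beta + beta_G + 1)
    ============  =======================  =======================  =======================

    ``kappa`` for N is ``lambda2 + lambda3 - lambda4``.  Discount, decay and
    state-weight parameters pass through unchanged.
    """

    mode: Mode
    b_eff: float
    c_inf_eff: float
    c_treat_eff: float
    c_gov_eff: float
    kappa: float
    log_efficacy: float
    rho: float
    delta1: float
    delta2: float
    l1: float
    l2: float
    lambda1: float


@dataclass(frozen=True)
class StatePoint:
    """A point of the state space: elderly health ``x1``, credibility ``x2``."""

    x1: float
    x2: float
    t: float = 0.0


@dataclass(frozen=True)
class Controls:
    """The control triple: service level M, infection level I, resource input F.

    ``I`` is a control of the elderly agent; its equilibrium value is
    negative under the model's closed form and is reported as-is, without
    clipping (see the methods note for discussion).
    """

    M: float
    I: float
    F: float


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_POSITIVE_FIELDS = (
    ("delta1", "decay rate of elderly satisfaction"),
    ("delta2", "decay rate of government credibility"),
    ("b", "benefit per unit medical service"),
    ("b_G", "extra green-channel benefit"),
    ("l1", "welfare weight of the health state"),
    ("l2", "welfare weight of the credibility state"),
    ("c_I", "damage per unit infection"),
    ("c_M", "cost per unit medical service"),
    ("c_F", "cost per unit government resource"),
    ("alpha1", "cross-infection reduction under home care"),
    ("lambda1", "health damage rate from squared infection"),
    ("lambda2", "credibility per unit resource"),
    ("lambda3", "extra credibility rate without special care"),
    ("lambda4", "queue-induced credibility-loss rate"),
    ("lambda_H", "extra credibility rate for home care"),
    ("lambda_G", "extra credibility rate for the green channel"),
    ("beta", "baseline treatment efficacy"),
    ("beta_H", "extra efficacy of home care"),
    ("beta_G", "extra efficacy of the green channel"),
)


def validate_parameters(
    params: GameParameters, *, allow_degenerate: bool = False
) -> GameParameters:
    """Check every admissibility constraint and return ``params`` unchanged.

    Raises :class:`ParameterError` naming the violated inequality.  With
    ``allow_degenerate=True`` the requirement ``lambda2+lambda3-lambda4 > 0``
    (a positive N-mode credibility-gain rate) is waived for exploration of
    degenerate regimes; every other constraint always applies.
    """
    if not (0.0 < params.rho <= 1.0):
        raise ParameterError(
            f"rho = {params.rho}: discount rate must satisfy 0 < rho <= 1 "
            "(rho = 0 would make the discounted value 1/rho diverge)"
        )
    for name, meaning in _POSITIVE_FIELDS:
        value = getattr(params, name)
        if not (value > 0.0) or not math.isfinite(value):
            raise ParameterError(
                f"{name} = {value}: {meaning} must be strictly positive and finite"
            )
    # extra costs may be zero: a zero extra cost is the left end of every
    # cost curve and collapses the special mode onto the baseline cost
    for name in ("c_H", "c_G"):
        value = getattr(params, name)
        if value < 0.0 or not math.isfinite(value):
            raise ParameterError(
                f"{name} = {value}: extra cost must be nonnegative and finite"
            )
    if params.c_I - params.alpha1 < 0.0:
        raise ParameterError(
            f"c_I - alpha1 = {params.c_I - params.alpha1} < 0: home care cannot "
            "remove more infection harm than infection causes"
        )
    kappa_n = params.lambda2 + params.lambda3 - params.lambda4
    if kappa_n <= 0.0 and not allow_degenerate:
        raise ParameterError(
            f"lambda2 + lambda3 - lambda4 = {kappa_n} <= 0: the no-special-care "
            "credibility-gain rate must be positive (pass allow_degenerate=True "
            "to explore this regime)"
        )
    return params


def effective_params(params: GameParameters, mode: Mode) -> EffectiveParams:
    """Collapse a validated parameter set into the coefficients of one mode."""
    mode = Mode(mode)
    common = dict(
        mode=mode,
        rho=params.rho,
        delta1=params.delta1,
        delta2=params.delta2,
        l1=params.l1,
        l2=params.l2,
        lambda1=params.lambda1,
    )
    if mode is Mode.N:
        return EffectiveParams(
            b_eff=params.b,
            c_inf_eff=params.c_I,
            c_treat_eff=params.c_M,
            c_gov_eff=params.c_F,
            kappa=params.lambda2 + params.lambda3 - params.lambda4,
            log_efficacy=math.log(params.beta + 1.0),
            **common,
        )
    if mode is Mode.H:
        return EffectiveParams(
            b_eff=params.b,
            c_inf_eff=params.c_I - params.alpha1,
            c_treat_eff=params.c_M + params.c_H,
            c_gov_eff=params.c_F + params.c_H,
            kappa=params.lambda2 + params.lambda_H,
            log_efficacy=math.log(params.beta + params.beta_H + 1.0),
            **common,
        )
    return EffectiveParams(
        b_eff=params.b + params.b_G,
        c_inf_eff=params.c_I,
        c_treat_eff=params.c_M + params.c_G,
        c_gov_eff=params.c_F + params.c_G,
        kappa=params.lambda2 + params.lambda_G,
        log_efficacy=math.log(params.beta + params.beta_G + 1.0),
        **common,
    )


# ---------------------------------------------------------------------------
# instantaneous utility rates and state drifts
# ---------------------------------------------------------------------------

def elderly_utility_rate(eff: EffectiveParams, c: Controls, s: StatePoint) -> float:
    """Instantaneous elderly welfare: service benefit minus infection harm and
    quadratic treatment cost, plus the satisfaction carried by the health state.
    """
    return (
        eff.b_eff * c.M
        - eff.c_inf_eff * c.I
        - 0.5 * eff.c_treat_eff * c.M**2
        + eff.l1 * s.x1
    )


def government_utility_rate(eff: EffectiveParams, c: Controls, s: StatePoint) -> float:
    """Instantaneous government welfare: quadratic resource cost plus the
    credibility carried by the state."""
    return -0.5 * eff.c_gov_eff * c.F**2 + eff.l2 * s.x2


def health_drift(eff: EffectiveParams, c: Controls, s: StatePoint) -> float:
    """Rate of change of elderly health: quadratic infection damage, service
    gain at the mode's log-efficacy, exponential decay of satisfaction."""
    return -eff.lambda1 * c.I**2 + eff.log_efficacy * c.M - eff.delta1 * s.x1


def credibility_drift(eff: EffectiveParams, c: Controls, s: StatePoint) -> float:
    """Rate of change of government credibility: resource input times the
    mode's credibility-gain rate, minus exponential decay."""
    return eff.kappa * c.F - eff.delta2 * s.x2
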