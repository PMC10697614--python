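"""End-to-end runs and result serialisation.

:func:`run_full` executes every stage of the analysis for one scenario —
equilibria, HJB verification, trajectories, cost curves, decompositions,
crossovers, rankings and the reference parity table — and returns a plain
dictionary.  :func:`write_report` turns that dictionary into CSV and JSON
files plus a human-readable summary, and returns a manifest of what it
wrote.  Outputs are deterministic: identical scenario, config and seed
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, trajectories, verification
from .config import RunConfig
from .equilibrium import equilibrium_record, evaluate_value, value_function
from .model import Agent, GameParameters, Mode, StatePoint
from .scenarios import ScenarioSpec, random_scenarios

__all__ = ["reference_parity", "run_full", "write_report"]

# Reference two-decimal values from the published numerical example, used
# only for the parity table in the generated report.  Each entry:
# (label, reference value, getter name, kwargs, note or None).
_REFERENCE_SWEEPS = [
    ("home-care elderly constant K0 at alpha1=0.5", 1.28,
     dict(mode="H", agent="elderly", override={"alpha1": 0.5}, quantity="K0"), None),
    ("home-care elderly constant K0 at alpha1=1", 1.07,
     dict(mode="H", agent="elderly", override={"alpha1": 1.0}, quantity="K0"), None),
    ("home-care elderly coefficient K1", 23.44,
     dict(mode="H", agent="elderly", override={}, quantity="K1"),
     "reference rounds the intermediate logarithm; exact recomputation gives 23.49"),
    ("green-channel elderly coefficient K1 at b_G=1", 23.47,
     dict(mode="G", agent="elderly", override={"b_G": 1.0}, quantity="K1"), None),
    ("green-channel elderly coefficient K1 at b_G=0.5", 20.0,
     dict(mode="G", agent="elderly", override={"b_G": 0.5}, quantity="K1"), None),
    ("green-channel elderly constant K0", 1.0,
     dict(mode="G", agent="elderly", override={}, quantity="K0",
          reproducible=False),
     "reported constant 1 is not reproducible from the closed-form value "
     "function, which gives 1.625 at the baseline; the closed form is kept"),
    ("home-care government coefficient K1 at lambda_H=0.3", 0.94,
     dict(mode="H", agent="government", override={"lambda_H": 0.3}, quantity="K1"), None),
    ("home-care government coefficient K1 at lambda_H=0.5", 1.25,
     dict(mode="H", agent="government", override={"lambda_H": 0.5}, quantity="K1"), None),
    ("green-channel government coefficient K1 at lambda_G=0.3", 0.94,
     dict(mode="G", agent="government", override={"lambda_G": 0.3}, quantity="K1"), None),
    ("green-channel government coefficient K1 at lambda_G=0.4", 1.09,
     dict(mode="G", agent="government", override={"lambda_G": 0.4}, quantity="K1"), None),
]


def reference_parity(params: GameParameters, x0: StatePoint) -> list[dict]:
    """Computed-versus-reference table for the published two-decimal values.

    Rows whose reference cannot be reproduced from the closed forms are
    flagged with ``match = False`` and an explanatory note; the computed
    value is canonical throughout the package.
    """
    rows = []
    v_n2 = evaluate_value(value_function(params, Mode.N, Agent.GOVERNMENT), x0)
    rows.append(
        {
            "label": "no-special-care government value at x2=1",
            "reference": 1.278,
            "computed": v_n2,
            "match": abs(round(v_n2, 3) - 1.278) < 5e-4,
            "note": None,
        }
    )
    v_n1 = evaluate_value(value_function(params, Mode.N, Agent.ELDERLY), x0)
    rows.append(
        {
            "label": "elderly value at the baseline example",
            "reference": 6.63,
            "computed": v_n1,
            "match": False,
            "note": "reported value 6.63 is not reproducible from the stated "
            "closed forms; recomputation gives about 7.255, which the package "
            "treats as canonical",
        }
    )
    for label, ref, spec, note in _REFERENCE_SWEEPS:
        p = dataclasses.replace(params, **spec["override"])
        dec = analysis.affine_in_inverse_cost(
            p, Mode(spec["mode"]), Agent(spec["agent"]), x0
        )
        computed = getattr(dec, spec["quantity"])
        if spec.get("reproducible", True):
            tol = 0.005 * ref if spec["quantity"] == "K1" else 5e-3
            match = bool(abs(computed - ref) <= max(tol, 5e-3))
        else:
            match = False
        rows.append(
            {
                "label": label,
                "reference": ref,
                "computed": computed,
                "match": match,
                "note": note,
            }
        )
    return rows


def run_full(params: GameParameters, config: RunConfig) -> dict:
    """Execute every analysis stage for one scenario; return a results dict."""
    x0 = StatePoint(x1=config.x0[0], x2=config.x0[1])
    cost_grid = np.linspace(*config.cost_grid[:2], int(config.cost_grid[2]))
    state_grid = np.linspace(*config.state_grid[:2], int(config.state_grid[2]))

    results: dict = {"config": config.to_dict(), "params": params.to_dict()}
    results["equilibrium"] = [
        equilibrium_record(params, mode, ndigits=config.round_decimals)
        for mode in Mode
        if mode.value in config.modes
    ]
    results["residuals"] = [
        verification.hjb_residual(params, mode, agent, state_grid).to_dict()
        for mode in Mode
        if mode.value in config.modes
        for agent in Agent
        if agent.value in config.agents
    ]
    results["trajectories"] = {}
    for mode in Mode:
        if mode.value not in config.modes:
            continue
        traj = trajectories.simulate(params, mode, x0, config.horizon, config.step)
        results["trajectories"][mode.value] = pd.DataFrame(
            {
                "t": traj.times,
                "x1": traj.x1_path,
                "x2": traj.x2_path,
                "M": traj.controls.M,
                "I": traj.controls.I,
                "F": traj.controls.F,
            }
        )
    results["welfare"] = {
        mode.value: trajectories.discounted_welfare(params, mode, x0, config.tolerance)
        for mode in Mode
        if mode.value in config.modes
    }
    results["curves"] = {}
    results["decompositions"] = []
    results["crossovers"] = []
    for mode in (Mode.H, Mode.G):
        if mode.value not in config.modes:
            continue
        for agent in Agent:
            if agent.value not in config.agents:
                continue
            curve = analysis.cost_curve(params, mode, agent, cost_grid, x0)
            results["curves"][f"{mode.value}_{agent.value}"] = pd.DataFrame(
                {
                    "extra_cost": curve.grid,
                    "value": curve.values,
                    "baseline": curve.baseline,
                }
            )
            dec = analysis.affine_in_inverse_cost(params, mode, agent, x0)
            results["decompositions"].append(dec.to_dict())
            results["crossovers"].append(
                {
                    "mode": mode.value,
                    "agent": agent.value,
                    "crossover": curve.crossover,
                }
            )
    results["ranking"] = {
        agent.value: [m.value for m in modes]
        for agent, modes in analysis.recommend_mode(
            params, params.c_H, params.c_G, x0
        ).items()
    }
    results["parity"] = reference_parity(params, x0)
    results["seed"] = config.seed
    return results


def _summary_text(results: dict) -> str:
    lines = ["Elderly-care differential game: run summary", ""]
    lines.append(f"seed: {results.get('seed')}")
    for rec in results.get("equilibrium", []):
        c = rec["controls"]
        lines.append(
            f"mode {rec['mode']}: M*={c['M']:.4f} I*={c['I']:.4f} F*={c['F']:.4f}  "
            f"V1(x)={rec['elderly']['slope']:.4f}x+{rec['elderly']['intercept']:.4f}  "
            f"V2(x)={rec['government']['slope']:.4f}x+{rec['government']['intercept']:.4f}"
        )
    if results.get("crossovers"):
        lines.append("")
        lines.append("crossover extra costs (special-care value meets no-special-care):")
        for row in results["crossovers"]:
            c = row["crossover"]
            lines.append(
                f"  mode {row['mode']}, {row['agent']}: "
                + ("never crosses" if c is None else f"{c:.4f}")
            )
    if results.get("parity"):
        lines.append("")
        lines.append("reference parity (computed vs published two-decimal values):")
        for row in results["parity"]:
            flag = "ok " if row["match"] else "FLAG"
            lines.append(
                f"  [{flag}] {row['label']}: reference {row['reference']} "
                f"computed {row['computed']:.4f}"
            )
            if row["note"]:
                lines.append(f"         note: {row['note']}")
    lines.append("")
    return "\n".join(lines)


def write_report(results: dict, output_dir: str | Path) -> list[str]:
    """Write CSVs, JSONs and a summary; return the manifest of files written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def write_json(name: str, obj) -> None:
        (out / name).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        manifest.append(name)

    def write_csv(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, index=False, float_format="%.17g", lineterminator="\n")
        manifest.append(name)

    for key in ("equilibrium", "residuals", "decompositions", "crossovers",
                "ranking", "parity", "welfare", "params", "config"):
        if key in results:
            write_json(f"{key}.json", results[key])
    for name, df in results.get("curves", {}).items():
        write_csv(f"curve_{name}.csv", df)
    for name, df in results.get("trajectories", {}).items():
        write_csv(f"trajectory_{name}.csv", df)
    (out / "summary.txt").write_text(_summary_text(results))
    manifest.append("summary.txt")
    (out / "manifest.json").write_text(
        json.dumps(sorted(manifest), indent=2) + "\n"
    )
    manifest.append("manifest.json")
    return sorted(manifest)


def scenario_batch(seed: int, count: int) -> list[GameParameters]:
    """Convenience wrapper: seeded batch of admissible random scenarios."""
    return random_scenarios(ScenarioSpec(seed=seed, count=count))
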