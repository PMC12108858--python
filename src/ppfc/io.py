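"""Model/report serialization: JSON for configs and reports, CSV for
trajectories and fields.

Model JSON layout::

    {
      "omega": 2.0,
      "coefficients": {
        "r1": {"const": 22.0, "terms": [{"fn": "cos", "amp": 1.0, "freq": 3.14159}]},
        ...
      },
      "delays": {"tau11": 0.001, ..., "tau43": 0.006}
    }

Floats in reports are serialized at full precision (repr round-trips in
Python 3) so downstream comparisons are reproducible; a 4-decimal display
value accompanies each bound/criterion for readability.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .coefficients import PeriodicCoefficient, TrigTerm
from .dde import STATE_NAMES, HistoryFunctions, Trajectory
from .model import COEFFICIENT_NAMES, DELAY_NAMES, DelaySet, ModelParameters
from .pde import SpacetimeSolution
from .permanence import PermanenceBounds
from .stability import StabilityReport

__all__ = [
    "load_model",
    "save_model",
    "load_history",
    "write_bounds_report",
    "write_stability_report",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_fields_csv",
    "ModelFileError",
]


class ModelFileError(ValueError):
    """Schema problem in a model/config file, with the offending key named."""


def _coef_to_json(c: PeriodicCoefficient) -> dict:
    out: dict = {"const": c.constant_term}
    if c.trig_terms:
        out["terms"] = [
            {"fn": t.kind, "amp": t.amplitude, "freq": t.angular_frequency}
            for t in c.trig_terms
        ]
    if c.period is not None:
        out["period"] = c.period
    return out


def _coef_from_json(name: str, block: dict) -> PeriodicCoefficient:
    if not isinstance(block, dict) or "const" not in block:
        raise ModelFileError(f"coefficient {name}: need an object with 'const'")
    terms = []
    for j, term in enumerate(block.get("terms", [])):
        try:
            terms.append(TrigTerm(term["fn"], float(term["amp"]), float(term["freq"])))
        except (KeyError, ValueError, TypeError) as exc:
            raise ModelFileError(f"coefficient {name}, term {j}: {exc}") from exc
    return PeriodicCoefficient(
        constant_term=float(block["const"]),
        trig_terms=tuple(terms),
        period=block.get("period"),
    )


def save_model(params: ModelParameters, path: str | Path) -> None:
    doc = {
        "omega": params.omega,
        "coefficients": {
            n: _coef_to_json(params.coefficients[n]) for n in COEFFICIENT_NAMES
        },
        "delays": params.delays.as_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> ModelParameters:
    """Load and validate a model JSON file."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if "coefficients" not in doc:
        raise ModelFileError(f"{path}: missing 'coefficients' block")
    blocks = doc["coefficients"]
    missing = [n for n in COEFFICIENT_NAMES if n not in blocks]
    if missing:
        raise ModelFileError(
            f"{path}: missing coefficient blocks: {', '.join(missing)}"
        )
    coefs = {n: _coef_from_json(n, blocks[n]) for n in COEFFICIENT_NAMES}
    delays_doc = doc.get("delays", {})
    missing_delays = [n for n in DELAY_NAMES if n not in delays_doc]
    if missing_delays:
        raise ModelFileError(
            f"{path}: delays block is missing: {', '.join(missing_delays)}"
        )
    delays = DelaySet(**{n: float(delays_doc[n]) for n in DELAY_NAMES})
    omega = float(doc.get("omega", 1.0))
    params = ModelParameters(coefficients=coefs, delays=delays, omega=omega)
    report = params.validate()
    if not report.valid:
        raise ModelFileError(f"{path}: {report}")
    return params


def load_history(path: str | Path) -> HistoryFunctions:
    """Constant-history JSON: ``{"v": [..4 values..], "u": [..4 values..]}``."""
    doc = json.loads(Path(path).read_text())
    try:
        values = [float(x) for x in doc["v"]] + [float(x) for x in doc["u"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFileError(f"{path}: need 'v' and 'u' lists of 4 numbers") from exc
    if len(doc["v"]) != 4 or len(doc["u"]) != 4:
        raise ModelFileError(f"{path}: 'v' and 'u' must each hold 4 values")
    return HistoryFunctions.constant(values)


def _display(x) -> float | None:
    return None if x is None else round(float(x), 4)


def write_bounds_report(
    bounds: PermanenceBounds, criteria, path: str | Path
) -> dict:
    """JSON report of the permanence constants and H1–H10."""
    doc = {
        "bounds": {k: v for k, v in asdict(bounds).items()},
        "bounds_display": {k: _display(v) for k, v in asdict(bounds).items()},
        "criteria": [
            {
                "name": c.name,
                "value": c.value,
                "value_display": _display(c.value),
                "satisfied": c.satisfied,
                "expression": c.description,
            }
            for c in criteria
        ],
        "all_satisfied": all(c.satisfied for c in criteria),
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def write_stability_report(report: StabilityReport, path: str | Path) -> dict:
    """JSON report of A1–A4, B1–B4, H1–H18 and the overall verdict."""
    def crit_doc(c):
        return {
            "name": c.name,
            "value": c.value,
            "value_display": _display(c.value),
            "satisfied": c.satisfied,
            "expression": c.description,
        }

    doc = {
        "A": {f"A{i+1}": report.A[i] for i in range(4)},
        "B": {f"B{i+1}": report.B[i] for i in range(4)},
        "A_display": {f"A{i+1}": _display(report.A[i]) for i in range(4)},
        "B_display": {f"B{i+1}": _display(report.B[i]) for i in range(4)},
        "permanence_criteria": [crit_doc(c) for c in report.permanence_criteria],
        "stability_criteria": [crit_doc(c) for c in report.criteria],
        "bounds": {k: v for k, v in asdict(report.bounds).items()},
        "prerequisites_ok": report.prerequisites_ok,
        "verdict": report.verdict,
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    header = "t," + ",".join(STATE_NAMES)
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.17g")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    times = data[:, 0]
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    return Trajectory(times=times, states=data[:, 1:], dt=dt)


def write_fields_csv(
    sol: SpacetimeSolution, path: str | Path, stride: int = 1
) -> None:
    """Long-format CSV: ``t, x, channel, value`` (optionally strided in time)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "x", "channel", "value"])
        x = sol.grid.nodes
        for it in range(0, len(sol.times), stride):
            t = sol.times[it]
            for ch, name in enumerate(STATE_NAMES):
                for ix in range(sol.grid.n_nodes):
                    writer.writerow(
                        [f"{t:.17g}", f"{x[ix]:.17g}", name,
                         f"{sol.fields[it, ch, ix]:.17g}"]
                    )
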