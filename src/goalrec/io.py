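"""JSON scenario schema and tabular result output.

A scenario document is::

    {
      "start": [x, y],
      "goals": [[x, y], ...],
      "trajectories": [
        {"goal_id": 1, "curve_index": 1, "points": [[x, y], ...]},
        ...
      ]
    }

Goal ids are 1-based indices into ``goals``.  Tabular results are CSV with
a provenance header comment (version, config hash, seed) that pandas skips
with ``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scenario import Scenario, Trajectory

__all__ = [
    "SchemaError",
    "scenario_to_dict",
    "scenario_from_dict",
    "read_scenario",
    "write_scenario",
    "write_table",
    "config_hash",
]


class SchemaError(ValueError):
    """Scenario document violates the schema; lists the offending fields."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid scenario document: " + "; ".join(problems))


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "start": [float(v) for v in scenario.start],
        "goals": [[float(v) for v in g] for g in scenario.goals],
        "trajectories": [
            {
                "goal_id": t.goal_id,
                "curve_index": t.curve_index,
                "points": [[float(x), float(y)] for x, y in t.points],
            }
            for t in scenario.all_trajectories()
        ],
    }


def _check_point(value, field: str, problems: list[str]) -> bool:
    ok = (
        isinstance(value, (list, tuple))
        and len(value) == 2
        and all(isinstance(v, (int, float)) and np.isfinite(v) for v in value)
    )
    if not ok:
        problems.append(f"{field}: expected a finite [x, y] pair")
    return ok


def scenario_from_dict(doc: dict) -> Scenario:
    problems: list[str] = []
    if not isinstance(doc, dict):
        raise SchemaError(["document: expected a JSON object"])
    start = doc.get("start")
    _check_point(start, "start", problems)
    goals = doc.get("goals")
    if not isinstance(goals, list) or len(goals) < 2:
        problems.append("goals: expected a list of >= 2 points")
    else:
        for i, g in enumerate(goals):
            _check_point(g, f"goals[{i}]", problems)
    trajs = doc.get("trajectories")
    if not isinstance(trajs, list):
        problems.append("trajectories: expected a list")
        trajs = []
    parsed = []
    for i, td in enumerate(trajs):
        if not isinstance(td, dict):
            problems.append(f"trajectories[{i}]: expected an object")
            continue
        missing = [k for k in ("goal_id", "curve_index", "points") if k not in td]
        if missing:
            problems.append(f"trajectories[{i}]: missing fields {missing}")
            continue
        if not isinstance(td["goal_id"], int) or not (
            isinstance(goals, list) and 1 <= td["goal_id"] <= len(goals)
        ):
            problems.append(f"trajectories[{i}].goal_id: must index a goal (1-based)")
            continue
        if not isinstance(td["curve_index"], int) or td["curve_index"] < 1:
            problems.append(f"trajectories[{i}].curve_index: must be a positive integer")
            continue
        pts = td["points"]
        if (
            not isinstance(pts, list)
            or len(pts) < 1
            or not all(_check_point(p, f"trajectories[{i}].points[{j}]", []) for j, p in enumerate(pts))
        ):
            problems.append(f"trajectories[{i}].points: expected a non-empty list of [x, y] pairs")
            continue
        parsed.append(td)
    if problems:
        raise SchemaError(problems)

    scenario = Scenario(start=np.array(start), goals=[np.array(g) for g in goals])
    library: dict[int, list[Trajectory]] = {gid: [] for gid in scenario.goal_ids}
    for td in parsed:
        library[td["goal_id"]].append(
            Trajectory(
                points=np.array(td["points"], dtype=float),
                goal_id=td["goal_id"],
                curve_index=td["curve_index"],
            )
        )
    for gid in library:
        library[gid].sort(key=Trajectory.key)
    scenario.library = library
    return scenario


def read_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(json.load(fh))


def write_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(json.dumps(scenario_to_dict(scenario), indent=1))


def config_hash(config: dict) -> str:
    """Short stable hash of a run configuration, for provenance headers."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config: dict | None = None, seed=None) -> None:
    """Write a result table as CSV with a provenance header comment."""
    config = config or {}
    header = (
        f"# goalrec {__version__} config={config_hash(config)} seed={seed}\n"
        f"# config: {json.dumps(config, sort_keys=True, default=str)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
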