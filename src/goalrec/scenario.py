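"""Synthetic two-goal scenarios with plan libraries of curved trajectories.

The default scenario emulates the layout of the robot-arm goal-recognition
study this package models: a single start point facing two goals equidistant
from it, and a plan library of 7 trajectories per goal ranging from the
straight (optimal) plan to strongly curved, inefficient ones.  Trajectories
are numbered by their distance from the *distractor* goal (the goal they do
not reach): index 1 is closest to the distractor, index 7 farthest.  Because
every curved trajectory bows to the same lateral side, the straight plan is
index 1 for one goal and index 7 for the other.

One trajectory pair to *different* goals is built to share an identical
initial segment, reproducing the qualitative overlap structure that makes
early observations ambiguous for library-based recognizers.

Trajectory shapes are quadratic Bezier curves with laterally offset control
points — a parametric stand-in that reproduces the ordinal structure of the
original apparatus (curvature ranking, one optimal plan per goal, early
cross-goal overlap) without claiming coordinate fidelity to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import arclength, as_point, as_polyline, optimal_cost, prefix, prefix_match

__all__ = [
    "Trajectory",
    "Scenario",
    "make_berkovitz_scenario",
    "overlapping_pairs",
    "sample_library",
    "generate_observations",
    "observation_fractions",
]

# fraction of the library default tolerance relative to the scenario diameter
TOL_DIAMETER_FACTOR = 1e-6


@dataclass(frozen=True, eq=False)
class Trajectory:
    """A library plan: a polyline from the start to one goal.

    ``curve_index`` ranks trajectories of the same goal by mean distance
    from the distractor goal (1 = closest, n = farthest).
    """

    points: np.ndarray
    goal_id: int
    curve_index: int

    def __post_init__(self):
        object.__setattr__(self, "points", as_polyline(self.points))

    @property
    def polyline(self) -> np.ndarray:
        return self.points

    @property
    def cost(self) -> float:
        return arclength(self.points)

    def key(self) -> tuple[int, int]:
        return (self.goal_id, self.curve_index)


@dataclass
class Scenario:
    """Start point, goal points, and a plan library partitioned by goal."""

    start: np.ndarray
    goals: list[np.ndarray]
    library: dict[int, list[Trajectory]] = field(default_factory=dict)

    def __post_init__(self):
        self.start = as_point(self.start)
        self.goals = [as_point(g) for g in self.goals]
        if len(self.goals) < 2:
            raise ValueError("a scenario needs at least 2 goals")
        for g in self.goals:
            if np.allclose(g, self.start):
                raise ValueError("goals must be distinct from the start point")

    @property
    def goal_ids(self) -> list[int]:
        return list(range(1, len(self.goals) + 1))

    def goal_point(self, goal_id: int) -> np.ndarray:
        return self.goals[goal_id - 1]

    def all_trajectories(self) -> list[Trajectory]:
        out: list[Trajectory] = []
        for gid in sorted(self.library):
            out.extend(self.library[gid])
        return out

    @property
    def diameter(self) -> float:
        pts = np.vstack([self.start] + self.goals)
        return float(
            max(np.linalg.norm(a - b) for i, a in enumerate(pts) for b in pts[i + 1:])
        )

    @property
    def default_tol(self) -> float:
        """Default prefix-match tolerance: a fixed fraction of the diameter."""
        return TOL_DIAMETER_FACTOR * self.diameter


def _bezier(p0, ctrl, p1, n_points: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n_points)[:, None]
    p0, ctrl, p1 = (np.asarray(p, dtype=float) for p in (p0, ctrl, p1))
    return (1 - u) ** 2 * p0 + 2 * u * (1 - u) * ctrl + u**2 * p1


def _mean_distance(points: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean(np.linalg.norm(points - target, axis=1)))


def make_berkovitz_scenario(
    span: float = 6.0,
    depth: float = 10.0,
    n_per_goal: int = 7,
    curvature_scale: float = 1.0,
    n_points: int = 200,
    overlap_fraction: float = 0.2,
) -> Scenario:
    """Build the default two-goal scenario with ``2 * n_per_goal`` trajectories.

    The start sits at the origin; the goals at ``(-span/2, depth)`` and
    ``(span/2, depth)`` are equidistant from it.  Curved trajectories are
    quadratic Beziers whose control points are offset increasingly toward
    +x, scaled by ``curvature_scale``.  For ``n_per_goal >= 2`` one of goal
    1's trajectories is a composite that follows the initial
    ``overlap_fraction`` of goal 2's least-curved non-straight plan exactly
    before curving off to goal 1, giving the cross-goal early overlap.

    Parameters
    ----------
    span : horizontal separation of the goals (length units).
    depth : vertical distance from start to the goal line.
    n_per_goal : trajectories per goal (default 7, i.e. 14 total).
    curvature_scale : multiplies every lateral control-point offset.
    n_points : points per discretized trajectory (>= 100 recommended).
    overlap_fraction : arclength fraction of the donor plan shared by the
        composite trajectory.
    """
    if span <= 0 or depth <= 0:
        raise ValueError("span and depth must be positive")
    if n_per_goal < 1:
        raise ValueError("n_per_goal must be >= 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    start = np.zeros(2)
    g1 = np.array([-span / 2.0, depth])
    g2 = np.array([span / 2.0, depth])
    scenario = Scenario(start=start, goals=[g1, g2])

    offsets = [curvature_scale * span * k / 3.0 for k in range(n_per_goal)]

    def family(goal: np.ndarray, offs) -> list[np.ndarray]:
        mid = (start + goal) / 2.0
        out = []
        for off in offs:
            if off == 0.0:
                out.append(np.linspace(start, goal, n_points))
            else:
                out.append(_bezier(start, mid + np.array([off, 0.0]), goal, n_points))
        return out

    curves_g2 = family(g2, offsets)

    if n_per_goal == 1:
        curves_g1 = family(g1, [0.0])
    else:
        # goal 1: straight plan, n-2 bowed Beziers, and the composite that
        # shadows goal 2's least-curved non-straight plan early on
        curves_g1 = family(g1, offsets[: n_per_goal - 1])
        donor = curves_g2[1]
        shared = prefix(donor, overlap_fraction)
        branch = shared[-1]
        tangent = shared[-1] - shared[-2]
        tangent = tangent / np.linalg.norm(tangent)
        ctrl = branch + tangent * 0.5 * optimal_cost(branch, g1)
        tail = _bezier(branch, ctrl, g1, n_points)
        curves_g1.append(np.vstack([shared, tail[1:]]))

    library: dict[int, list[Trajectory]] = {}
    for gid, curves in ((1, curves_g1), (2, curves_g2)):
        distractor = scenario.goal_point(2 if gid == 1 else 1)
        dists = [_mean_distance(c, distractor) for c in curves]
        order = np.argsort(dists)
        sorted_d = np.sort(dists)
        if np.any(np.diff(sorted_d) <= 0):
            raise ValueError(
                "curvature family is degenerate: mean distances from the "
                "distractor are not strictly ordered; increase curvature_scale"
            )
        library[gid] = [
            Trajectory(points=curves[j], goal_id=gid, curve_index=rank + 1)
            for rank, j in enumerate(order)
        ]
    scenario.library = library

    if n_per_goal >= 2 and not overlapping_pairs(scenario):
        raise ValueError(
            "overlap construction failed: no cross-goal trajectory pair "
            "shares an early prefix"
        )
    return scenario


def overlapping_pairs(scenario: Scenario, probe_fraction: float = 0.15,
                      tol: float | None = None) -> list[tuple[Trajectory, Trajectory]]:
    """Cross-goal trajectory pairs whose early prefixes coincide.

    Returns pairs ``(a, b)`` with different goals where
    ``prefix(a, probe_fraction)`` spatially matches ``b``.
    """
    tol = scenario.default_tol if tol is None else tol
    pairs = []
    trajs = scenario.all_trajectories()
    for a in trajs:
        pa = prefix(a.points, probe_fraction)
        for b in trajs:
            if b.goal_id != a.goal_id and prefix_match(pa, b.points, tol):
                pairs.append((a, b))
    return pairs


def sample_library(
    scenario: Scenario,
    size: int,
    exclude: Trajectory,
    seed: int,
) -> dict[int, list[Trajectory]]:
    """Uniformly sample a sub-library of ``size`` plans, holding one out.

    Draws from the scenario library minus ``exclude``, rejection-sampling
    until every goal is represented by at least one plan.  Deterministic
    given ``seed``.
    """
    n_goals = len(scenario.goals)
    pool = [t for t in scenario.all_trajectories() if t.key() != exclude.key()]
    if not any(t.key() == exclude.key() for t in scenario.all_trajectories()):
        raise ValueError("excluded trajectory is not in the scenario library")
    if size < n_goals:
        raise ValueError(
            f"library size {size} cannot represent all {n_goals} goals"
        )
    if size > len(pool):
        raise ValueError(f"library size {size} exceeds the {len(pool)} available plans")

    rng = np.random.default_rng(seed)
    while True:
        idx = rng.choice(len(pool), size=size, replace=False)
        chosen = [pool[i] for i in idx]
        if len({t.goal_id for t in chosen}) == n_goals:
            break
    out: dict[int, list[Trajectory]] = {gid: [] for gid in scenario.goal_ids}
    for t in sorted(chosen, key=Trajectory.key):
        out[t.goal_id].append(t)
    return out


def observation_fractions(step_fraction: float) -> np.ndarray:
    """The observed-length grid: step, 2*step, ..., 1.0."""
    if not 0.0 < step_fraction <= 1.0:
        raise ValueError(f"step_fraction must be in (0, 1], got {step_fraction}")
    m = int(np.ceil(round(1.0 / step_fraction, 9)))
    return np.minimum(np.arange(1, m + 1) * step_fraction, 1.0)


def generate_observations(trajectory: Trajectory, step_fraction: float = 0.02) -> list[np.ndarray]:
    """Incremental observation prefixes of one trajectory.

    Prefixes are taken at arclength fractions ``step, 2*step, ..., 1.0``;
    the final element is the full trajectory.
    """
    pts = trajectory.points if isinstance(trajectory, Trajectory) else as_polyline(trajectory)
    return [prefix(pts, f) for f in observation_fractions(step_fraction)]
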