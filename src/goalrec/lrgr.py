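"""Library-based Rational Goal Recognition (LRGR).

LRGR scores each goal by matching the observation against the goal's known
plans and rating the rationality of the best match:

* if the observation is a spatial prefix of a library plan ``t``, the
  matching score is M(t) = 1;
* otherwise an ad-hoc plan is hypothesized that follows the observations,
  detours to the closest point ``w`` on ``t``, and continues optimally from
  ``w`` to the goal.  Its cost is
  ``C = cost(o) + cost(Q, w) + cost(w, g)`` (``Q`` the last observed point),
  and ``M(t) = cost(optimal plan to g) / C``;
* when no close plan exists — the goal has no library plans, or the closest
  point exceeds a distance cutoff — the closest plan is taken to be the
  observed one itself (``w = Q``, approach cost 0), which makes the score
  identical to the mirroring ratio.

A goal's score is the maximum M over its plans; scores are normalized over
goals into a posterior.  With an empty library LRGR therefore reduces
exactly to the mirroring recognizer; with a library, observations that
prefix-match plans toward several goals spread probability over all of
them, modeling the observer's confusion at overlapping plans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    arclength,
    as_polyline,
    batch_prefix_state,
    closest_point,
    last_point,
    optimal_cost,
    prefix_cuts,
    prefix_match,
)
from .recognizers import GoalPosterior, _check_anchored
from .scenario import Scenario, Trajectory

__all__ = ["MatchingScore", "matching_score", "lrgr_posterior", "lrgr_series"]


@dataclass(frozen=True)
class MatchingScore:
    """Score of one library plan against an observation.

    ``M`` is in (0, 1]; M = 1 iff the observation directly prefix-matches
    the plan or the ad-hoc detour plan is itself optimal.  ``via_point`` is
    the closest-point waypoint used by the detour, absent for a direct
    match or when the cutoff suppressed it.
    """

    trajectory: Trajectory | None
    M: float
    via_point: np.ndarray | None = None


def _detour_score(scenario: Scenario, goal_id: int, o: np.ndarray,
                  w: np.ndarray | None) -> float:
    """M for the ad-hoc plan through waypoint ``w`` (None = fall back to Q)."""
    q = last_point(o)
    g = scenario.goal_point(goal_id)
    approach = 0.0 if w is None else optimal_cost(q, w)
    through = q if w is None else w
    c = arclength(o) + approach + optimal_cost(through, g)
    return optimal_cost(scenario.start, g) / c


def matching_score(
    scenario: Scenario,
    library: dict[int, list[Trajectory]],
    goal_id: int,
    trajectory: Trajectory,
    o,
    cutoff: float | None = None,
    tol: float | None = None,
) -> MatchingScore:
    """Score one library plan of ``goal_id`` against observation ``o``."""
    if not any(t is trajectory or t.key() == trajectory.key()
               for t in library.get(goal_id, [])):
        raise ValueError("trajectory is not in the library partition for this goal")
    o = as_polyline(o)
    _check_anchored(scenario, o, tol)
    tol = scenario.default_tol if tol is None else tol
    if prefix_match(o, trajectory.points, tol):
        return MatchingScore(trajectory=trajectory, M=1.0)
    w = closest_point(last_point(o), trajectory.points, cutoff)
    return MatchingScore(
        trajectory=trajectory,
        M=_detour_score(scenario, goal_id, o, w),
        via_point=w,
    )


def lrgr_posterior(
    scenario: Scenario,
    library: dict[int, list[Trajectory]],
    o,
    cutoff: float | None = None,
    tol: float | None = None,
    include_optimal: bool = False,
) -> GoalPosterior:
    """Goal posterior of the LRGR algorithm.

    Parameters
    ----------
    library : plan library partitioned by goal id; goals absent or empty
        fall back to the rationality-only (mirroring) score.
    cutoff : maximum distance for the closest-point detour; beyond it the
        observed plan itself is the closest plan.  None = unbounded.
    tol : prefix-match tolerance; defaults to the scenario tolerance.
    include_optimal : also score the straight optimal plan to each goal as
        a virtual library member (sensitivity analysis; off by default —
        only actual library plans are scored).
    """
    o = as_polyline(o)
    _check_anchored(scenario, o, tol)
    scores: dict[int, float] = {}
    for g in scenario.goal_ids:
        plans = list(library.get(g, []))
        if include_optimal:
            plans.append(
                Trajectory(
                    points=np.vstack([scenario.start, scenario.goal_point(g)]),
                    goal_id=g,
                    curve_index=0,
                )
            )
        if not plans:
            scores[g] = _detour_score(scenario, g, o, None)
            continue
        best = 0.0
        eff_tol = scenario.default_tol if tol is None else tol
        for t in plans:
            if prefix_match(o, t.points, eff_tol):
                best = 1.0
                break
            w = closest_point(last_point(o), t.points, cutoff)
            best = max(best, _detour_score(scenario, g, o, w))
        scores[g] = best
    return GoalPosterior.from_scores(scores)


def lrgr_series(
    scenario: Scenario,
    library: dict[int, list[Trajectory]],
    trajectory: Trajectory,
    fractions: np.ndarray,
    cutoff: float | None = None,
    tol: float | None = None,
) -> list[GoalPosterior]:
    """LRGR posteriors at every observation prefix of one trajectory.

    Numerically equivalent to calling :func:`lrgr_posterior` on each prefix
    (same projections, same costs), but projects each observed point onto
    each library plan once for the whole series instead of once per prefix.
    """
    obs = as_polyline(trajectory.points if isinstance(trajectory, Trajectory) else trajectory)
    _check_anchored(scenario, obs, tol)
    eff_tol = scenario.default_tol if tol is None else tol
    fractions = np.asarray(fractions, dtype=float)
    idx, cuts = prefix_cuts(obs, fractions)
    obs_len = fractions * arclength(obs)

    n = len(fractions)
    scores = {}
    for g in scenario.goal_ids:
        gp = scenario.goal_point(g)
        opt = optimal_cost(scenario.start, gp)
        d_cut_goal = np.linalg.norm(cuts - gp, axis=1)
        plans = library.get(g, [])
        if not plans:
            scores[g] = opt / (obs_len + d_cut_goal)
            continue
        best = np.zeros(n)
        for t in plans:
            matched, d_cut, proj_cut = batch_prefix_state(
                obs, idx, cuts, t.points, eff_tol
            )
            if cutoff is not None:
                use = d_cut <= cutoff
                approach = np.where(use, d_cut, 0.0)
                through_goal = np.where(
                    use, np.linalg.norm(proj_cut - gp, axis=1), d_cut_goal
                )
            else:
                approach = d_cut
                through_goal = np.linalg.norm(proj_cut - gp, axis=1)
            m = opt / (obs_len + approach + through_goal)
            best = np.maximum(best, np.where(matched, 1.0, m))
        scores[g] = best
    total = sum(scores.values())
    return [
        GoalPosterior({g: float(scores[g][k] / total[k]) for g in scenario.goal_ids})
        for k in range(n)
    ]
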