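"""Rationality-based goal recognizers (RGR) for continuous 2D motion.

Each recognizer maps an observation prefix ``o`` (a polyline starting at the
scenario start ``S``, with last point ``Q``) to a probability distribution
over the scenario's goals.  All of them ignore the plan library and rank
goals by how *rational* (cost-efficient) the observed motion is with respect
to each goal, under the shared cost model: costs are Euclidean arclengths,
the optimal plan between two points is the straight segment.

Four published formulations are implemented:

* ``ramirez_geffner`` — P(g|o) proportional to exp(-(C(g,o) - C(g,o-bar))),
  comparing the optimal observation-matching plan against the optimal plan
  constrained *not* to match the observations.
* ``mirroring`` — P(g|o) proportional to C(g) / C(g,o), the ratio of the
  optimal plan cost to the cost of the cheapest plan through the
  observations.
* ``masters_sardina`` — a per-goal sigmoid of C(g,Q) - C(g,S), depending
  only on the last observed point; raw values do not sum to 1 and are kept
  alongside the normalized posterior.
* ``dragan_posterior`` — the legibility-model posterior
  P(g|o) proportional to exp(-(C(o) + C(Q->g) - C(S->g))), scoring how
  efficient reaching g through the observed portion is relative to the
  direct plan; ``legibility_score`` integrates it along a trajectory with
  linearly decaying weight f(tau) = T - tau.

Here C(g,o) = cost(o) + cost(Q, g), the cost of the cheapest plan to g that
passes through every observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import arclength, as_polyline, last_point, optimal_cost, prefix, prefix_match
from .scenario import Scenario, Trajectory

__all__ = [
    "GoalPosterior",
    "cost_matching",
    "ramirez_geffner",
    "mirroring",
    "masters_sardina",
    "dragan_posterior",
    "legibility_score",
    "RECOGNIZERS",
    "get_recognizer",
]

# exponent clipping guard before exponentiation
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class GoalPosterior:
    """Normalized probability per goal, with optional unnormalized scores.

    ``probabilities`` sums to 1 except for the deliberately unnormalized
    all-zero output of the idealized library recognizer.
    """

    probabilities: dict[int, float]
    raw: dict[int, float] | None = field(default=None, compare=False)

    def __getitem__(self, goal_id: int) -> float:
        return self.probabilities[goal_id]

    @property
    def goal_ids(self) -> list[int]:
        return sorted(self.probabilities)

    @staticmethod
    def from_scores(scores: dict[int, float], raw: dict[int, float] | None = None) -> "GoalPosterior":
        total = sum(scores.values())
        if total <= 0:
            raise ValueError("cannot normalize non-positive scores")
        return GoalPosterior({g: s / total for g, s in scores.items()}, raw=raw)


def _check_anchored(scenario: Scenario, o: np.ndarray, tol: float | None = None) -> None:
    tol = scenario.default_tol if tol is None else tol
    if optimal_cost(o[0], scenario.start) > max(tol, 1e-9):
        raise ValueError("observation must begin at the scenario start point")


def _exp(x: float) -> float:
    return float(np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP)))


def cost_matching(scenario: Scenario, goal_id: int, o) -> float:
    """C(g, o): cost of the cheapest plan to the goal through the observations.

    With Euclidean costs this is the observed arclength plus the straight
    segment from the last observed point to the goal.
    """
    o = as_polyline(o)
    _check_anchored(scenario, o)
    return arclength(o) + optimal_cost(last_point(o), scenario.goal_point(goal_id))


def _cost_not_matching(scenario: Scenario, goal_id: int, o: np.ndarray) -> float:
    """C(g, o-bar): cheapest plan to the goal avoiding the observations.

    In an obstacle-free plane a plan constrained *away* from the observed
    points is ill-defined in the limit, so we use a declared convention:
    when the observation is not itself a prefix of the straight plan, the
    optimal plan already fails to match and C(g, o-bar) is the optimal cost;
    otherwise a minimal detour of twice the match tolerance is added.
    """
    g = scenario.goal_point(goal_id)
    straight = np.vstack([scenario.start, g])
    tol = scenario.default_tol
    base = optimal_cost(scenario.start, g)
    if prefix_match(o, straight, tol):
        return base + 2.0 * tol
    return base


def ramirez_geffner(scenario: Scenario, o, library=None) -> GoalPosterior:
    """Cost-difference posterior: P(g|o) ∝ exp(-(C(g,o) - C(g,o-bar)))."""
    o = as_polyline(o)
    scores = {
        g: _exp(-(cost_matching(scenario, g, o) - _cost_not_matching(scenario, g, o)))
        for g in scenario.goal_ids
    }
    return GoalPosterior.from_scores(scores)


def mirroring(scenario: Scenario, o, library=None) -> GoalPosterior:
    """Cost-ratio posterior: P(g|o) ∝ C(g) / C(g,o)."""
    o = as_polyline(o)
    scores = {
        g: optimal_cost(scenario.start, scenario.goal_point(g))
        / cost_matching(scenario, g, o)
        for g in scenario.goal_ids
    }
    return GoalPosterior.from_scores(scores)


def masters_sardina(scenario: Scenario, o, library=None) -> GoalPosterior:
    """Last-observation sigmoid posterior.

    Per goal, P = e^{-d} / (1 + e^{-d}) with d = C(g,Q) - C(g,S): how much
    closer (in optimal cost) the agent has come to the goal since the start.
    The raw sigmoids do not sum to one across goals; they are kept in
    ``raw`` and additionally normalized for cross-algorithm comparison.
    """
    o = as_polyline(o)
    _check_anchored(scenario, o)
    q = last_point(o)
    raw = {}
    for g in scenario.goal_ids:
        gp = scenario.goal_point(g)
        d = optimal_cost(q, gp) - optimal_cost(scenario.start, gp)
        e = _exp(-d)
        raw[g] = e / (1.0 + e)
    return GoalPosterior.from_scores(dict(raw), raw=raw)


def dragan_posterior(scenario: Scenario, o, library=None) -> GoalPosterior:
    """Legibility-model posterior: P(g|o) ∝ exp(-(C(o) + C(Q→g) - C(S→g)))."""
    o = as_polyline(o)
    _check_anchored(scenario, o)
    q = last_point(o)
    c_o = arclength(o)
    scores = {}
    for g in scenario.goal_ids:
        gp = scenario.goal_point(g)
        scores[g] = _exp(-(c_o + optimal_cost(q, gp) - optimal_cost(scenario.start, gp)))
    return GoalPosterior.from_scores(scores)


def legibility_score(
    scenario: Scenario,
    trajectory: Trajectory,
    true_goal: int,
    n_steps: int = 50,
) -> float:
    """Weighted time-average of the true goal's probability along a trajectory.

    Approximates  ∫ P(g*|prefix_tau) f(tau) dtau / ∫ f(tau) dtau  over the
    arclength parameter tau in [0, T], with f(tau) = T - tau weighting the
    early motion most, using the per-prefix ``dragan_posterior`` and
    trapezoidal quadrature on a uniform grid of ``n_steps`` intervals.
    """
    pts = trajectory.points if isinstance(trajectory, Trajectory) else as_polyline(trajectory)
    T = arclength(pts)
    fracs = np.arange(n_steps + 1) / n_steps
    weights = T - fracs * T
    probs = np.array(
        [dragan_posterior(scenario, prefix(pts, f))[true_goal] for f in fracs]
    )
    return float(np.trapezoid(weights * probs, fracs) / np.trapezoid(weights, fracs))


def _lrgr_entry(scenario, o, library=None, **kwargs):
    from .lrgr import lrgr_posterior

    return lrgr_posterior(scenario, library or {}, o, **kwargs)


def _ideal_entry(scenario, o, library=None, **kwargs):
    from .baselines import ideal_posterior

    posterior, _ = ideal_posterior(scenario, library or {}, o, **kwargs)
    return posterior


#: Uniform recognizer contract: f(scenario, observation, library=None, **kw)
RECOGNIZERS = {
    "rg": ramirez_geffner,
    "mirroring": mirroring,
    "ms": masters_sardina,
    "dragan": dragan_posterior,
    "lrgr": _lrgr_entry,
    "ideal": _ideal_entry,
}


def get_recognizer(name: str):
    try:
        return RECOGNIZERS[name]
    except KeyError:
        raise KeyError(
            f"unknown recognizer {name!r}; available: {sorted(RECOGNIZERS)}"
        ) from None
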