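"""Idealized library-based plan recognizer.

The classic comparison point for library-aware recognition: it assumes the
plan library is complete and does no dynamic plan generation.  Let K be the
set of goals with at least one library plan the observation prefix-matches.
Each goal in K receives likelihood 1/|K| — 1 for a unique match, 0.5 when
the observation matches plans toward two goals — and when K is empty every
goal receives 0 (the output is deliberately left unnormalized: the
recognizer has no opinion, which the convergence detector treats as
not-yet-decided).
"""

from __future__ import annotations

from .geometry import as_polyline, prefix_match
from .recognizers import GoalPosterior
from .scenario import Scenario, Trajectory

__all__ = ["ideal_posterior"]


def ideal_posterior(
    scenario: Scenario,
    library: dict[int, list[Trajectory]],
    o,
    tol: float | None = None,
) -> tuple[GoalPosterior, int]:
    """All-or-nothing library matching.

    Returns the posterior and the number of matched goals |K|.
    """
    o = as_polyline(o)
    tol = scenario.default_tol if tol is None else tol
    matched = [
        g
        for g in scenario.goal_ids
        if any(prefix_match(o, t.points, tol) for t in library.get(g, []))
    ]
    k = len(matched)
    probs = {g: (1.0 / k if g in matched else 0.0) for g in scenario.goal_ids}
    return GoalPosterior(probs), k


def ideal_series(
    scenario: Scenario,
    library: dict[int, list[Trajectory]],
    trajectory: Trajectory,
    fractions,
    tol: float | None = None,
) -> list[GoalPosterior]:
    """Idealized-recognizer posteriors at every observation prefix.

    Same decisions as calling :func:`ideal_posterior` per prefix, with each
    observed point projected onto each library plan only once.
    """
    import numpy as np

    from .geometry import batch_prefix_state, prefix_cuts

    obs = trajectory.points if isinstance(trajectory, Trajectory) else trajectory
    obs = as_polyline(obs)
    tol = scenario.default_tol if tol is None else tol
    fractions = np.asarray(fractions, dtype=float)
    idx, cuts = prefix_cuts(obs, fractions)
    matched = {}
    for g in scenario.goal_ids:
        m = np.zeros(len(fractions), dtype=bool)
        for t in library.get(g, []):
            mt, _, _ = batch_prefix_state(obs, idx, cuts, t.points, tol)
            m |= mt
        matched[g] = m
    k_counts = np.sum(np.array([matched[g] for g in scenario.goal_ids]), axis=0)
    out = []
    for i in range(len(fractions)):
        k = int(k_counts[i])
        out.append(
            GoalPosterior(
                {
                    g: (1.0 / k if k and matched[g][i] else 0.0)
                    for g in scenario.goal_ids
                }
            )
        )
    return out
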