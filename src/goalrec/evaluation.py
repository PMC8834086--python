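"""Incremental-observation evaluation harness.

Feeds each recognizer observation prefixes of increasing length, records
the per-prefix goal posterior (a :class:`PosteriorSeries`), and reduces a
series to its *decision-convergence point*: the earliest observed fraction
at which the correct goal's probability exceeds 0.5 and never falls back to
0.5 or below.  Convergence is the computational analogue of a human
observer's response time, and the regression utilities here relate the two
with an ordinary least-squares fit and the F-test for its R².

Also provides the robustness experiments around an incomplete plan
library: the leave-one-out design (observe each of the 14 trajectories
with the other 13 as the library) and seeded library-size sweeps, plus a
synthetic response-time generator that stands in for human reaction-time
data when exercising the regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recognizers import GoalPosterior, get_recognizer
from .scenario import (
    Scenario,
    Trajectory,
    generate_observations,
    observation_fractions,
    sample_library,
)

__all__ = [
    "PosteriorSeries",
    "ConvergencePoint",
    "RegressionStats",
    "run_series",
    "convergence_point",
    "leave_one_out",
    "library_size_sweep",
    "linear_fit_r2",
    "synth_response_times",
]


@dataclass(frozen=True)
class PosteriorSeries:
    """Goal posteriors at strictly increasing observed fractions (last = 1)."""

    fractions: np.ndarray
    posteriors: list[GoalPosterior]
    algorithm: str
    trajectory: Trajectory | None = None

    def __len__(self) -> int:
        return len(self.fractions)

    def probabilities_of(self, goal_id: int) -> np.ndarray:
        return np.array([p[goal_id] for p in self.posteriors])


@dataclass(frozen=True)
class ConvergencePoint:
    """Earliest fraction of committed correct recognition; None if never."""

    fraction: float | None
    correct_goal: int

    @property
    def converged(self) -> bool:
        return self.fraction is not None


@dataclass(frozen=True)
class RegressionStats:
    """Simple linear fit with the F-test for R^2 on (1, n-2) dof."""

    r2: float
    p_value: float
    slope: float
    intercept: float
    n: int


def run_series(
    algorithm: str,
    scenario: Scenario,
    library: dict[int, list[Trajectory]] | None,
    trajectory: Trajectory,
    step_fraction: float = 0.02,
    **algo_kwargs,
) -> PosteriorSeries:
    """Run one recognizer over all observation prefixes of one trajectory.

    The library-based recognizers (``lrgr``, ``ideal``) go through batch
    scorers that share point projections across the nested prefixes; the
    per-prefix recognizers are called on each generated observation.  Both
    routes produce the same posteriors.
    """
    fractions = observation_fractions(step_fraction)
    if algorithm == "lrgr":
        from .lrgr import lrgr_series

        posteriors = lrgr_series(
            scenario, library or {}, trajectory, fractions, **algo_kwargs
        )
    elif algorithm == "ideal":
        from .baselines import ideal_series

        posteriors = ideal_series(
            scenario, library or {}, trajectory, fractions, **algo_kwargs
        )
    else:
        recognizer = get_recognizer(algorithm)
        observations = generate_observations(trajectory, step_fraction)
        posteriors = [
            recognizer(scenario, o, library=library, **algo_kwargs)
            for o in observations
        ]
    return PosteriorSeries(
        fractions=fractions,
        posteriors=posteriors,
        algorithm=algorithm,
        trajectory=trajectory,
    )


def convergence_point(series: PosteriorSeries, correct_goal: int) -> ConvergencePoint:
    """Earliest fraction with P(correct) > 0.5 and no later fall to <= 0.5.

    A probability of exactly 0.5 does not count as decided.  Evaluated on
    the sampled prefix grid.
    """
    p = series.probabilities_of(correct_goal)
    if len(p) == 0:
        raise ValueError("empty posterior series")
    above = p > 0.5
    if not above[-1]:
        return ConvergencePoint(fraction=None, correct_goal=correct_goal)
    # first index after the last dip to <= 0.5
    below = np.flatnonzero(~above)
    first = 0 if len(below) == 0 else int(below[-1]) + 1
    return ConvergencePoint(
        fraction=float(series.fractions[first]), correct_goal=correct_goal
    )


def _loo_rows(
    algorithm: str,
    scenario: Scenario,
    library: dict[int, list[Trajectory]],
    held_out: Trajectory,
    step_fraction: float,
    **algo_kwargs,
) -> dict:
    series = run_series(
        algorithm, scenario, library, held_out, step_fraction, **algo_kwargs
    )
    cp = convergence_point(series, held_out.goal_id)
    return {
        "algorithm": algorithm,
        "goal_id": held_out.goal_id,
        "curve_index": held_out.curve_index,
        "convergence_fraction": cp.fraction if cp.converged else np.nan,
    }


def leave_one_out(
    algorithm: str,
    scenario: Scenario,
    step_fraction: float = 0.02,
    **algo_kwargs,
) -> pd.DataFrame:
    """One recognition problem per trajectory: observe it, library = the rest.

    Returns a table with one row per library trajectory (14 in the default
    scenario); unconverged problems carry NaN.
    """
    rows = []
    for held_out in scenario.all_trajectories():
        library = {
            gid: [t for t in trajs if t is not held_out]
            for gid, trajs in scenario.library.items()
        }
        rows.append(
            _loo_rows(algorithm, scenario, library, held_out, step_fraction, **algo_kwargs)
        )
    return pd.DataFrame(rows)


def _repeat_seed(seed: int, size: int, traj_index: int, repeat: int) -> int:
    ss = np.random.SeedSequence([seed, size, traj_index, repeat])
    return int(ss.generate_state(1)[0] % (2**31))


def library_size_sweep(
    algorithm: str,
    scenario: Scenario,
    sizes: list[int],
    repeats: int = 20,
    seed: int = 0,
    step_fraction: float = 0.02,
    **algo_kwargs,
) -> pd.DataFrame:
    """Convergence under randomly sampled sub-libraries of controlled size.

    For each size, each held-out trajectory and each of ``repeats`` seeded
    draws, samples a sub-library (held-out plan excluded, both goals
    represented) and records the convergence fraction — with the default
    14-trajectory scenario, 14 x repeats rows per size.  Fully
    deterministic given ``seed``.
    """
    rows = []
    trajectories = scenario.all_trajectories()
    for size in sizes:
        for ti, held_out in enumerate(trajectories):
            for r in range(repeats):
                rseed = _repeat_seed(seed, size, ti, r)
                library = sample_library(scenario, size, held_out, rseed)
                row = _loo_rows(
                    algorithm, scenario, library, held_out, step_fraction, **algo_kwargs
                )
                row.update(library_size=size, repeat=r, repeat_seed=rseed)
                rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "algorithm",
            "goal_id",
            "curve_index",
            "library_size",
            "repeat",
            "repeat_seed",
            "convergence_fraction",
        ],
    )


def linear_fit_r2(x, y) -> RegressionStats:
    """Ordinary least squares of y on x with the F-test for R^2.

    The p-value is from F = R^2 (n-2) / (1 - R^2) on (1, n-2) degrees of
    freedom (equivalent to the two-sided t-test on the slope).  A constant
    y yields R^2 = 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for the F-test")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the fit is undefined")
    if np.ptp(y) == 0:
        return RegressionStats(r2=0.0, p_value=1.0, slope=0.0, intercept=float(y[0]), n=n)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if r2 >= 1.0:
        p = 0.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
    return RegressionStats(
        r2=r2, p_value=p, slope=float(fit.slope), intercept=float(fit.intercept), n=n
    )


def synth_response_times(
    convergence_fractions,
    slope: float = 1.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic normalized response times, linear in convergence + noise.

    Stands in for human reaction-time data when exercising the regression
    stage: rt_i = intercept + slope * conv_i + N(0, noise_sd).
    """
    conv = np.asarray(convergence_fractions, dtype=float)
    if np.any(~np.isfinite(conv)):
        raise ValueError("all convergence fractions must be present (finite)")
    rng = np.random.default_rng(seed)
    return intercept + slope * conv + rng.normal(0.0, noise_sd, size=conv.shape)
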