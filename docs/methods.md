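# Methods

## Problem setting

An agent moves in an obstacle-free plane from a start point `S` toward one
of a known set of goals `G`. An observer sees an ever-growing prefix `o` of
the motion trajectory and must infer the intended goal — *goal
recognition*. Two families of methods address this:

* **Rationality-based goal recognition (RGR)** assumes the agent is
  rational (cost-efficient) and scores each goal by comparing the cost of
  an optimal plan constrained to pass through the observations against an
  unconstrained (or observation-avoiding) optimal plan. No plan library is
  needed.
* **Library-based plan recognition** assumes a library `T_G` of known
  plans, partitioned into `T_g` per goal, and recognizes goals through the
  plans that match the observations.

The package implements four published RGR recognizers, an idealized
library matcher, and LRGR — a hybrid that matches observations to library
plans through a closest-point detour and rates the detour's rationality,
falling back to pure rationality when no plan is available.

## Cost model

All costs are Euclidean arclengths. Because the plane has no obstacles,
the optimal plan between two points is the straight segment and
`cost(p1, p2)` is the Euclidean distance; `cost(t)` of a polyline is the
sum of its segment lengths. The cost of the cheapest plan to goal `g`
through observation `o` ending at `Q` is

    C(g, o) = cost(o) + cost(Q, g).

Coordinates are dimensionless continuous reals; there is no grid.

## The recognizers

With `C(g) = cost(S, g)` the optimal cost, the four RGR posteriors are
(each normalized over goals):

* **Cost difference** (`rg`): `P(g|o) ∝ exp(-(C(g,o) - C(g,ō)))`, where
  `C(g,ō)` is the cost of the cheapest plan *not* matching the
  observations. In a continuous obstacle-free plane a non-matching plan
  can come arbitrarily close to the optimal one, so `C(g,ō)` is
  ill-defined in the limit; we adopt a declared convention: when `o` is
  not itself a prefix of the straight plan to `g`, the optimal plan
  already fails to match and `C(g,ō) = C(g)`; otherwise a minimal detour
  of twice the prefix-match tolerance is added. This preserves the
  formula's sign behavior and is an approximation of the original
  discrete formulation, where plans occupy distinct states.
* **Mirroring** (`mirroring`): `P(g|o) ∝ C(g) / C(g,o)`.
* **Last observation** (`ms`): per-goal sigmoid
  `P = e^{-d} / (1 + e^{-d})` with `d = C(g,Q) - C(g,S)`. The raw
  sigmoids do not sum to one; they are preserved on the returned posterior
  (`raw`) and also normalized so that all recognizers plot on a common
  probability axis.
* **Legibility model** (`dragan`): per-prefix posterior
  `P(g|o) ∝ exp(-(cost(o) + C(Q,g) - C(S,g)))`, and the integrated
  legibility of a full trajectory,
  `∫ P(g*|prefix_τ) f(τ) dτ / ∫ f(τ) dτ` with weight `f(τ) = T - τ`
  favoring early motion. For decision-convergence analysis we use the
  per-prefix posterior (the integrated score is a single number per
  trajectory, not a time course); both are exposed.

For two equidistant goals, the sign of `P(g1) - 0.5` reduces, in all three
of `rg`, `mirroring` and `ms`, to the sign of `C(g2,Q) - C(g1,Q)`; their
decision *times* therefore coincide even though their probability values
differ. The evaluation suite checks this identity empirically.

## LRGR

For each goal `g` and each library plan `t ∈ T_g`, the matching score is

    M(t) = 1                       if o prefix-matches t,
    M(t) = cost(t̂_g) / C          otherwise,

where `t̂_g` is the optimal (straight) plan to `g` — computed, not looked
up, since optimal plans need not be in the library — and
`C = cost(o) + cost(Q, w) + cost(w, g)` is the cost of the ad-hoc plan
that follows the observations, detours to the closest point `w` on `t`,
and continues optimally. When no close plan exists (empty `T_g`, or `w`
suppressed by a distance cutoff), the closest plan is taken to be the
observed one itself (`w = Q`, approach cost 0), which makes `M` the
mirroring ratio exactly. `score(g) = max_t M(t)`; the posterior is
`η · score(g)` with `η = 1 / Σ_g score(g)`.

Design choices at points the formulation leaves open:

* When `T_g` is non-empty, only actual library plans are scored; the
  observed-only hypothesis is *not* added as an implicit extra candidate.
  The `include_optimal` flag adds the straight plan as a virtual library
  member for sensitivity analysis.
* The closest-point cutoff defaults to unbounded (it *may* be enforced).
* Ties among plans for the max are immaterial (only the value is used).

By the triangle inequality `C ≥ cost(t̂_g)`, so `M ≤ 1` always, with
equality only for a direct match or an ad-hoc plan that is itself optimal.

## Idealized library matcher

The `ideal` baseline returns likelihood `1/|K|` for each goal in the set
`K` of goals with at least one prefix-matching library plan (1 for a
unique match, 0.5 for a two-goal match) and 0 for every goal when `K` is
empty. The all-zero output is deliberately unnormalized; the convergence
detector treats it as "not yet decided".

## Geometry and matching tolerances

`prefix_match(o, t, tol)` requires every point of `o` to lie within `tol`
of the polyline `t` *and* the arclength parameters of their projections to
be non-decreasing starting at 0. Monotone progression matters: an
observation that curls near the start of a straight plan stays within
tolerance but is not a prefix of it. The default tolerance is `1e-6 ×`
the scenario diameter (distance units); the closest-point query projects
onto segment interiors in closed form. Series evaluation uses a batched
path that projects each observed point onto each library plan once and
reuses the projections across all nested prefixes; it is algebraically
identical to the per-prefix computation (the tests assert agreement to
`1e-12`).

## Synthetic scenario generator

`make_berkovitz_scenario` emulates the layout of the motivating human
study: start at the origin, two goals equidistant from it at `(-span/2,
depth)` and `(span/2, depth)` (defaults 6 and 10, so the straight plans
diverge slowly and early prefixes are ambiguous), and 7 trajectories per
goal from straight to strongly curved. Curved members are quadratic
Bézier curves (discretized to 200 points) whose control points are offset
laterally toward +x by `curvature_scale · span · k / 3`; per goal,
`curve_index` is assigned by sorting on mean distance from the distractor
goal (1 = closest). Since every curve bows toward +x, the straight plan
lands at index 1 for the +x goal and index 7 for the other — one optimal
plan per goal, at opposite index ends.

One goal-1 trajectory is a composite: it follows the initial 20% of goal
2's least-curved non-straight plan *exactly*, then continues to goal 1
along a tangent-continuous Bézier. This engineers a genuine cross-goal
overlap (verified by `prefix_match` at construction), reproducing the
structure that makes early observations ambiguous for library-based
recognizers.

What the generator does **not** emulate: the original apparatus's exact
trajectory coordinates (published only as figures), its kinematics
(velocity profiles, fixed arm speed), and measurement noise. Tests passing
on this generator therefore establish the algorithms' ordinal and
structural behavior under the stated layout, not quantitative agreement
with recorded human data.

## Evaluation harness

* Observations are prefixes at arclength fractions `step, 2·step, …, 1.0`
  (default step 0.02, i.e. 50 prefixes — the sampling density is
  configurable since no canonical value exists).
* The convergence point is the earliest grid fraction where the correct
  goal's probability exceeds 0.5 with no later value at or below 0.5;
  exactly 0.5 does not count. Unconverged series are recorded as missing
  and dropped from regressions with a logged count.
* Leave-one-out: 14 problems, each observing one trajectory with the other
  13 as library. Library-size sweep: for each size (e.g. 10/6/3), each
  held-out trajectory and each of 20 repeats, a sub-library is sampled
  uniformly (rejection-sampled until both goals are represented) — 280
  problems per size, bit-reproducible from the top-level seed via
  `numpy.random.SeedSequence`.
* The regression stage is ordinary least squares with the F-test for R²
  on (1, n−2) degrees of freedom. Human response times are not bundled;
  any `(trajectory, normalized RT)` table can be supplied, and
  `synth_response_times` generates synthetic RTs (linear in convergence
  plus Gaussian noise) so the pipeline is testable end to end. RTs are
  treated as pre-normalized.

## Numerical choices

* Legibility quadrature: trapezoidal on a uniform grid (default 50
  intervals). The integrand is smooth, and trapezoidal refinement
  converges at O(1/n²), so the 50-interval default agrees with a
  5000-interval reference within 10⁻³.
* Exponents are clipped to ±500 before exponentiation.
* Posterior normalization is by the exact score sum; sums are asserted to
  1 within 10⁻⁹ in tests.
* Degenerate inputs: single-point polylines have zero arclength; duplicate
  consecutive points are allowed; a prefix fraction outside [0,1], a
  non-anchored observation, an infeasible library size, and a constant
  predictor in the regression all raise `ValueError`.

## Problem sizes used in the shipped experiments

The default test and example runs use the 14-trajectory scenario at 200
points per trajectory, observation steps of 0.02–0.1, sweep sizes
{10, 6, 3} × 20 repeats (280 problems per size), 1000 random series for
the convergence-detector cross-check, and 500 Monte-Carlo replicates for
regression parameter recovery. These sizes were chosen to characterize
the algorithms' behavior fully on the two-goal layout; all are parameters
of the public API and scale up directly.

## Known limitations

* Goals and plans are flat; hierarchical goal/plan schemas are out of
  scope.
* The cost model is obstacle-free Euclidean arclength; no planning
  backend is pluggable.
* The `C(g,ō)` convention for the cost-difference recognizer is a declared
  approximation of its discrete original.
* LRGR here is offline per prefix: no caching of matching state across a
  growing observation beyond the batched projection reuse.
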