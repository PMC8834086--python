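"""The four rationality-based recognizers and the legibility score."""

import numpy as np
import pytest

import goalrec.recognizers as rec
from goalrec import (
    Scenario,
    arclength,
    cost_matching,
    dragan_posterior,
    get_recognizer,
    last_point,
    legibility_score,
    masters_sardina,
    mirroring,
    optimal_cost,
    prefix,
    ramirez_geffner,
)

ALL_RGR = [ramirez_geffner, mirroring, masters_sardina, dragan_posterior]

START_ONLY = np.zeros((1, 2))
# straight 2 units toward goal 1 = (-3, 4)
O_TOWARD_G1 = np.array([[0.0, 0.0], [-1.2, 1.6]])


def random_observation(triangle_scenario, rng, n=8):
    steps = rng.normal(size=(n - 1, 2), scale=0.4)
    pts = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return pts + triangle_scenario.start


class TestCostMatching:
    def test_empty_observation_gives_optimal_cost(self, triangle_scenario):
        assert cost_matching(triangle_scenario, 1, START_ONLY) == pytest.approx(5.0)

    def test_partial_straight_observation(self, triangle_scenario):
        assert cost_matching(triangle_scenario, 1, O_TOWARD_G1) == pytest.approx(5.0)

    def test_full_straight_plan(self, triangle_scenario):
        o = np.array([[0.0, 0.0], [-3.0, 4.0]])
        assert cost_matching(triangle_scenario, 1, o) == pytest.approx(5.0)

    def test_unanchored_observation_rejected(self, triangle_scenario):
        with pytest.raises(ValueError):
            cost_matching(triangle_scenario, 1, np.array([[1.0, 1.0], [2.0, 2.0]]))


class TestRamirezGeffner:
    def test_uniform_at_start_in_symmetric_scenario(self, triangle_scenario):
        p = ramirez_geffner(triangle_scenario, START_ONLY)
        assert p[1] == pytest.approx(0.5) and p[2] == pytest.approx(0.5)

    def test_straight_observation_favors_its_goal(self, triangle_scenario):
        p = ramirez_geffner(triangle_scenario, O_TOWARD_G1)
        assert p[1] > p[2]

    def test_matches_independent_formula_evaluation(self, triangle_scenario, rng):
        s = triangle_scenario
        for _ in range(10):
            o = random_observation(s, rng)
            got = ramirez_geffner(s, o)
            # independent route: raw formula with the declared C(G, o-bar)
            # convention (optimal cost; the observation is off both straight
            # plans with probability 1)
            raw = {}
            for g in (1, 2):
                c_match = arclength(o) + optimal_cost(o[-1], s.goal_point(g))
                c_not = optimal_cost(s.start, s.goal_point(g))
                raw[g] = np.exp(-(c_match - c_not))
            z = raw[1] + raw[2]
            assert got[1] == pytest.approx(raw[1] / z, abs=1e-12)


class TestMirroring:
    def test_hand_computed_example(self, triangle_scenario):
        p = mirroring(triangle_scenario, O_TOWARD_G1)
        # ratios (1.0, 5/6.8374...), normalized
        r2 = 5.0 / (2.0 + np.sqrt(23.4))
        assert p[1] == pytest.approx(1.0 / (1.0 + r2), abs=1e-9)
        assert p[1] == pytest.approx(0.5776, abs=1e-4)

    def test_uniform_at_start(self, triangle_scenario):
        p = mirroring(triangle_scenario, START_ONLY)
        assert p[1] == pytest.approx(0.5)

    def test_ratio_is_one_on_straight_plan(self, triangle_scenario):
        for f in (0.2, 0.7, 1.0):
            o = prefix(np.array([[0.0, 0.0], [-3.0, 4.0]]), f)
            c = cost_matching(triangle_scenario, 1, o)
            assert c == pytest.approx(5.0, abs=1e-12)


class TestMastersSardina:
    def test_raw_half_at_start(self, triangle_scenario):
        p = masters_sardina(triangle_scenario, START_ONLY)
        assert p.raw[1] == 0.5 and p.raw[2] == 0.5

    def test_hand_computed_sigmoids(self, triangle_scenario):
        p = masters_sardina(triangle_scenario, O_TOWARD_G1)
        assert p.raw[1] == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-9)
        d2 = np.sqrt(23.4) - 5.0
        assert p.raw[2] == pytest.approx(1 / (1 + np.exp(d2)), abs=1e-9)

    def test_depends_only_on_last_observation(self, triangle_scenario):
        zigzag = np.array([[0, 0], [1.0, 0.5], [-0.5, 1.0], [-1.2, 1.6]])
        a = masters_sardina(triangle_scenario, O_TOWARD_G1)
        b = masters_sardina(triangle_scenario, zigzag)
        assert a.raw == pytest.approx(b.raw)

    def test_normalized_posterior_sums_to_one(self, triangle_scenario):
        p = masters_sardina(triangle_scenario, O_TOWARD_G1)
        assert sum(p.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(p.raw.values()) != pytest.approx(1.0, abs=1e-3)


class TestDragan:
    def test_uniform_at_start(self, triangle_scenario):
        p = dragan_posterior(triangle_scenario, START_ONLY)
        assert p[1] == pytest.approx(0.5)

    def test_hand_computed_example(self, triangle_scenario):
        p = dragan_posterior(triangle_scenario, O_TOWARD_G1)
        unnorm2 = np.exp(-(2.0 + np.sqrt(23.4) - 5.0))
        assert p[1] == pytest.approx(1.0 / (1.0 + unnorm2), abs=1e-9)
        assert p[1] == pytest.approx(0.8626, abs=1e-4)

    def test_matches_independent_formula_evaluation(self, triangle_scenario, rng):
        s = triangle_scenario
        for _ in range(10):
            o = random_observation(s, rng)
            got = dragan_posterior(s, o)
            raw = {
                g: np.exp(
                    -(
                        arclength(o)
                        + optimal_cost(o[-1], s.goal_point(g))
                        - optimal_cost(s.start, s.goal_point(g))
                    )
                )
                for g in (1, 2)
            }
            z = raw[1] + raw[2]
            assert got[2] == pytest.approx(raw[2] / z, abs=1e-12)


class TestLegibility:
    def test_constant_posterior_gives_that_constant(self, triangle_scenario, monkeypatch):
        from goalrec.recognizers import GoalPosterior

        for const in (1.0, 0.5):
            monkeypatch.setattr(
                rec,
                "dragan_posterior",
                lambda s, o, library=None, c=const: GoalPosterior({1: c, 2: 1 - c}),
            )
            t = np.array([[0.0, 0.0], [-3.0, 4.0]])
            assert rec.legibility_score(triangle_scenario, t, 1) == pytest.approx(const)

    def test_quadrature_refinement_agrees(self, triangle_scenario):
        t = np.linspace([0.0, 0.0], [-3.0, 4.0], 100)
        coarse = legibility_score(triangle_scenario, t, 1, n_steps=50)
        fine = legibility_score(triangle_scenario, t, 1, n_steps=5000)
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_score_within_unit_interval(self, scenario):
        t = scenario.library[1][0]
        score = legibility_score(scenario, t, 1, n_steps=25)
        assert 0.0 <= score <= 1.0


class TestSharedProperties:
    @pytest.mark.parametrize("recognizer", ALL_RGR)
    def test_posteriors_sum_to_one(self, triangle_scenario, rng, recognizer):
        for _ in range(5):
            o = random_observation(triangle_scenario, rng)
            p = recognizer(triangle_scenario, o)
            assert sum(p.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("recognizer", ALL_RGR)
    def test_mirror_symmetry_swaps_goals(self, triangle_scenario, rng, recognizer):
        flip = np.array([-1.0, 1.0])
        for _ in range(5):
            o = random_observation(triangle_scenario, rng)
            p = recognizer(triangle_scenario, o)
            q = recognizer(triangle_scenario, o * flip)
            assert p[1] == pytest.approx(q[2], abs=1e-12)
            assert p[2] == pytest.approx(q[1], abs=1e-12)

    def test_registry_exposes_all_algorithms(self):
        for name in ("rg", "mirroring", "ms", "dragan", "lrgr", "ideal"):
            assert callable(get_recognizer(name))
        with pytest.raises(KeyError):
            get_recognizer("nope")
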