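"""Unit and property tests for the Mamdani engine."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from fuzzyair.fuzzy import (
    FuzzyInferenceSystem,
    FuzzyRule,
    LinguisticVariable,
    MembershipFunction,
    NoRuleFiredWarning,
    defuzzify_centroid,
    trapezoid,
    triangle,
)
from oracles import clipped_trapezoid_centroid


class TestMembershipFunction:
    @pytest.mark.parametrize("points, x, expected", [
        ((0, 0, 15, 35), 24.0, 0.55),     # worked PM10 example
        ((0, 0, 15, 35), 0.0, 1.0),       # plateau point
        ((0, 0, 15, 35), 35.0, 0.0),      # support edge
        ((15, 35, 150, 150), 24.0, 0.45),  # complementary shoulder
        ((2, 5, 5, 8), 5.0, 1.0),          # triangle apex
        ((2, 5, 5, 8), 3.5, 0.5),          # triangle mid-rise
        ((2, 5, 5, 8), 1.0, 0.0),          # outside support
        ((2, 5, 5, 8), 9.0, 0.0),
    ])
    def test_piecewise_linear_evaluation(self, points, x, expected):
        assert trapezoid(*points)(x) == pytest.approx(expected, abs=1e-12)

    def test_triangle_is_degenerate_trapezoid(self):
        tri = triangle(0, 0, 1.11)
        assert tri.shape == "triangle"
        assert tri.params == (0, 0, 1.11)
        xs = np.linspace(-1, 2, 301)
        np.testing.assert_allclose(tri(xs), trapezoid(0, 0, 0, 1.11)(xs))

    def test_decreasing_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            MembershipFunction(5, 3, 6, 7)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            trapezoid(0, 1, 2, 3)(np.nan)

    @given(
        pts=st.lists(st.floats(-50, 50), min_size=4, max_size=4).map(sorted),
        x=st.floats(-100, 100),
    )
    @settings(derandomize=True, max_examples=200)
    def test_membership_always_in_unit_interval(self, pts, x):
        mu = trapezoid(*pts)(x)
        assert 0.0 <= mu <= 1.0

    @given(
        pts=st.lists(st.floats(-50, 50), min_size=4, max_size=4).map(sorted),
        x=st.floats(-60, 60),
    )
    @settings(derandomize=True, max_examples=200)
    def test_membership_is_continuous(self, pts, x):
        """Lipschitz in x for non-degenerate rise/fall segments (shoulder
        functions are only evaluated on the clamped domain in practice)."""
        assume(pts[1] - pts[0] > 1e-3 and pts[3] - pts[2] > 1e-3)
        mf = trapezoid(*pts)
        eps = 1e-9
        max_slope = max(1.0 / (pts[1] - pts[0]), 1.0 / (pts[3] - pts[2]))
        assert abs(mf(x + eps) - mf(x)) <= max_slope * eps + 1e-12


class TestLinguisticVariable:
    @pytest.fixture()
    def pm10(self):
        return LinguisticVariable("pm10", (0.0, 150.0), {
            "acceptable": trapezoid(0, 0, 15, 35),
            "unacceptable": trapezoid(15, 35, 150, 150),
        })

    @pytest.mark.parametrize("x, acc, unacc", [
        (24.0, 0.55, 0.45),
        (0.0, 1.0, 0.0),
        (25.0, 0.5, 0.5),   # crossover midpoint of the (15, 35) segment
    ])
    def test_fuzzify_examples(self, pm10, x, acc, unacc):
        degrees = pm10.fuzzify(x)
        assert degrees["acceptable"] == pytest.approx(acc, abs=1e-12)
        assert degrees["unacceptable"] == pytest.approx(unacc, abs=1e-12)

    def test_out_of_domain_clamped_not_rejected(self, pm10):
        assert pm10.fuzzify(300.0) == pm10.fuzzify(150.0)
        assert pm10.fuzzify(-5.0) == pm10.fuzzify(0.0)

    def test_non_finite_rejected_with_variable_name(self, pm10):
        with pytest.raises(ValueError, match="pm10"):
            pm10.fuzzify(float("inf"))


class TestRuleActivation:
    def _fuzzified(self, a, b, c, d):
        return {
            "pm10": {"acceptable": a}, "temperature": {"high": b},
            "no2": {"acceptable": c}, "wind": {"strong": d},
        }

    ANTECEDENT = {"pm10": "acceptable", "temperature": "high",
                  "no2": "acceptable", "wind": "strong"}

    @pytest.mark.parametrize("degrees, weight, expected", [
        ((1.0, 1.0, 1.0, 1.0), 1.0, 1.0),       # identity
        ((0.55, 1.0, 0.45, 1.0), 1.0, 0.45),    # min over conjuncts
        ((0.9, 0.0, 0.8, 0.7), 1.0, 0.0),       # annihilator
        ((0.6, 0.8, 0.9, 0.7), 0.5, 0.3),       # weight scales the minimum
    ])
    def test_min_conjunction(self, degrees, weight, expected):
        rule = FuzzyRule(self.ANTECEDENT, "L", weight=weight)
        assert rule.activation(self._fuzzified(*degrees)) == pytest.approx(expected)

    def test_unknown_term_is_configuration_error(self):
        rule = FuzzyRule({"pm10": "bogus"}, "L")
        with pytest.raises(KeyError, match="bogus"):
            rule.activation({"pm10": {"acceptable": 1.0}})

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            FuzzyRule(self.ANTECEDENT, "L", weight=0.0)


@pytest.fixture()
def toy_output():
    return LinguisticVariable("out", (0.0, 10.0), {
        "low": triangle(0, 0, 4),
        "high": triangle(6, 10, 10),
    })


@pytest.fixture()
def toy_fis(toy_output):
    var = LinguisticVariable("x", (0.0, 1.0), {
        "small": trapezoid(0, 0, 0.4, 0.6),
        "large": trapezoid(0.4, 0.6, 1, 1),
    })
    rules = [FuzzyRule({"x": "small"}, "low"), FuzzyRule({"x": "large"}, "high")]
    return FuzzyInferenceSystem(inputs=[var], output=toy_output, rules=rules)


class TestAggregation:
    def test_single_rule_full_activation_equals_consequent(self, toy_fis, toy_output):
        grid = toy_output.grid(501)
        curve = toy_fis.aggregate([("low", 1.0)], grid)
        np.testing.assert_allclose(curve, toy_output.terms["low"](grid))

    def test_partial_activation_is_alpha_cut(self, toy_fis, toy_output):
        grid = toy_output.grid(501)
        curve = toy_fis.aggregate([("low", 0.5)], grid)
        np.testing.assert_allclose(curve, np.minimum(0.5, toy_output.terms["low"](grid)))

    def test_disjoint_consequents_union_is_pointwise_max(self, toy_fis, toy_output):
        grid = toy_output.grid(501)
        curve = toy_fis.aggregate([("low", 0.7), ("high", 0.3)], grid)
        expected = np.maximum(np.minimum(0.7, toy_output.terms["low"](grid)),
                              np.minimum(0.3, toy_output.terms["high"](grid)))
        np.testing.assert_allclose(curve, expected)
        # disjoint supports: each clipped set is recovered on its own support
        assert curve[grid < 4].max() == pytest.approx(0.7)
        assert curve[grid > 6].max() == pytest.approx(0.3)

    def test_zero_activation_contributes_nothing(self, toy_fis, toy_output):
        grid = toy_output.grid(501)
        curve = toy_fis.aggregate([("low", 1.0), ("high", 0.0)], grid)
        np.testing.assert_allclose(curve, toy_output.terms["low"](grid))

    def test_no_rule_fired_signalled(self, toy_fis, toy_output):
        with pytest.raises(ValueError, match="no rule fired"):
            toy_fis.aggregate([], toy_output.grid(101))


class TestCentroid:
    @pytest.mark.parametrize("mf, expected", [
        (triangle(2, 5, 8), 5.0),          # symmetric triangle
        (triangle(0, 0, 1.11), 0.37),      # closed form (a+b+c)/3
    ])
    def test_full_triangle_closed_form(self, mf, expected):
        grid = np.linspace(0, 9, 1001)
        assert defuzzify_centroid(grid, mf(grid)) == pytest.approx(expected, abs=1e-3)

    def test_uniform_curve_gives_midpoint(self):
        grid = np.linspace(0, 9, 1001)
        assert defuzzify_centroid(grid, np.ones_like(grid)) == pytest.approx(4.5, abs=1e-12)

    def test_zero_mass_signals_no_rule_fired(self):
        grid = np.linspace(0, 9, 101)
        with pytest.raises(ValueError, match="no rule fired"):
            defuzzify_centroid(grid, np.zeros_like(grid))

    def test_clipped_trapezoid_matches_analytic_oracle(self):
        rng = np.random.default_rng(123)
        grid = np.linspace(0, 10, 1001)
        for _ in range(50):
            a, b, c, d = np.sort(rng.uniform(0.5, 9.5, 4))
            alpha = rng.uniform(0.1, 1.0)
            if d - a < 0.2:
                continue
            curve = np.minimum(alpha, trapezoid(a, b, c, d)(grid))
            expected = clipped_trapezoid_centroid(a, b, c, d, alpha)
            assert defuzzify_centroid(grid, curve) == pytest.approx(expected, abs=1e-3)

    def test_grid_refinement_convergence(self):
        """Resolutions 501 and 5001 agree within 0.01 on random activation sets."""
        rng = np.random.default_rng(99)
        terms = [triangle(0, 0.9, 1.8), triangle(1.8, 2.7, 3.6), triangle(3.6, 4.5, 5.4),
                 triangle(5.4, 6.3, 7.2), trapezoid(7.2, 8.1, 9, 9)]
        for _ in range(30):
            degrees = rng.uniform(0, 1, 5)
            if degrees.max() < 0.05:
                continue
            results = []
            for res in (501, 5001):
                grid = np.linspace(0, 9, res)
                curve = np.zeros_like(grid)
                for mf, deg in zip(terms, degrees):
                    curve = np.maximum(curve, np.minimum(deg, mf(grid)))
                results.append(defuzzify_centroid(grid, curve))
            assert abs(results[0] - results[1]) < 1e-2


class TestInference:
    def test_output_bounded_on_random_inputs(self, toy_fis):
        rng = np.random.default_rng(5)
        xs = rng.uniform(-0.5, 1.5, 10_000)  # includes out-of-domain values
        out = toy_fis.infer_batch({"x": xs})
        lo, hi = toy_fis.output.domain
        assert np.all((out >= lo) & (out <= hi))

    def test_continuity_under_tiny_perturbation(self, toy_fis):
        rng = np.random.default_rng(6)
        xs = rng.uniform(0, 1, 200)
        base = toy_fis.infer_batch({"x": xs})
        bumped = toy_fis.infer_batch({"x": xs + 1e-6})
        assert np.max(np.abs(base - bumped)) < 1e-3

    def test_scalar_and_batch_agree(self, toy_fis):
        for x in (0.0, 0.3, 0.5, 0.62, 1.0):
            assert toy_fis.infer({"x": x}) == pytest.approx(
                float(toy_fis.infer_batch({"x": np.array([x])})[0]))

    def test_midpoint_fallback_when_rules_cannot_fire(self, toy_output):
        gappy = LinguisticVariable("x", (0.0, 1.0), {"small": trapezoid(0, 0, 0.1, 0.2)})
        fis = FuzzyInferenceSystem(
            inputs=[gappy], output=toy_output,
            rules=[FuzzyRule({"x": "small"}, "low")])
        with pytest.warns(NoRuleFiredWarning):
            out = fis.infer({"x": 0.9})
        assert out == pytest.approx(5.0)  # output-domain midpoint

    def test_missing_input_rejected(self, toy_fis):
        with pytest.raises(KeyError, match="x"):
            toy_fis.infer({})

    def test_rule_referencing_unknown_term_rejected_at_build(self, toy_output):
        var = LinguisticVariable("x", (0.0, 1.0), {"small": trapezoid(0, 0, 0.5, 1)})
        with pytest.raises(ValueError, match="bogus"):
            FuzzyInferenceSystem(inputs=[var], output=toy_output,
                                 rules=[FuzzyRule({"x": "bogus"}, "low")])


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self, fis):
        clone = type(fis).from_yaml(fis.to_yaml())
        assert clone.to_dict() == fis.to_dict()

    def test_json_round_trip_is_lossless(self, fis):
        clone = type(fis).from_json(fis.to_json())
        assert clone.to_dict() == fis.to_dict()

    def test_round_trip_preserves_predictions(self, fis):
        clone = type(fis).from_yaml(fis.to_yaml())
        point = {"pm10": 47.0, "no2": 63.0, "temperature": 28.0, "wind": 2.1}
        assert clone.infer(point) == pytest.approx(fis.infer(point), abs=1e-12)
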