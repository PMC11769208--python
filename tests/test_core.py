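"""Unit and property tests for the weighted multicriteria engine."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdrisk.core import (
    CriteriaTable,
    CriterionDef,
    CriterionKind,
    InvalidInputError,
    RiskInput,
    RoundingMode,
    blend_likelihoods,
    compute_weight_coefficients,
    element_factor,
    round_half_even,
    scenario_probability,
    verify_normalization,
)


class TestWeightCoefficients:
    @pytest.mark.parametrize("scores,mode,expected", [
        ((1, 1, 1, 1, 1, 2), "table_match",
         [0.143, 0.143, 0.143, 0.143, 0.143, 0.285]),
        ((1, 1, 1, 2, 1, 1, 2), "table_match",
         [0.111, 0.111, 0.111, 0.222, 0.111, 0.111, 0.223]),
        ((1, 1, 1, 2, 1, 1, 2), "display3",
         [0.111, 0.111, 0.111, 0.222, 0.111, 0.111, 0.222]),
        ((1, 1, 1, 1, 1, 2), "display3",
         [0.143, 0.143, 0.143, 0.143, 0.143, 0.286]),
        ((1, 1, 1, 1), "exact", [Fraction(1, 4)] * 4),
    ])
    def test_published_and_trivial_vectors(self, scores, mode, expected):
        assert compute_weight_coefficients(scores, mode) == expected

    def test_exact_mode_is_rational_and_normalized(self):
        q = compute_weight_coefficients([3, 1, 5], RoundingMode.EXACT)
        assert all(isinstance(x, Fraction) for x in q)
        assert sum(q) == 1

    @pytest.mark.parametrize("bad", [[], [0, 1], [1, -2], [1.5, 1]])
    def test_invalid_scores_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            compute_weight_coefficients(bad)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=12))
    @settings(deadline=None)
    def test_exact_normalization_property(self, scores):
        assert sum(compute_weight_coefficients(scores, "exact")) == 1

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=12))
    @settings(deadline=None)
    def test_table_match_display_sums_to_one(self, scores):
        q = compute_weight_coefficients(scores, "table_match")
        assert round(sum(q) * 1000) == 1000


class TestElementFactor:
    @pytest.mark.parametrize("a,q,expected", [
        (1.120, 0.143, 0.160),   # sex criterion, male level
        (1.009, 0.222, 0.224),   # shoulder symmetry, left
        (0.161, 0.143, 0.023),   # neck readiness, high
    ])
    def test_published_cells_display_mode(self, a, q, expected):
        assert element_factor(a, q, "display3").value == expected

    def test_unit_likelihood_returns_weight(self):
        assert element_factor(1.0, 0.5).value == 0.5

    def test_exact_mode_full_precision(self):
        f = element_factor(1.018, float(Fraction(1, 7)))
        assert f.value == pytest.approx(1.018 / 7, abs=1e-15)

    @pytest.mark.parametrize("a,q", [(0, 0.5), (-1, 0.5), (1, 0), (1, 1.5)])
    def test_domain_errors(self, a, q):
        with pytest.raises(InvalidInputError):
            element_factor(a, q)


class TestBlendLikelihoods:
    def test_equal_share_blend_of_belt_levels(self):
        assert blend_likelihoods((0.919, 1.041), (0.5, 0.5)) == pytest.approx(0.980)

    def test_degenerate_mixture_returns_first(self):
        assert blend_likelihoods((0.7, 1.3), (1.0, 0.0)) == 0.7

    def test_constant_mixture(self):
        assert blend_likelihoods((1.0, 1.0), (0.25, 0.75)) == 1.0

    def test_shares_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            blend_likelihoods((1.0, 1.0), (0.6, 0.6))

    @given(
        a1=st.floats(0.1, 3.0), a2=st.floats(0.1, 3.0),
        c1=st.floats(0.0, 1.0),
    )
    @settings(deadline=None)
    def test_blend_bounded_by_inputs(self, a1, a2, c1):
        a = blend_likelihoods((a1, a2), (c1, 1.0 - c1))
        assert min(a1, a2) - 1e-12 <= a <= max(a1, a2) + 1e-12


def _factors(likelihoods, scores, mode="exact"):
    qs = compute_weight_coefficients(scores, mode)
    return [
        element_factor(a, float(q), mode, criterion=f"c{i}")
        for i, (a, q) in enumerate(zip(likelihoods, qs))
    ]


class TestScenarioProbability:
    def test_neutral_likelihoods_return_baseline(self):
        out = scenario_probability(RiskInput(0.37, _factors([1, 1, 1], [1, 2, 5])))
        assert out.probability == pytest.approx(0.37, abs=1e-15)
        assert not out.clipped

    def test_worked_shift_example_factor_sum_one(self):
        out = scenario_probability(RiskInput(0.5, _factors([1.0] * 4, [1] * 4)))
        assert out.probability == pytest.approx(0.5, abs=1e-15)

    def test_baseline_times_published_factor_sum(self):
        # neck baseline at age 43 scaled by the table's all-default sum 1.013
        factors = _factors([1.013], [1])
        out = scenario_probability(RiskInput(0.46533, factors))
        assert out.probability == pytest.approx(0.4714, abs=5e-5)

    def test_clipping_flags_and_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = scenario_probability(RiskInput(0.9, _factors([2.0, 2.0], [1, 1])))
        assert out.clipped and out.probability == 1.0

    def test_factor_table_mismatch_rejected(self):
        table = CriteriaTable(region="neck", criteria=[
            CriterionDef("a", 1, CriterionKind.PARAMETRIC),
            CriterionDef("b", 1, CriterionKind.PARAMETRIC),
        ])
        factors = _factors([1.0], [1])
        with pytest.raises(InvalidInputError):
            scenario_probability(RiskInput(0.5, factors), table)

    @given(
        q_scale=st.floats(0.1, 1.9),
        likelihoods=st.lists(st.floats(0.2, 1.8), min_size=1, max_size=6),
    )
    @settings(deadline=None)
    def test_linear_in_baseline(self, q_scale, likelihoods):
        factors = _factors(likelihoods, [1] * len(likelihoods))
        base = 0.4
        p1 = scenario_probability(RiskInput(base, factors))
        p2 = scenario_probability(RiskInput(min(1.0, base * q_scale), factors))
        if not (p1.clipped or p2.clipped):
            assert p2.probability == pytest.approx(
                p1.probability * min(1.0, base * q_scale) / base, rel=1e-12)

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_matches_exact_rational_oracle(self, data):
        n = data.draw(st.integers(1, 7))
        scores = data.draw(st.lists(st.integers(1, 9), min_size=n, max_size=n))
        # likelihoods as exact thousandths, like published tables
        milli = data.draw(st.lists(st.integers(100, 3000), min_size=n, max_size=n))
        base = Fraction(data.draw(st.integers(1, 999)), 1000)
        qs = compute_weight_coefficients(scores, "exact")
        oracle = base * sum(Fraction(m, 1000) * q for m, q in zip(milli, qs))
        factors = [
            element_factor(m / 1000, float(q), criterion=f"c{i}")
            for i, (m, q) in enumerate(zip(milli, qs))
        ]
        got = scenario_probability(RiskInput(float(base), factors))
        assert got.probability == pytest.approx(min(1.0, float(oracle)), abs=1e-12)


class TestNormalizationCheck:
    def test_exact_mode_zero_residual(self, neck_table):
        exact = CriteriaTable(region="neck", criteria=neck_table.criteria,
                              rounding_mode="exact")
        check = verify_normalization(exact)
        assert check.ok and abs(check.residual) <= 1e-12

    def test_elbow_display_residual_reported(self, tables):
        check = verify_normalization(tables["elbow"])
        assert check.ok  # within display tolerance...
        assert check.residual == pytest.approx(-0.001, abs=1e-9)  # ...but visible

    def test_manually_broken_weights_fail(self, neck_table, monkeypatch):
        broken = CriteriaTable(region="neck", criteria=neck_table.criteria,
                               rounding_mode="exact")
        monkeypatch.setattr(CriteriaTable, "weight_coefficients",
                            lambda self, mode=None: [0.4, 0.5])
        check = verify_normalization(broken)
        assert not check.ok and check.residual == pytest.approx(-0.1)


class TestCriteriaTable:
    def test_json_round_trip_is_lossless(self, tables):
        for table in tables.values():
            again = CriteriaTable.from_json(table.to_json())
            assert again == table

    def test_single_criterion_table_is_legal(self):
        t = CriteriaTable(region="neck",
                          criteria=[CriterionDef("only", 3,
                                                 CriterionKind.PARAMETRIC)])
        assert t.weight_coefficients() == [Fraction(1)]

    def test_duplicate_names_rejected(self):
        crit = CriterionDef("x", 1, CriterionKind.PARAMETRIC)
        with pytest.raises(InvalidInputError):
            CriteriaTable(region="neck", criteria=[crit, crit])

    def test_proportional_needs_two_levels(self):
        with pytest.raises(InvalidInputError):
            CriterionDef("side", 1, CriterionKind.PROPORTIONAL,
                         levels={"Left": 1.0})

    def test_nonpositive_likelihood_rejected(self):
        with pytest.raises(InvalidInputError):
            CriterionDef("sex", 1, levels={"Male": 0.0})


def test_round_half_even_is_bankers():
    assert round_half_even(Fraction(2, 7)) == 0.286
    assert round_half_even(0.0005) == 0.0
    assert round_half_even(0.0015) == 0.002
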