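"""Content model, input-quantity invariants, and configuration I/O."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mubudget import (
    DistributionSpec,
    InputQuantity,
    MeasurementModel,
    SchemaError,
    dumps_budget,
    evaluate_content,
    load_budget,
)


def q(symbol, value, u=None, rel=None, **kw):
    return InputQuantity(
        symbol, value, standard_uncertainty=u, relative_uncertainty=rel, **kw
    )


class TestEvaluateContent:
    def test_nominal_with_equal_areas_gives_purity_times_100(self, budget):
        # all dilution factors cancel by design: content = P * 100
        values = {s: budget.quantities[s].value for s in budget.model.symbols}
        values["At"] = values["Ast"]
        assert budget.model.evaluate(values) == pytest.approx(99.99, rel=1e-9)

    def test_nominal_area_ratio_gives_99_700(self, budget):
        # brute-force product oracle: 0.9971010 * 99.99
        oracle = (70.509 / 70.714) * (100 / 100) * (5 / 25) * (100 / 2) * 0.9999 * 10
        c = budget.content()
        assert c == pytest.approx(oracle, rel=1e-12)
        assert c == pytest.approx(99.700, abs=5e-4)

    def test_identity_product(self):
        model = MeasurementModel(numerator=("x",), denominator=("y",))
        assert model.evaluate({"x": 1.0, "y": 1.0}) == 1.0

    def test_missing_symbol_names_it(self):
        model = MeasurementModel(numerator=("x", "zz"))
        with pytest.raises(SchemaError, match="zz"):
            model.evaluate({"x": 1.0})

    def test_nonpositive_denominator_is_domain_error(self):
        model = MeasurementModel(numerator=("x",), denominator=("y",))
        with pytest.raises(ValueError):
            model.evaluate({"x": 1.0, "y": 0.0})

    @given(c=st.floats(0.1, 10.0))
    def test_scaling_a_numerator_scales_the_content(self, budget, c):
        values = {s: budget.quantities[s].value for s in budget.model.symbols}
        base = budget.model.evaluate(values)
        values["Pt"] *= c
        assert budget.model.evaluate(values) == pytest.approx(c * base, rel=1e-12)


class TestInputQuantity:
    def test_relative_filled_from_standard(self):
        assert q("V", 2.0, u=0.0042).relative_uncertainty == pytest.approx(0.0021)

    def test_standard_filled_from_relative(self):
        assert q("V", 2.0, rel=0.0021).standard_uncertainty == pytest.approx(0.0042)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(SchemaError, match="inconsistent"):
            q("V", 2.0, u=0.0042, rel=0.9)

    def test_relative_effect_factor_keeps_both(self):
        cx = q("Cx", 1.0, u=0.0004, rel=0.002, relative_effect=True)
        assert cx.standard_uncertainty == 0.0004
        assert cx.relative_uncertainty == 0.002

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(value=-1.0, u=0.1),
            dict(value=2.0, u=0.1, dof=0.5),
            dict(value=2.0),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        value = kwargs.pop("value")
        u = kwargs.pop("u", None)
        with pytest.raises(SchemaError):
            q("V", value, u=u, **kwargs)


class TestDistributionSpec:
    def test_triangular_implied_sd(self):
        d = DistributionSpec("triangular", a=1.99, b=2.01)
        assert d.implied_sd == pytest.approx(0.02 / (2 * math.sqrt(6)), rel=1e-9)
        assert d.implied_sd == pytest.approx(0.004082, abs=5e-7)

    def test_rectangular_implied_sd(self):
        d = DistributionSpec("rectangular", a=0.0, b=1.0)
        assert d.implied_sd == pytest.approx(1 / (2 * math.sqrt(3)))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="lognormal", mean=1, sd=1),
            dict(family="rectangular", a=2.0, b=1.0),
            dict(family="normal", mean=1.0, sd=-1.0),
            dict(family="triangular", a=1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(SchemaError):
            DistributionSpec(**kwargs)


class TestBudgetIO:
    def test_packaged_fixture_shape(self, budget):
        assert len(budget.quantities) == 11
        assert budget.n_distribution_rows == 16
        assert budget.reported_content == 99.41
        for sym in ("At", "Ast", "Pt", "Vt1", "Vp", "Vt2", "Vt", "VSample",
                    "P", "delta_r", "Cx"):
            assert sym in budget.quantities

    def test_fixture_matches_published_budget_values(self, budget):
        expect = {
            "At": (70.509, 0.0022),
            "Ast": (70.714, 0.0022),
            "Pt": (100.0, 0.01155),
            "Vt1": (100.0, 0.06339),
            "Vt2": (25.0, 0.02034),
            "Vp": (5.0, 0.00659),
            "Vt": (100.0, 0.06339),
            "VSample": (2.0, 0.0042),
            "P": (0.9999, 0.000058),
            "delta_r": (1.0, 0.0005),
        }
        for sym, (value, u) in expect.items():
            assert budget.quantities[sym].value == value
            assert budget.quantities[sym].standard_uncertainty == u
        assert budget.quantities["Cx"].relative_uncertainty == 0.002

    def test_json_round_trip_preserves_values(self, budget):
        clone = load_budget(dumps_budget(budget), fmt="json")
        assert clone.content() == budget.content()
        assert clone.n_distribution_rows == budget.n_distribution_rows
        for sym, orig in budget.quantities.items():
            assert clone.quantities[sym] == orig
        assert dumps_budget(clone) == dumps_budget(budget)

    def test_empty_quantity_list_is_schema_error(self):
        text = '[model]\nnumerator = ["x"]\n'
        with pytest.raises(SchemaError, match="quantities"):
            load_budget(text)

    def test_unknown_family_reports_path(self):
        text = (
            '[model]\nnumerator = ["x"]\n'
            "[quantities.x]\nvalue = 1.0\nstandard_uncertainty = 0.1\n"
            '[distributions.x.main]\nfamily = "cauchy"\n'
        )
        with pytest.raises(SchemaError, match="distributions.x.main"):
            load_budget(text)

    def test_distribution_vs_declared_u_cross_check(self):
        # declared u 0.1 but rectangular bounds implying sd ~0.0289: >3% off
        text = (
            '[model]\nnumerator = ["x"]\n'
            "[quantities.x]\nvalue = 1.0\nstandard_uncertainty = 0.1\n"
            '[distributions.x.main]\nfamily = "rectangular"\na = 0.95\nb = 1.05\n'
        )
        with pytest.raises(SchemaError, match="implied"):
            load_budget(text)
        assert load_budget(text, check=False).n_distribution_rows == 1
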