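"""Costing layer: cashflow arithmetic, NPV, cumulative present value,
labor/maintenance/investment calibration and the breakeven machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioscrub.lcc import (
    CashflowSeries,
    PriceTable,
    annual_cashflow,
    breakeven_grid,
    cumulative_present_value,
    investment_cost,
    irr,
    labor_cost,
    maintenance_cost,
    npv,
)


class TestAnnualCashflow:
    def test_zero_lines(self):
        assert annual_cashflow({}) == 0.0
        assert annual_cashflow({"a": 0.0, "b": 0.0}) == 0.0

    @given(
        values=st.lists(
            st.floats(min_value=-1e7, max_value=1e7, allow_nan=False), min_size=1, max_size=8
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_permutation_invariant_and_linear(self, values):
        lines = {f"l{i}": v for i, v in enumerate(values)}
        shuffled = dict(reversed(list(lines.items())))
        assert annual_cashflow(lines) == pytest.approx(annual_cashflow(shuffled))
        doubled = {k: 2 * v for k, v in lines.items()}
        assert annual_cashflow(doubled) == pytest.approx(2 * annual_cashflow(lines), rel=1e-12)


class TestNpv:
    def test_zero_interest_is_plain_sum(self):
        s = CashflowSeries(-1000.0, [100.0, 200.0, 300.0], interest_rate=0.0)
        assert npv(s) == pytest.approx(-1000.0 + 600.0)

    def test_single_year_discounting(self):
        s = CashflowSeries(0.0, [100.0], interest_rate=0.015)
        assert npv(s) == pytest.approx(100.0 / 1.015, rel=1e-12)

    @pytest.mark.parametrize("rate", [0.015, 0.05, 0.12])
    @pytest.mark.parametrize("years", [1, 5, 20])
    def test_constant_flow_matches_annuity_closed_form(self, rate, years):
        r = -836348.0
        s = CashflowSeries.constant(0.0, r, years, rate)
        annuity = r * (1.0 - (1.0 + rate) ** -years) / rate
        assert npv(s) == pytest.approx(annuity, rel=1e-9)

    @given(rate1=st.floats(min_value=0.001, max_value=0.2), d=st.floats(min_value=1e-4, max_value=0.2))
    @settings(max_examples=100, derandomize=True)
    def test_npv_magnitude_decreasing_in_rate_for_uniform_sign(self, rate1, d):
        flows = [-100.0] * 10
        lo = npv(CashflowSeries(0.0, flows, rate1))
        hi = npv(CashflowSeries(0.0, flows, rate1 + d))
        assert abs(hi) < abs(lo)

    def test_validation(self):
        with pytest.raises(ValueError):
            CashflowSeries(0.0, [], 0.015)
        with pytest.raises(ValueError):
            CashflowSeries(0.0, [1.0], -1.5)


class TestCumulativePresentValue:
    def test_zero_interest_running_sums(self):
        s = CashflowSeries(-10.0, [1.0, 2.0, 3.0], 0.0)
        np.testing.assert_allclose(cumulative_present_value(s), [-9.0, -7.0, -4.0])

    def test_first_year_element(self):
        s = CashflowSeries(-500.0, [100.0, 100.0], 0.015)
        assert cumulative_present_value(s)[0] == pytest.approx(-500.0 + 100.0 / 1.015)

    def test_final_element_equals_npv_on_random_series(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            s = CashflowSeries(
                float(rng.normal(scale=1e6)),
                list(rng.normal(scale=1e5, size=rng.integers(1, 30))),
                float(rng.uniform(0.0, 0.2)),
            )
            assert cumulative_present_value(s)[-1] == pytest.approx(npv(s), rel=1e-12, abs=1e-6)


class TestIrr:
    def test_undefined_for_uniform_sign_flows(self):
        assert np.isnan(irr(CashflowSeries(-100.0, [-10.0] * 5)))

    def test_root_for_mixed_flows(self):
        s = CashflowSeries(-100.0, [60.0, 60.0])
        rate = irr(s)
        t = np.arange(3)
        flows = np.array([-100.0, 60.0, 60.0])
        assert np.sum(flows / (1 + rate) ** t) == pytest.approx(0.0, abs=1e-8)


class TestCalibratedCostStructure:
    """The fitted capital/labor/maintenance parameters reproduce the
    baseline totals they were anchored to (within printed rounding)."""

    prices = PriceTable()

    def test_investment_totals(self):
        assert investment_cost("CS", 3.70) == pytest.approx(-51672.0, abs=1.0)
        assert investment_cost("BS-PG", 3.70, 1000.3, 2277.0) == pytest.approx(
            -3191321.0, abs=60.0
        )

    def test_maintenance_totals(self):
        inv_cs = investment_cost("CS", 3.70)
        inv_bs = investment_cost("BS-PG", 3.70, 1000.3, 2277.0)
        assert maintenance_cost("CS", inv_cs, self.prices) == pytest.approx(-2885.0, abs=2.0)
        assert maintenance_cost("BS-PG", inv_bs, self.prices) == pytest.approx(
            -131699.0, abs=10.0
        )

    def test_labor_lines(self):
        assert labor_cost("CS", self.prices) == pytest.approx(-6395.0, abs=1.0)
        assert labor_cost("BS-PG", self.prices) == pytest.approx(-28473.0, abs=1.0)

    def test_labor_formula_structure(self):
        # wage x 37.5 h x 52 weeks x (1 + 35%) per FTE
        assert labor_cost("CS", self.prices, fte=1.0) == pytest.approx(
            -self.prices.labor_wage_eur_h * 37.5 * 52 * 1.35
        )


class TestBreakevenGrid:
    def _results(self):
        from bioscrub.lcc import LccResult

        series_bs = CashflowSeries.constant(-3.2e6, -1.5e6, 20, 0.015)
        bs = LccResult(
            scenario="BS-PCG",
            operative_lines={
                "carbon_source": -4310.0 * 520.0,
                "biogas_revenue": 4000.0 * 68.9,
                "other": -400000.0,
            },
            labor=-28473.0,
            maintenance=-131699.0,
            investment=-3.2e6,
            cashflow=-4310.0 * 520.0 + 4000.0 * 68.9 - 400000.0 - 28473.0 - 131699.0,
            npv=0.0,
            series=series_bs,
            quantities={"carbon_t_y": 4310.0, "biogas_mwh_y": 4000.0},
        )
        series_cs = CashflowSeries.constant(-51672.0, -836348.0, 20, 0.015)
        cs = LccResult(
            scenario="CS",
            operative_lines={"other": -836348.0},
            labor=0.0,
            maintenance=0.0,
            investment=-51672.0,
            cashflow=-836348.0,
            npv=npv(series_cs),
            series=series_cs,
        )
        return bs, cs

    def test_surface_monotonicity(self):
        bs, cs = self._results()
        grid = breakeven_grid(bs, cs, np.linspace(0, 1000, 9), np.linspace(0, 300, 9))
        surf = grid["npv_bs"]
        assert np.all(np.diff(surf, axis=0) <= 1e-9)  # dearer glycerol never helps
        assert np.all(np.diff(surf, axis=1) >= -1e-9)  # dearer gas never hurts

    def test_corner_maximum(self):
        bs, cs = self._results()
        grid = breakeven_grid(bs, cs, np.linspace(0, 1000, 5), np.linspace(0, 300, 5))
        delta = grid["delta"]
        assert delta[0, -1] == pytest.approx(np.max(delta))

    def test_isoline_brackets_sign_change(self):
        bs, cs = self._results()
        grid = breakeven_grid(bs, cs, np.linspace(0, 1000, 9), np.linspace(0, 300, 9))
        if grid["iso_line"]:
            for gly, gas in grid["iso_line"]:
                assert 0 <= gly <= 1000 and 0 <= gas <= 300

    def test_empty_isoline_is_not_an_error(self):
        bs, cs = self._results()
        grid = breakeven_grid(bs, cs, np.linspace(900, 1000, 3), np.linspace(0, 1, 3))
        assert isinstance(grid["iso_line"], list)

    def test_rejects_non_monotone_axes(self):
        bs, cs = self._results()
        with pytest.raises(ValueError):
            breakeven_grid(bs, cs, [1.0, 1.0], [0.0, 1.0])
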