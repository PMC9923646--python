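"""Currency conversion, uplift, capital annualization and staff-time valuation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from eecc_costing import (
    CareLevel,
    CareStream,
    CostCategory,
    CostType,
    CostingContext,
    Country,
    Currency,
    Money,
    ResourceLine,
    Severity,
    StaffCadre,
    UnitPrice,
    ValidationError,
    annualize_capital,
    annuity_factor,
    apply_uplift,
    convert_to_usd,
    line_daily_cost,
    staff_cost_per_patient_day,
)

BOTH = frozenset({CareLevel.EECC, CareLevel.ACC})


def _line(item_id, category, qty, stream=CareStream.TREATMENT):
    return ResourceLine(
        item_id, item_id, category, stream, BOTH,
        {Severity.MODERATE: 0.0, Severity.SEVERE: qty, Severity.CRITICAL: qty},
    )


class TestFxAndUplift:
    @pytest.mark.parametrize(
        "amount,currency,expected",
        [
            (2300, Currency.TZS, 1.0),
            (115, Currency.KES, 1.0),
            (0, Currency.TZS, 0.0),
            (42.5, Currency.USD, 42.5),
        ],
    )
    def test_conversion_at_reference_rates(self, ctx, amount, currency, expected):
        assert convert_to_usd(Money(amount, currency), ctx) == pytest.approx(expected)

    def test_uplift_examples(self, ctx):
        assert apply_uplift(100.0, ctx) == pytest.approx(117.40)
        assert apply_uplift(0.0, ctx) == 0.0
        no_uplift = CostingContext(transport_uplift=0.0)
        assert apply_uplift(55.5, no_uplift) == 55.5

    def test_uplift_rejects_negative_price(self, ctx):
        with pytest.raises(ValidationError):
            apply_uplift(-1.0, ctx)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=20))
    def test_currency_associativity(self, amounts):
        # converting each line then summing equals summing then converting
        ctx = CostingContext()
        one_by_one = sum(convert_to_usd(Money(a, Currency.TZS), ctx) for a in amounts)
        in_bulk = convert_to_usd(Money(sum(amounts), Currency.TZS), ctx)
        assert one_by_one == pytest.approx(in_bulk, abs=1e-9 * max(1, in_bulk))


class TestAnnualization:
    @pytest.mark.parametrize(
        "price,life,rate,expected",
        [
            (1000, 5, 0.03, 218.35),   # AF = 4.57971
            (1000, 5, 0.0, 200.00),    # straight-line limit
            (1000, 1, 0.03, 1030.00),  # AF = 1/1.03
        ],
    )
    def test_reference_examples(self, price, life, rate, expected):
        assert annualize_capital(price, life, rate) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("rate", [0.0, 0.01, 0.03, 0.1])
    @pytest.mark.parametrize("life", range(1, 21))
    def test_matches_independent_closed_form(self, rate, life):
        # independent oracle: AF as an explicit geometric sum of discount factors
        af_oracle = sum((1.0 + rate) ** -t for t in range(1, life + 1))
        assert annuity_factor(rate, life) == pytest.approx(af_oracle, abs=1e-9)

    def test_af_below_life_for_positive_rates(self):
        for life in (1, 5, 20):
            assert annuity_factor(0.03, life) < life
        assert annuity_factor(1e-12, 7) == pytest.approx(7, rel=1e-6)

    def test_nonpositive_life_rejected(self):
        with pytest.raises(ValidationError):
            annualize_capital(100, 0, 0.03)


class TestStaffTime:
    def _cadre(self, salary=12000):
        return StaffCadre("nurse", "G5", Money(salary, Currency.USD), Country.TZ)

    def test_direct_arithmetic(self):
        ctx = CostingContext(working_minutes_per_year=120_000)
        assert staff_cost_per_patient_day(self._cadre(), 60, ctx) == pytest.approx(6.0)

    def test_zero_minutes_costs_nothing(self, ctx):
        assert staff_cost_per_patient_day(self._cadre(), 0, ctx) == 0.0

    @given(st.floats(0.1, 600))
    def test_linearity_in_minutes(self, minutes):
        ctx = CostingContext()
        single = staff_cost_per_patient_day(self._cadre(), minutes, ctx)
        double = staff_cost_per_patient_day(self._cadre(), 2 * minutes, ctx)
        assert double == pytest.approx(2 * single)


class TestLineDailyCost:
    def test_recurrent_consumable(self, ctx):
        line = _line("syringe", CostCategory.NONPHARMA_RECURRENT, qty=2.0)
        price = UnitPrice("syringe", Money(0.50, Currency.USD), CostType.RECURRENT)
        cost = line_daily_cost(line, price, Severity.SEVERE, ctx)
        assert cost.usd_per_patient_day == pytest.approx(1.00)

    def test_capital_constructed_round_number(self, ctx):
        # price chosen so the annualized cost is exactly 365 USD/yr at L=5:
        # price = 365 * AF(0.03, 5); with device fraction 1.0 -> 1 USD/day
        price_usd = 365 * annuity_factor(0.03, 5)
        line = _line("monitor", CostCategory.NONPHARMA_CAPITAL, qty=1.0)
        price = UnitPrice("monitor", Money(price_usd, Currency.USD),
                          CostType.CAPITAL, useful_life_years=5.0)
        cost = line_daily_cost(line, price, Severity.SEVERE, ctx)
        assert cost.usd_per_patient_day == pytest.approx(1.00, abs=1e-9)

    def test_price_line_mismatch_rejected(self, ctx):
        line = _line("a", CostCategory.PPE, 1.0)
        price = UnitPrice("b", Money(1, Currency.USD), CostType.RECURRENT)
        with pytest.raises(ValidationError):
            line_daily_cost(line, price, Severity.SEVERE, ctx)

    @given(
        qty=st.floats(0, 100),
        unit_price=st.floats(0, 1000),
        uplift=st.floats(0, 1),
    )
    def test_monotone_in_quantity_price_and_uplift(self, qty, unit_price, uplift):
        ctx = CostingContext(transport_uplift=uplift)
        line_lo = _line("x", CostCategory.PPE, qty)
        line_hi = _line("x", CostCategory.PPE, qty * 2 + 1)
        price = UnitPrice("x", Money(unit_price, Currency.USD),
                          CostType.RECURRENT, needs_uplift=True)
        price_hi = UnitPrice("x", Money(unit_price * 2 + 1, Currency.USD),
                             CostType.RECURRENT, needs_uplift=True)
        base = line_daily_cost(line_lo, price, Severity.SEVERE, ctx).usd_per_patient_day
        assert line_daily_cost(line_hi, price, Severity.SEVERE, ctx).usd_per_patient_day >= base
        assert line_daily_cost(line_lo, price_hi, Severity.SEVERE, ctx).usd_per_patient_day >= base
        hi_uplift = CostingContext(transport_uplift=uplift + 0.1)
        assert (
            line_daily_cost(line_lo, price, Severity.SEVERE, hi_uplift).usd_per_patient_day
            >= base
        )

    @given(life=st.floats(1, 19))
    def test_longer_useful_life_never_costs_more(self, life):
        ctx = CostingContext()
        line = _line("x", CostCategory.NONPHARMA_CAPITAL, 0.5)
        short = UnitPrice("x", Money(1000, Currency.USD), CostType.CAPITAL,
                          useful_life_years=life)
        long = UnitPrice("x", Money(1000, Currency.USD), CostType.CAPITAL,
                         useful_life_years=life + 1)
        assert (
            line_daily_cost(line, long, Severity.SEVERE, ctx).usd_per_patient_day
            <= line_daily_cost(line, short, Severity.SEVERE, ctx).usd_per_patient_day
        )


def test_context_defaults_are_the_reference_constants():
    ctx = CostingContext()
    assert ctx.fx_rate_tzs_per_usd == 2300
    assert ctx.fx_rate_kes_per_usd == 115
    assert ctx.discount_rate == 0.03
    assert ctx.transport_uplift == 0.174
    assert ctx.psa_draws == 1000
    assert ctx.ci_quantiles == (0.025, 0.975)


def test_context_validation():
    with pytest.raises(ValidationError):
        CostingContext(discount_rate=1.0)
    with pytest.raises(ValidationError):
        CostingContext(fx_rate_tzs_per_usd=0)
    with pytest.raises(ValidationError):
        CostingContext(working_minutes_per_year=0)
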