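"""Scenario bounds and the gamma Monte Carlo sensitivity analysis."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from eecc_costing import (
    CareLevel,
    CostBreakdown,
    CostCategory,
    CostingContext,
    Country,
    ScenarioBounds,
    ScenarioSpec,
    Severity,
    ValidationError,
    build_bounds,
    fit_gamma,
    run_psa,
    sample_totals,
)


def _breakdown(values, level=CareLevel.EECC):
    per_cat = {c: 0.0 for c in CostCategory}
    per_cat.update(values)
    return CostBreakdown(Country.TZ, Severity.SEVERE, level, per_cat)


def _bounds(per_category):
    full = {c: (0.0, 0.0, 0.0) for c in CostCategory}
    full.update(per_category)
    return ScenarioBounds(per_category=full)


class TestBuildBounds:
    def test_oxygen_multipliers(self):
        ref = _breakdown({CostCategory.OXYGEN: 4.74})
        spec = ScenarioSpec(staffing_mode="reference")
        bounds = build_bounds(ref, spec)
        assert bounds.per_category[CostCategory.OXYGEN] == pytest.approx(
            (3.555, 4.74, 5.925)
        )

    def test_identity_spec_gives_degenerate_bounds(self):
        ref = _breakdown({CostCategory.OXYGEN: 4.74, CostCategory.STAFFING: 3.35})
        spec = ScenarioSpec(
            oxygen_multipliers=(1.0, 1.0),
            pharma_multipliers=(1.0, 1.0),
            staffing_mode="reference",
        )
        bounds = build_bounds(ref, spec)
        for lo, mid, hi in bounds.per_category.values():
            assert lo == mid == hi

    def test_pharma_varies_only_for_advanced_care(self):
        values = {CostCategory.PHARMACEUTICALS: 1.70}
        spec = ScenarioSpec(staffing_mode="reference")
        eecc = build_bounds(_breakdown(values), spec)
        acc = build_bounds(_breakdown(values, level=CareLevel.ACC), spec)
        lo, _, hi = eecc.per_category[CostCategory.PHARMACEUTICALS]
        assert lo == hi == 1.70
        lo, _, hi = acc.per_category[CostCategory.PHARMACEUTICALS]
        assert (lo, hi) == pytest.approx((1.275, 2.125))

    def test_staffing_override_is_used(self):
        ref = _breakdown({CostCategory.STAFFING: 0.86})
        spec = ScenarioSpec(
            per_category_overrides={CostCategory.STAFFING: (0.21, 2.13)}
        )
        bounds = build_bounds(ref, spec)
        assert bounds.per_category[CostCategory.STAFFING] == (0.21, 0.86, 2.13)

    def test_cadre_range_without_schedule_rejected(self):
        ref = _breakdown({CostCategory.STAFFING: 3.35})
        with pytest.raises(ValidationError):
            build_bounds(ref, ScenarioSpec())

    def test_multiplier_pairs_must_bracket_one(self):
        with pytest.raises(ValidationError):
            ScenarioSpec(oxygen_multipliers=(1.1, 1.25))

    def test_bound_ordering_enforced(self):
        with pytest.raises(ValidationError):
            _bounds({CostCategory.OXYGEN: (5.0, 4.0, 6.0)})


class TestFitGamma:
    def test_moment_identity(self):
        # mean 4, sd 2 (bounds spanning 3.92 * 2): shape 4, scale 1
        shape, scale = fit_gamma(4.0, 4.0 - 3.92, 4.0 + 3.92)
        assert shape == pytest.approx(4.0)
        assert scale == pytest.approx(1.0)

    def test_degenerate_bounds_are_a_point_mass(self):
        assert fit_gamma(5.0, 5.0, 5.0) is None

    def test_reference_oxygen_fit(self):
        shape, scale = fit_gamma(4.74, 3.555, 5.925)
        assert shape == pytest.approx(61.46, abs=0.01)
        assert scale == pytest.approx(0.0771, abs=0.0001)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValidationError):
            fit_gamma(4.0, 5.0, 6.0)

    @given(
        ref=st.floats(0.1, 1000),
        spread=st.floats(0.001, 0.5),
    )
    def test_fitted_moments_match_inputs(self, ref, spread):
        low, high = ref * (1 - spread), ref * (1 + spread)
        shape, scale = fit_gamma(ref, low, high)
        assert shape * scale == pytest.approx(ref, rel=1e-9)  # mean
        sd = (high - low) / 3.92
        assert math.sqrt(shape) * scale == pytest.approx(sd, rel=1e-9)


class TestRunPsa:
    def test_degenerate_bounds_recover_point_estimate_exactly(self):
        bounds = _bounds({c: (v, v, v) for c, v in
                          [(CostCategory.OXYGEN, 4.74), (CostCategory.STAFFING, 3.35)]})
        result = run_psa(bounds, CostingContext(seed=7, psa_draws=100))
        assert result.mean_usd == bounds.total_reference
        assert result.ci_low_usd == result.ci_high_usd == result.mean_usd

    def test_identical_seed_is_bit_identical(self):
        bounds = _bounds({CostCategory.OXYGEN: (3.555, 4.74, 5.925),
                          CostCategory.STAFFING: (2.445, 3.35, 13.455)})
        ctx = CostingContext(seed=11)
        assert run_psa(bounds, ctx) == run_psa(bounds, ctx)

    def test_different_seeds_differ(self):
        bounds = _bounds({CostCategory.OXYGEN: (3.555, 4.74, 5.925)})
        r1 = run_psa(bounds, CostingContext(seed=1))
        r2 = run_psa(bounds, CostingContext(seed=2))
        assert r1.mean_usd != r2.mean_usd

    def test_scale_equivariance(self):
        base = {CostCategory.OXYGEN: (3.555, 4.74, 5.925),
                CostCategory.STAFFING: (2.445, 3.35, 13.455)}
        doubled = {c: tuple(2 * x for x in t) for c, t in base.items()}
        ctx = CostingContext(seed=3)
        r1 = run_psa(_bounds(base), ctx)
        r2 = run_psa(_bounds(doubled), ctx)
        assert r2.mean_usd == pytest.approx(2 * r1.mean_usd, rel=1e-12)
        assert r2.ci_low_usd == pytest.approx(2 * r1.ci_low_usd, rel=1e-12)
        assert r2.ci_high_usd == pytest.approx(2 * r1.ci_high_usd, rel=1e-12)

    def test_sample_mean_near_analytic_mean(self):
        # analytic mean of the total is the sum of category references
        per_cat = {CostCategory.OXYGEN: (3.555, 4.74, 5.925),
                   CostCategory.STAFFING: (2.445, 3.35, 13.455),
                   CostCategory.PHARMACEUTICALS: (1.275, 1.70, 2.125)}
        bounds = _bounds(per_cat)
        ctx = CostingContext(seed=1, psa_draws=10_000)
        var = sum(((hi - lo) / 3.92) ** 2 for lo, _, hi in per_cat.values())
        se = math.sqrt(var / ctx.psa_draws)
        result = run_psa(bounds, ctx)
        assert abs(result.mean_usd - bounds.total_reference) < 2 * se

    def test_interval_brackets_mean(self):
        bounds = _bounds({CostCategory.OXYGEN: (3.555, 4.74, 5.925)})
        r = run_psa(bounds, CostingContext(seed=5))
        assert r.ci_low_usd <= r.mean_usd <= r.ci_high_usd

    def test_single_gamma_quantiles_match_closed_form(self):
        # coverage sanity: empirical 2.5/97.5 percentiles of one gamma vs scipy ppf
        ref, lo, hi = 10.0, 8.0, 14.0
        shape, scale = fit_gamma(ref, lo, hi)
        bounds = _bounds({CostCategory.OXYGEN: (lo, ref, hi)})
        r = run_psa(bounds, CostingContext(seed=2, psa_draws=10_000))
        true_lo = scipy.stats.gamma.ppf(0.025, a=shape, scale=scale)
        true_hi = scipy.stats.gamma.ppf(0.975, a=shape, scale=scale)
        sd = (hi - lo) / 3.92
        assert r.ci_low_usd == pytest.approx(true_lo, abs=0.1 * sd)
        assert r.ci_high_usd == pytest.approx(true_hi, abs=0.1 * sd)

    def test_mean_error_shrinks_with_draws(self):
        bounds = _bounds({CostCategory.OXYGEN: (3.555, 4.74, 5.925)})
        errs = {}
        for n in (100, 10_000):
            errors = [
                abs(
                    run_psa(bounds, CostingContext(seed=s, psa_draws=n)).mean_usd
                    - bounds.total_reference
                )
                for s in range(8)
            ]
            errs[n] = np.mean(errors)
        assert errs[10_000] < errs[100]
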