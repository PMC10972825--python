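"""Relative-risk curves, per-unit conversion, and TMREL resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craburden.exposures import fit_mom
from craburden.risks import (RelativeRiskCurve, RiskCurveError,
                             RiskOutcomePair, RiskOutcomeRegistry,
                             ShapeError, TMRELSpec, category_to_per_unit,
                             resolve_tmrel, rr_at)


def log_linear(beta, risk="r", cause="c", reference=0.0):
    shape = "monotone_increasing" if beta > 0 else "monotone_decreasing"
    return RelativeRiskCurve(risk=risk, cause=cause, form="log_linear",
                             shape=shape, beta=beta, reference=reference)


class TestCategoryToPerUnit:
    def test_processed_meat_17pct_per_50g(self):
        # categories at 25 g and 75 g carrying RR 1.17 and 1.17^2
        beta = category_to_per_unit([25.0, 75.0], [1.17, 1.17 ** 2])
        assert beta == pytest.approx(np.log(1.17) / 50.0, rel=1e-12)

    def test_red_meat_18pct_per_100g(self):
        beta = category_to_per_unit([50.0, 150.0], [1.18, 1.18 ** 2])
        assert beta == pytest.approx(np.log(1.18) / 100.0, rel=1e-12)

    def test_unit_rrs_give_zero_slope(self):
        assert category_to_per_unit([10, 20, 30], [1.0, 1.0, 1.0]) == 0.0

    def test_exact_log_linear_reproduced(self):
        beta = np.log(1.3) / 10.0
        mids = [5.0, 15.0, 25.0]
        rrs = [np.exp(beta * m) for m in mids]
        assert category_to_per_unit(mids, rrs) == pytest.approx(beta)

    def test_single_category_rejected(self):
        with pytest.raises(RiskCurveError):
            category_to_per_unit([25.0], [1.17])

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(RiskCurveError):
            category_to_per_unit([25.0, 75.0], [1.17, -1.0])


class TestRRAt:
    def test_reference_gives_unity(self):
        curve = log_linear(0.05)
        assert rr_at(curve, 0.0) == pytest.approx(1.0)

    def test_processed_meat_curve(self):
        curve = log_linear(np.log(1.17) / 50.0)
        assert rr_at(curve, 50.0) == pytest.approx(1.17)
        assert rr_at(curve, 100.0) == pytest.approx(1.3689)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(x1=st.floats(-20, 20), x2=st.floats(-20, 20))
    def test_log_linearity(self, x1, x2):
        curve = log_linear(0.03)
        assert rr_at(curve, x1 + x2) == pytest.approx(
            rr_at(curve, x1) * rr_at(curve, x2), rel=1e-9)

    def test_tabulated_interpolates_and_holds_flat(self):
        curve = RelativeRiskCurve(
            risk="r", cause="c", form="tabulated_monotone",
            shape="monotone_increasing", reference=0.0,
            knots=(0.0, 5.0, 10.0), values=(1.0, 1.5, 2.0))
        assert curve.rr(0.0) == pytest.approx(1.0)
        assert 1.0 < curve.rr(2.5) < 1.5
        # constant extrapolation beyond last knot
        assert curve.rr(50.0) == pytest.approx(2.0)

    def test_tabulated_interpolation_monotone(self):
        curve = RelativeRiskCurve(
            risk="r", cause="c", form="tabulated_monotone",
            shape="monotone_increasing", reference=0.0,
            knots=(0.0, 2.0, 4.0, 8.0), values=(1.0, 1.2, 1.9, 2.0))
        grid = np.linspace(0, 8, 801)
        assert np.all(np.diff(curve.rr(grid)) >= -1e-12)


class TestShapeVerification:
    def test_contradictory_declared_shape_fails(self):
        with pytest.raises(ShapeError):
            RelativeRiskCurve(risk="r", cause="c", form="tabulated_monotone",
                              shape="monotone_increasing", reference=0.0,
                              knots=(0.0, 1.0, 2.0), values=(1.0, 2.0, 1.5))

    def test_beta_sign_checked(self):
        with pytest.raises(ShapeError):
            RelativeRiskCurve(risk="r", cause="c", form="log_linear",
                              shape="monotone_decreasing", beta=0.1)

    def test_reference_rr_must_be_unity(self):
        with pytest.raises(RiskCurveError):
            RelativeRiskCurve(risk="r", cause="c", form="tabulated_monotone",
                              shape="monotone_increasing", reference=0.0,
                              knots=(0.0, 5.0), values=(1.1, 2.0))


class TestResolveTmrel:
    def test_harmful_increasing_gets_zero(self):
        curve = log_linear(0.05)
        assert resolve_tmrel(TMRELSpec("fixed_zero"), curve) == 0.0

    def test_inverted_v_nadir_read_off(self):
        curve = RelativeRiskCurve(
            risk="r", cause="c", form="tabulated_monotone",
            shape="inverted_V", reference=3.0,
            knots=(0.0, 3.0, 6.0), values=(1.5, 1.0, 1.8))
        assert resolve_tmrel(TMRELSpec("nadir"), curve) == \
            pytest.approx(3.0, abs=1e-2)

    def test_protective_85th_percentile(self):
        curve = log_linear(-0.01)
        dist = fit_mom(100.0, 10.0, "normal")
        assert resolve_tmrel(TMRELSpec("percentile_85"), curve, dist) == \
            pytest.approx(110.364, abs=5e-4)

    def test_nadir_on_monotone_curve_rejected(self):
        with pytest.raises(ShapeError):
            resolve_tmrel(TMRELSpec("nadir"), log_linear(0.05))

    def test_percentile_without_distribution_rejected(self):
        with pytest.raises(RiskCurveError):
            resolve_tmrel(TMRELSpec("percentile_85"), log_linear(-0.01))

    def test_nadir_tie_broken_toward_lowest_exposure(self):
        # flat bottom between 2 and 4: the lowest grid point wins
        curve = RelativeRiskCurve(
            risk="r", cause="c", form="tabulated_monotone",
            shape="inverted_V", reference=2.0,
            knots=(0.0, 2.0, 4.0, 6.0), values=(1.5, 1.0, 1.0, 1.8))
        assert resolve_tmrel(TMRELSpec("nadir"), curve) == \
            pytest.approx(2.0, abs=1e-2)


class TestRegistry:
    def test_duplicate_pair_rejected(self):
        reg = RiskOutcomeRegistry()
        pair = RiskOutcomePair("r", "c", log_linear(0.05),
                               TMRELSpec("fixed_zero"))
        reg.add(pair)
        with pytest.raises(RiskCurveError):
            reg.add(pair)

    def test_lookup_failure_names_the_pair(self):
        reg = RiskOutcomeRegistry()
        with pytest.raises(RiskCurveError, match="smoking"):
            reg.get("smoking", "lung_cancer")

    def test_non_minimal_rr_at_tmrel_warns(self):
        # decreasing curve with TMREL pinned at 0: RR(0) is the maximum
        curve = log_linear(-0.05)
        reg = RiskOutcomeRegistry()
        with pytest.warns(UserWarning, match="not the curve minimum"):
            reg.add(RiskOutcomePair("r", "c", curve,
                                    TMRELSpec("explicit_value", 0.0)),
                    dist=fit_mom(10.0, 2.0, "normal"))
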