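"""PAF formulas: continuous quadrature, discrete sums, combination, draws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craburden.exposures import categorical_exposure, fit_mom
from craburden.paf import (PAFError, attributable_burden, combine_pafs,
                           paf_continuous, paf_continuous_draws,
                           paf_discrete, ui_from_draws)
from craburden.risks import RelativeRiskCurve


def log_linear(beta, reference=0.0):
    shape = "monotone_increasing" if beta > 0 else "monotone_decreasing"
    return RelativeRiskCurve(risk="r", cause="c", form="log_linear",
                             shape=shape, beta=beta, reference=reference)


class TestContinuous:
    def test_point_mass_at_tmrel_is_zero(self):
        dist = fit_mom(5.0, 0.0, "normal")
        assert paf_continuous(dist, log_linear(0.1), tmrel=5.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_point_mass_with_rr_two(self):
        # all exposure at x* with RR(x*) = 2 and RR(tmrel) = 1 -> (2-1)/2
        beta = np.log(2.0) / 10.0
        dist = fit_mom(10.0, 0.0, "normal")
        assert paf_continuous(dist, log_linear(beta), tmrel=0.0) == \
            pytest.approx(0.5, rel=1e-9)

    def test_quadrature_matches_monte_carlo(self, rng):
        dist = fit_mom(2.0, 1.0, "lognormal")
        curve = log_linear(np.log(1.5))
        paf_q = paf_continuous(dist, curve, tmrel=0.0)
        x = dist.sample(1_000_000, rng)
        rr = np.asarray(curve.rr(x))
        paf_mc = (rr.mean() - 1.0) / rr.mean()
        assert abs(paf_q - paf_mc) < 0.005

    def test_protective_direction_negative(self):
        # population below the counterfactual exposure: negative PAF allowed
        dist = fit_mom(50.0, 5.0, "normal")
        curve = log_linear(-0.01)
        paf = paf_continuous(dist, curve, tmrel=40.0)
        assert paf < 0

    def test_draw_path_matches_scalar_path(self):
        dist = fit_mom(26.0, 4.0, "lognormal")
        curve = log_linear(np.log(1.1) / 5.0, reference=21.0)
        scalar = paf_continuous(dist, curve, tmrel=21.0)
        batch = paf_continuous_draws(np.array([26.0]), 4.0, "lognormal",
                                     dist.support, curve, 21.0)
        assert batch[0] == pytest.approx(scalar, abs=1e-6)


class TestDiscrete:
    def test_dichotomous_closed_form(self):
        # p (r-1) / (1 + p (r-1)) with p = 0.5, r = 2 -> 1/3
        assert paf_discrete([0.5, 0.5], [1.0, 2.0]) == \
            pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_dichotomous_cohort_enumeration(self):
        # 1,000,000-person cohort, half exposed at RR 2: among cases,
        # the excess fraction is the PAF
        n = 1_000_000
        exposed = n // 2
        cases_unexposed = (n - exposed) * 1.0
        cases_exposed = exposed * 2.0
        total = cases_unexposed + cases_exposed
        counterfactual = n * 1.0
        assert paf_discrete([0.5, 0.5], [1.0, 2.0]) == \
            pytest.approx((total - counterfactual) / total, rel=1e-12)

    def test_zero_exposure_prevalence(self):
        assert paf_discrete([1.0, 0.0], [1.0, 5.0]) == 0.0

    def test_three_categories(self):
        # (0.2 + 0.45 + 1.5 - 1) / 2.15
        assert paf_discrete([0.2, 0.3, 0.5], [1.0, 1.5, 3.0]) == \
            pytest.approx(1.15 / 2.15, rel=1e-12)

    def test_prevalence_sum_violation(self):
        with pytest.raises(PAFError):
            paf_discrete([0.5, 0.6], [1.0, 2.0])

    def test_mixture_of_point_masses_matches_discrete(self):
        beta = 0.21
        curve = log_linear(beta)
        values = [0.0, 2.0, 5.0]
        prev = [0.3, 0.5, 0.2]
        dist = categorical_exposure(["a", "b", "c"], prev, values)
        rrs = [float(curve.rr(v)) for v in values]
        assert paf_continuous(dist, curve, tmrel=0.0) == \
            pytest.approx(paf_discrete(prev, rrs, 0), abs=1e-9)


class TestCombine:
    def test_identity_for_single_input(self):
        assert combine_pafs([0.5]) == 0.5

    def test_two_halves(self):
        assert combine_pafs([0.5, 0.5]) == pytest.approx(0.75)

    def test_eleven_published_pafs(self):
        pafs = [0.2324, 0.0551, 0.0507, 0.0437, 0.0350, 0.0341, 0.0350,
                0.0276, 0.0074, 0.0063, 0.0049]
        assert combine_pafs(pafs) == pytest.approx(0.4347, abs=5e-5)

    def test_rejects_paf_above_one(self):
        with pytest.raises(PAFError):
            combine_pafs([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_bounds_property(self, pafs):
        combined = combine_pafs(pafs)
        assert combined <= 1.0 + 1e-12
        assert combined >= max(pafs) - 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 0.99), min_size=2, max_size=6))
    def test_order_invariance(self, pafs):
        assert combine_pafs(pafs) == pytest.approx(
            combine_pafs(list(reversed(pafs))), rel=1e-12)


class TestUiFromDraws:
    def test_constant_draws(self):
        assert ui_from_draws([5.0, 5.0, 5.0, 5.0]) == (5.0, 5.0, 5.0)

    def test_thousand_draw_percentile_rule(self):
        lo, hi, point = ui_from_draws(np.arange(1.0, 1001.0))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)
        assert point == pytest.approx(500.5)

    def test_symmetric_draws_point_is_midpoint(self):
        draws = np.concatenate([100.0 - np.arange(50), 100.0 + np.arange(50)])
        lo, hi, point = ui_from_draws(draws)
        assert point == pytest.approx((lo + hi) / 2.0, abs=1e-9)

    def test_single_draw_rejected(self):
        with pytest.raises(PAFError):
            ui_from_draws([1.0])


class TestAttributableBurden:
    def _tables(self):
        paf = pd.DataFrame({
            "risk": ["r", "r"], "cause": ["c1", "c2"],
            "location": ["L", "L"], "year": [2019, 2019],
            "sex": ["Male", "Male"], "age_group": ["40-44", "40-44"],
            "paf": [0.25, 0.0],
            "draw_0": [0.1, 0.0], "draw_1": [0.2, 0.0]})
        burden = pd.DataFrame({
            "measure": ["DALYs", "DALYs"], "cause": ["c1", "c2"],
            "location": ["L", "L"], "year": [2019, 2019],
            "sex": ["Male", "Male"], "age_group": ["40-44", "40-44"],
            "value": [1000.0, 400.0],
            "draw_0": [100.0, 50.0], "draw_1": [100.0, 50.0]})
        return paf, burden

    def test_point_and_drawwise_products(self):
        paf, burden = self._tables()
        att = attributable_burden(paf, burden)
        assert att.loc[0, "value"] == pytest.approx(250.0)
        assert att.loc[0, "draw_0"] == pytest.approx(10.0)
        assert att.loc[0, "draw_1"] == pytest.approx(20.0)
        assert att.loc[1, "value"] == 0.0

    def test_conservation_drawwise(self):
        paf, burden = self._tables()
        att = attributable_burden(paf, burden)
        for col, total in [("draw_0", 100.0), ("draw_1", 100.0)]:
            complement = (1.0 - paf.loc[0, col]) * total
            assert att.loc[0, col] + complement == total  # exact

    def test_missing_stratum_raises_with_keys(self):
        paf, burden = self._tables()
        paf.loc[1, "cause"] = "missing_cause"
        with pytest.raises(PAFError, match="missing_cause"):
            attributable_burden(paf, burden)
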