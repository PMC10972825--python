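"""Age-standardisation, aggregation safety, and trend arithmetic."""

import numpy as np
import pandas as pd
import pytest

from craburden.burden import (BurdenError, StandardPopulation,
                              age_standardize, aggregate, paf_from_burden,
                              percent_change, round_half_away)
from craburden.datasets import load_global_trends, load_standard_population


class TestAgeStandardize:
    def test_equal_rates_return_the_rate(self):
        std = StandardPopulation({"a": 0.6, "b": 0.4})
        assert age_standardize({"a": 100.0, "b": 100.0}, std) == \
            pytest.approx(100.0)

    def test_weighted_sum(self):
        std = StandardPopulation({"a": 0.6, "b": 0.4})
        assert age_standardize({"a": 100.0, "b": 200.0}, std) == \
            pytest.approx(140.0)

    def test_zero_rates(self):
        std = StandardPopulation({"a": 0.6, "b": 0.4})
        assert age_standardize({"a": 0.0, "b": 0.0}, std) == 0.0

    def test_missing_age_group_named(self):
        std = StandardPopulation({"a": 0.6, "b": 0.4})
        with pytest.raises(BurdenError, match="b"):
            age_standardize({"a": 100.0}, std)

    def test_crude_rate_recovered_under_matching_structure(self):
        # population structure equal to the standard: ASR == crude rate
        weights = {"a": 0.5, "b": 0.3, "c": 0.2}
        std = StandardPopulation(weights)
        rates = {"a": 50.0, "b": 80.0, "c": 200.0}
        pop = {k: 1e6 * w for k, w in weights.items()}
        crude = sum(rates[k] * pop[k] for k in pop) / sum(pop.values())
        assert age_standardize(rates, std) == pytest.approx(crude)

    def test_invariant_to_uniform_population_scaling(self):
        std = StandardPopulation({"a": 0.5, "b": 0.5})
        rates = {"a": 10.0, "b": 30.0}
        assert age_standardize(rates, std) == pytest.approx(
            age_standardize(rates, std))  # weights are fractions already

    def test_weights_must_sum_to_one(self):
        with pytest.raises(BurdenError):
            StandardPopulation({"a": 0.6, "b": 0.5})


class TestPafFromBurden:
    def test_simple_ratios(self):
        assert paf_from_burden(0.0, 1000.0) == 0.0
        assert paf_from_burden(250.0, 1000.0) == 0.25

    def test_drawwise_ratio_then_mean(self):
        # per-draw ratio {0.1, 0.3} -> point 0.2, not ratio of sums
        pafs = paf_from_burden(np.array([10.0, 30.0]),
                               np.array([100.0, 100.0]))
        assert pafs.mean() == pytest.approx(0.20)

    def test_zero_total_rejected(self):
        with pytest.raises(BurdenError):
            paf_from_burden(10.0, 0.0)


class TestPercentChange:
    def test_all_risks_dalys_row(self):
        assert round_half_away(percent_change(65478.5, 105037.38)) == 60.42

    def test_tobacco_dalys_row(self):
        assert round_half_away(percent_change(40262.81, 59323.57)) == 47.34

    def test_no_change(self):
        assert percent_change(123.4, 123.4) == 0.0

    def test_reverse_is_algebraic_inverse(self):
        a, b = 65478.5, 105037.38
        pc = percent_change(a, b)
        assert 1.0 + pc / 100.0 == pytest.approx(b / a, rel=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(BurdenError):
            percent_change(0.0, 10.0)


class TestAggregate:
    def _table(self):
        return pd.DataFrame({
            "measure": ["DALYs"] * 4, "metric": ["Number"] * 4,
            "cause": ["c"] * 4, "location": ["L"] * 4, "year": [2019] * 4,
            "sex": ["Male", "Male", "Female", "Female"],
            "age_group": ["a", "b", "a", "b"],
            "value": [10.0, 20.0, 30.0, 40.0],
            "draw_0": [1.0, 2.0, 3.0, 4.0]})

    def test_number_metrics_sum(self):
        agg = aggregate(self._table(), over=["sex", "age_group"])
        assert agg["value"].tolist() == [100.0]
        assert agg["draw_0"].tolist() == [10.0]

    def test_empty_group_set_is_identity(self):
        df = self._table()
        assert aggregate(df, over=[]).equals(df)

    def test_male_plus_female_published_totals(self):
        df = pd.DataFrame({
            "measure": ["DALYs"] * 2, "metric": ["Number"] * 2,
            "cause": ["all_cancers"] * 2, "location": ["Global"] * 2,
            "year": [2019] * 2, "age_group": ["All ages"] * 2,
            "sex": ["Male", "Female"],
            "value": [67474.0, 37563.38]})
        agg = aggregate(df, over=["sex"])
        assert agg.loc[0, "value"] == pytest.approx(105037.38, abs=0.01)

    def test_rates_pooled_not_averaged(self):
        df = pd.DataFrame({
            "measure": ["DALYs"] * 2, "metric": ["Rate"] * 2,
            "cause": ["c"] * 2, "location": ["A", "B"], "year": [2019] * 2,
            "sex": ["Both"] * 2, "age_group": ["all"] * 2,
            "value": [10.0, 30.0], "population": [100_000.0, 300_000.0]})
        agg = aggregate(df, over=["location"])
        assert agg.loc[0, "value"] == pytest.approx(25.0)  # not 20

    def test_rate_without_population_rejected(self):
        df = self._table()
        df["metric"] = "Rate"
        with pytest.raises(BurdenError, match="population"):
            aggregate(df, over=["sex"])

    def test_percent_sum_rejected(self):
        df = self._table()
        df["metric"] = "Percent"
        with pytest.raises(BurdenError):
            aggregate(df, over=["sex"])

    def test_aggregation_associative(self):
        df = self._table()
        once = aggregate(df, over=["sex", "age_group"])
        twice = aggregate(aggregate(df, over=["sex"]), over=["age_group"])
        pd.testing.assert_frame_equal(
            once.sort_index(axis=1), twice.sort_index(axis=1))


@pytest.fixture(scope="module")
def trends():
    return load_global_trends()


class TestPublishedTrendFixture:
    """Trend arithmetic recomputed from the published 1990/2019 endpoints."""

    def test_daly_count_cells_reproduce(self, trends):
        sub = trends[trends["measure"] == "dalys_thousands"]
        for _, row in sub.iterrows():
            pc = percent_change(row["value_1990"], row["value_2019"])
            # printed endpoints are rounded; 2-dp agreement up to 0.01 slack
            assert abs(round_half_away(pc) - row["pct_change_printed"]) \
                <= 0.011, row["risk"]

    def test_asdr_cells_reproduce_within_input_rounding(self, trends):
        sub = trends[trends["measure"] == "asdr_per_100k"]
        for _, row in sub.iterrows():
            pc = percent_change(row["value_1990"], row["value_2019"])
            assert abs(round_half_away(pc) - row["pct_change_printed"]) \
                <= 0.05, row["risk"]

    def test_standard_population_weights_valid(self):
        std = load_standard_population()
        assert len(std.age_groups) == 8
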