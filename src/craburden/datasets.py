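"""Bundled reference tables.

``load_global_trends`` returns the published global 1990/2019 values —
attributable-DALY counts (thousands), age-standardised DALY rates per
100,000, and age-standardised PAF percentages — for eleven level-2 risk
factors plus their combination, by sex, together with the printed percent
changes.  The DALY-count and rate percent changes are reproducible from the
printed endpoint values to about rounding precision; the PAF percent
changes were produced at draw level upstream and are retained for reference
only.

``load_standard_population`` returns a synthetic standard population
(age weights for the default 40–79 five-year bands) used for direct age
standardisation on synthetic worlds; it is not any published standard.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .burden import StandardPopulation

__all__ = ["load_global_trends", "load_standard_population"]


def _data_path(name: str):
    return resources.files("craburden.data").joinpath(name)


def load_global_trends() -> pd.DataFrame:
    """Published global trend endpoints by risk, sex, and measure.

    Columns: risk, sex, measure ∈ {dalys_thousands, asdr_per_100k,
    paf_pct}, value_1990, value_2019, pct_change_printed.
    """
    with resources.as_file(_data_path("global_trends_1990_2019.csv")) as p:
        return pd.read_csv(p)


def load_standard_population() -> StandardPopulation:
    """Synthetic standard-population age weights (sum to 1)."""
    with resources.as_file(
            _data_path("standard_population_synthetic.csv")) as p:
        df = pd.read_csv(p)
    return StandardPopulation(dict(zip(df["age_group"], df["weight"])))
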