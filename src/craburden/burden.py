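"""Age-standardisation, aggregation, and trend arithmetic for burden tables.

Burden tables are tidy DataFrames with identifier columns (``measure``,
``cause``, ``risk``, ``location``, ``year``, ``sex``, ``age_group``), a
``metric`` in {Number, Rate, Percent}, a ``value``, optional draw columns
``draw_0 ... draw_{D-1}``, and — for Rate rows — a ``population`` column so
pooled rates can be recomputed from numerators and denominators rather than
averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .paf import draw_columns

__all__ = [
    "BurdenError",
    "StandardPopulation",
    "TrendResult",
    "age_standardize",
    "paf_from_burden",
    "percent_change",
    "aggregate",
    "round_half_away",
]

ID_COLS = ["measure", "metric", "risk", "cause", "location", "year", "sex",
           "age_group"]


class BurdenError(ValueError):
    pass


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights of a reference population; positive and summing to 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = np.asarray(list(self.weights.values()), dtype=float)
        if np.any(w <= 0):
            raise BurdenError("standard-population weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise BurdenError(
                f"standard-population weights sum to {w.sum()}, expected 1")

    @property
    def age_groups(self) -> list[str]:
        return list(self.weights.keys())


@dataclass(frozen=True)
class TrendResult:
    value_start: float
    value_end: float
    percent_change: float


def age_standardize(rates: Mapping[str, float],
                    std: StandardPopulation) -> float:
    """Directly age-standardised rate: Σ weight_a × rate_a (per 100,000).

    Every age group of the standard must be present in ``rates``; a gap is
    reported by name rather than silently renormalised.
    """
    missing = [a for a in std.age_groups if a not in rates]
    if missing:
        raise BurdenError(f"missing age-specific rates for {missing}")
    return float(sum(std.weights[a] * rates[a] for a in std.age_groups))


def paf_from_burden(attributable, total):
    """PAF as attributable / total burden; draw-wise when arrays are given.

    The draw-wise ratio is taken per draw and only then summarised, which
    differs from the ratio of draw means whenever draws and totals co-vary.
    """
    att = np.asarray(attributable, dtype=float)
    tot = np.asarray(total, dtype=float)
    if np.any(tot <= 0):
        raise BurdenError("PAF undefined for non-positive total burden")
    out = att / tot
    return out if out.ndim else float(out)


def percent_change(v_start: float, v_end: float) -> float:
    """100 × (v_end − v_start) / v_start; requires a positive baseline."""
    if not v_start > 0:
        raise BurdenError(f"percent change undefined for baseline {v_start}")
    return 100.0 * (v_end - v_start) / v_start


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report-layer presentation rule)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def aggregate(burden: pd.DataFrame, over: Iterable[str]) -> pd.DataFrame:
    """Collapse a burden table over a subset of {age_group, sex, location, cause}.

    Number metrics sum (value and draws alike).  Rate metrics are recomputed
    from summed numerators and denominators — rate rows must carry a
    ``population`` column — never averaged.  Percent rows cannot be summed
    and raise; recompute them from aggregated numerators instead.
    """
    over = list(over)
    if not over:
        return burden.copy()
    allowed = {"age_group", "sex", "location", "cause", "year"}
    bad = set(over) - allowed
    if bad:
        raise BurdenError(f"cannot aggregate over {sorted(bad)}")
    for col in over:
        if col not in burden.columns:
            raise BurdenError(f"grouping column {col!r} not in table")

    metrics = set(burden["metric"].unique()) if "metric" in burden.columns \
        else {"Number"}
    if "Percent" in metrics:
        raise BurdenError(
            "Percent metrics cannot be summed; recompute from numerators")
    if "Rate" in metrics and "population" not in burden.columns:
        raise BurdenError(
            "Rate aggregation requires a population column to pool "
            "numerators and denominators")

    keys = [c for c in ID_COLS if c in burden.columns and c not in over]
    dcols = draw_columns(burden)
    frames = []
    for metric, sub in (burden.groupby("metric", sort=False)
                        if "metric" in burden.columns
                        else [("Number", burden)]):
        sub = sub.copy()
        if metric == "Rate":
            pop = sub["population"].to_numpy()
            for c in ["value"] + dcols:
                sub[c] = sub[c].to_numpy() * pop  # back to counts
            agg = sub.groupby(keys, as_index=False, sort=True)[
                ["value", "population"] + dcols].sum()
            for c in ["value"] + dcols:
                agg[c] = agg[c] / agg["population"]
        else:
            spec = {c: "sum" for c in ["value"] + dcols}
            if "population" in sub.columns:
                spec["population"] = "sum"
            agg = sub.groupby(keys, as_index=False, sort=True).agg(spec)
        agg["metric"] = metric
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
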