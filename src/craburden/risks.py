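"""Relative-risk curves RR(x) and theoretical minimum-risk exposure levels.

A risk–outcome pair (say, high body-mass index → colorectal cancer) is
described by a dose–response curve RR(x) giving the relative risk of the
outcome at exposure x against a reference exposure where RR = 1, together
with a rule for its counterfactual exposure, the TMREL:

* harmful risks with monotonically increasing RR — TMREL 0 (or an explicit
  biological floor);
* J/V-shaped risks — the exposure at the curve's nadir;
* protective risks with monotonically decreasing RR (e.g. fruit intake) —
  the 85th percentile of the observed exposure distribution.

Curve forms: ``log_linear`` (epidemiology's per-unit log-RR slope beta,
obtained from per-category effect sizes), ``tabulated_monotone`` (a fitted
monotone or V-shaped curve handed over as a knot table, interpolated with a
shape-preserving monotone cubic in log RR and held constant beyond the last
knot), and ``categorical`` (one RR per exposure category).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exposures import ExposureDistribution, ExposureError

__all__ = [
    "RiskCurveError",
    "ShapeError",
    "RelativeRiskCurve",
    "TMRELSpec",
    "RiskOutcomePair",
    "RiskOutcomeRegistry",
    "category_to_per_unit",
    "rr_at",
    "resolve_tmrel",
]

SHAPES = ("monotone_increasing", "monotone_decreasing", "inverted_V")
TMREL_RULES = ("fixed_zero", "nadir", "percentile_85", "explicit_value")

_NADIR_GRID = 10_001  # documented search resolution for the nadir rule


class RiskCurveError(ValueError):
    pass


class ShapeError(RiskCurveError):
    """Declared curve shape contradicts the curve's values."""


def category_to_per_unit(category_bounds: Sequence[float],
                         category_rrs: Sequence[float]) -> float:
    """Convert per-category RRs to a per-unit log-RR slope (beta).

    ``category_bounds`` are the exposure midpoints of the reporting
    categories; beta is the least-squares slope of log RR on those
    midpoints, so exactly log-linear inputs are reproduced exactly (e.g.
    RR 1.17 per 50 g of processed meat from categories at 25 g and 75 g
    with RRs 1.17 and 1.17²).
    """
    x = np.asarray(category_bounds, dtype=float)
    r = np.asarray(category_rrs, dtype=float)
    if x.size < 2:
        raise RiskCurveError("need at least two categories to infer a slope")
    if np.any(r <= 0):
        raise RiskCurveError("relative risks must be positive")
    if np.any(np.diff(x) <= 0):
        raise RiskCurveError("category midpoints must be strictly increasing")
    y = np.log(r)
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


@dataclass(frozen=True)
class RelativeRiskCurve:
    """Dose–response RR(x) for one risk–outcome pair.

    ``reference`` is the exposure where RR = 1; for ``log_linear`` the curve
    is exp(beta·(x − reference)).  Tabulated curves interpolate log RR
    between knots with a monotone cubic and extrapolate flat.  The declared
    ``shape`` is verified against the curve at construction and a
    contradiction fails loudly.
    """

    risk: str
    cause: str
    form: str  # log_linear | tabulated_monotone | categorical
    shape: str
    beta: float | None = None
    reference: float = 0.0
    knots: tuple[float, ...] = ()
    values: tuple[float, ...] = ()
    category_rrs: Mapping[str, float] | None = None
    _interp: PchipInterpolator | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise RiskCurveError(f"unknown shape {self.shape!r}")
        if self.form == "log_linear":
            if self.beta is None:
                raise RiskCurveError("log_linear curve requires beta")
            if self.beta > 0 and self.shape != "monotone_increasing":
                raise ShapeError("beta > 0 contradicts declared shape")
            if self.beta < 0 and self.shape != "monotone_decreasing":
                raise ShapeError("beta < 0 contradicts declared shape")
        elif self.form == "tabulated_monotone":
            k = np.asarray(self.knots, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if k.size < 2 or k.size != v.size:
                raise RiskCurveError("tabulated curve needs matching knots/values")
            if np.any(np.diff(k) <= 0):
                raise RiskCurveError("knots must be strictly increasing")
            if np.any(v <= 0):
                raise RiskCurveError("RR values must be positive")
            self._verify_tabulated_shape(v)
            object.__setattr__(
                self, "_interp", PchipInterpolator(k, np.log(v), extrapolate=False))
        elif self.form == "categorical":
            if not self.category_rrs:
                raise RiskCurveError("categorical curve requires category_rrs")
            if any(r <= 0 for r in self.category_rrs.values()):
                raise RiskCurveError("RR values must be positive")
        else:
            raise RiskCurveError(f"unknown form {self.form!r}")
        rr_ref = self.rr(self.reference) if self.form != "categorical" else 1.0
        if abs(rr_ref - 1.0) > 1e-9:
            raise RiskCurveError(
                f"RR(reference={self.reference}) = {rr_ref}, expected 1")

    def _verify_tabulated_shape(self, v: np.ndarray) -> None:
        d = np.diff(v)
        if self.shape == "monotone_increasing":
            ok = np.all(d >= 0)
        elif self.shape == "monotone_decreasing":
            ok = np.all(d <= 0)
        else:  # inverted_V: falls to an interior nadir then rises
            imin = int(np.argmin(v))
            ok = (0 < imin < v.size - 1 and np.all(d[:imin] <= 0)
                  and np.all(d[imin:] >= 0))
        if not ok:
            raise ShapeError(
                f"values contradict declared shape {self.shape!r}")

    def rr(self, x) -> np.ndarray | float:
        """RR at exposure x (scalar or array); always positive."""
        xarr = np.asarray(x, dtype=float)
        if self.form == "log_linear":
            out = np.exp(self.beta * (xarr - self.reference))
        elif self.form == "tabulated_monotone":
            lo, hi = self.knots[0], self.knots[-1]
            clipped = np.clip(xarr, lo, hi)  # flat extrapolation
            out = np.exp(self._interp(clipped))
        else:
            raise RiskCurveError(
                "categorical curves are evaluated per category, not at x")
        return out if out.ndim else float(out)

    def rr_category(self, category: str) -> float:
        if self.form != "categorical":
            raise RiskCurveError("rr_category requires a categorical curve")
        try:
            return float(self.category_rrs[category])
        except KeyError:
            raise RiskCurveError(f"unknown category {category!r}") from None


def rr_at(curve: RelativeRiskCurve, x) -> np.ndarray | float:
    """Functional alias for ``curve.rr(x)``."""
    return curve.rr(x)


@dataclass(frozen=True)
class TMRELSpec:
    """Counterfactual exposure rule; ``value`` required for explicit_value."""

    rule: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in TMREL_RULES:
            raise RiskCurveError(f"unknown TMREL rule {self.rule!r}")
        if self.rule == "explicit_value" and self.value is None:
            raise RiskCurveError("explicit_value rule requires a value")


def resolve_tmrel(spec: TMRELSpec, curve: RelativeRiskCurve,
                  dist: ExposureDistribution | None = None) -> float:
    """Resolve a TMREL rule to a point exposure value.

    fixed_zero -> 0; explicit_value -> the given value; nadir -> argmin of
    RR over the exposure support on a 10,001-point grid (ties broken toward
    the lowest exposure); percentile_85 -> the 85th percentile of the
    stratum's exposure distribution (protective risks).
    """
    if spec.rule == "fixed_zero":
        return 0.0
    if spec.rule == "explicit_value":
        return float(spec.value)
    if spec.rule == "percentile_85":
        if dist is None:
            raise RiskCurveError(
                "percentile_85 rule requires an exposure distribution")
        return float(dist.quantile(0.85))
    # nadir
    if curve.shape != "inverted_V":
        raise ShapeError("nadir rule applies only to inverted_V curves")
    if dist is not None:
        lo, hi = dist.support
    elif curve.form == "tabulated_monotone":
        lo, hi = curve.knots[0], curve.knots[-1]
    else:
        raise RiskCurveError("nadir rule needs a support or a knot table")
    grid = np.linspace(lo, hi, _NADIR_GRID)
    rr = np.asarray(curve.rr(grid))
    return float(grid[int(np.argmin(rr))])  # argmin takes the first minimum


@dataclass(frozen=True)
class RiskOutcomePair:
    risk: str
    cause: str
    curve: RelativeRiskCurve
    tmrel: TMRELSpec

    def __post_init__(self) -> None:
        if (self.curve.risk, self.curve.cause) != (self.risk, self.cause):
            raise RiskCurveError("curve labelled for a different pair")


class RiskOutcomeRegistry:
    """One curve + TMREL rule per (risk, cause); duplicates are rejected.

    Registering a pair whose resolved RR(TMREL) is not the curve minimum
    over the checked range emits a warning rather than renormalising — the
    attributable-fraction formula subtracts RR at the TMREL as given.
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], RiskOutcomePair] = {}

    def add(self, pair: RiskOutcomePair,
            dist: ExposureDistribution | None = None) -> None:
        key = (pair.risk, pair.cause)
        if key in self._pairs:
            raise RiskCurveError(f"duplicate risk-outcome pair {key}")
        if pair.curve.form != "categorical" and pair.tmrel.rule != "percentile_85":
            try:
                t = resolve_tmrel(pair.tmrel, pair.curve, dist)
                if dist is not None and not dist.is_degenerate:
                    lo, hi = dist.support
                elif pair.curve.form == "tabulated_monotone":
                    lo, hi = pair.curve.knots[0], pair.curve.knots[-1]
                else:
                    lo = min(t, pair.curve.reference)
                    hi = max(t, pair.curve.reference) + 1e-9
                grid = np.linspace(lo, hi, 101)
                if pair.curve.rr(t) > np.min(pair.curve.rr(grid)) + 1e-9:
                    warnings.warn(
                        f"RR(TMREL) is not the curve minimum for {key}",
                        stacklevel=2)
            except (RiskCurveError, ExposureError):
                pass
        self._pairs[key] = pair

    def get(self, risk: str, cause: str) -> RiskOutcomePair:
        try:
            return self._pairs[(risk, cause)]
        except KeyError:
            raise RiskCurveError(
                f"no registered pair for ({risk!r}, {cause!r})") from None

    def pairs(self) -> list[RiskOutcomePair]:
        return list(self._pairs.values())

    def causes_of(self, risk: str) -> list[str]:
        return [c for (r, c) in self._pairs if r == risk]

    def risks(self) -> list[str]:
        return sorted({r for (r, _) in self._pairs})

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._pairs
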