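"""Stratum-level exposure distributions fitted from summary moments.

In the comparative-risk-assessment framework each population stratum
(location, year, sex, age group) carries a continuous exposure distribution
P(x) — e.g. body-mass index in kg/m² or fruit intake in g/day — summarised
upstream as a mean and standard deviation.  This module reconstructs a
parametric P(x) from those two moments (method of moments), truncates it to
a finite support [l, m] over which the attributable-fraction integral runs,
and exposes density, CDF, quantile, and sampling on the truncated law.

Families
--------
``normal``       moments are the parameters; truncated and renormalised.
``lognormal``    for strictly positive exposures; underlying (mu, sigma)
                 solved from mean/SD of the lognormal itself.
``gamma``        shape = (mean/sd)², scale = sd²/mean.
``point_mass``   degenerate atom (sd = 0); integrals reduce to evaluation.
``categorical``  discrete exposure levels with prevalences (optionally
                 mapped to numeric values so the continuous machinery can
                 treat it as a mixture of atoms).

Moments are matched *pre-truncation*: the fitted family has exactly the
requested mean/SD before the support clips it.  Truncation then renormalises
the density so it integrates to one on [l, m].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExposureError",
    "ExposureDistribution",
    "fit_mom",
    "default_support",
]


class ExposureError(ValueError):
    """Raised for infeasible moment fits or out-of-domain evaluation."""


_CONTINUOUS_FAMILIES = ("normal", "lognormal", "gamma")
_FAMILIES = _CONTINUOUS_FAMILIES + ("point_mass", "categorical")


def default_support(mean: float, sd: float, lower_bound: float = -np.inf,
                    upper_bound: float = np.inf) -> tuple[float, float]:
    """Default integration support: mean ± 6·sd clipped to the physical range.

    The attributable-fraction integral runs over a finite [l, m]; six
    standard deviations keep > 1 - 2e-9 of the mass of any of the supported
    families while bounding the integrand of exp-shaped risk curves.
    """
    if sd == 0:
        pad = max(abs(mean), 1.0) * 1e-6
        lo, hi = mean - pad, mean + pad
    else:
        lo, hi = mean - 6.0 * sd, mean + 6.0 * sd
    lo = max(lo, lower_bound)
    hi = min(hi, upper_bound)
    if not lo < hi:
        raise ExposureError(f"degenerate support [{lo}, {hi}]")
    return (lo, hi)


@dataclass(frozen=True)
class ExposureDistribution:
    """A (possibly truncated) exposure distribution P(x) for one stratum.

    Parameters
    ----------
    family
        One of ``normal``, ``lognormal``, ``gamma``, ``point_mass``,
        ``categorical``.
    mean, sd
        The pre-truncation moments the family was fitted to (exposure units).
    support
        Closed interval [l, m]; the density is renormalised to integrate to
        one over it.
    params
        Family-native parameters (e.g. ``{"mu": ..., "sigma": ...}`` for the
        lognormal's underlying normal).
    categories, prevalences, category_values
        For the categorical family only: labels, their population shares
        (sum to 1), and optional numeric exposure values per category.
    """

    family: str
    mean: float
    sd: float
    support: tuple[float, float]
    params: dict = field(default_factory=dict)
    categories: tuple[str, ...] = ()
    prevalences: tuple[float, ...] = ()
    category_values: tuple[float, ...] = ()
    risk: str | None = None
    stratum: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ExposureError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ExposureError("sd must be non-negative")
        if self.family == "categorical":
            total = float(np.sum(self.prevalences))
            if abs(total - 1.0) > 1e-9:
                raise ExposureError(
                    f"categorical prevalences sum to {total}, expected 1")
            if len(self.categories) != len(self.prevalences):
                raise ExposureError("categories/prevalences length mismatch")

    # -- internals ---------------------------------------------------------

    def _frozen(self):
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p["mu"], scale=p["sigma"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=p["scale"])
        raise ExposureError(f"{self.family} has no continuous form")

    def _trunc_mass(self) -> float:
        d = self._frozen()
        l, m = self.support
        mass = d.cdf(m) - d.cdf(l)
        if mass <= 0:
            raise ExposureError(
                f"support [{l}, {m}] carries no mass for {self.family}")
        return float(mass)

    # -- public surface ----------------------------------------------------

    @property
    def is_degenerate(self) -> bool:
        return self.family == "point_mass"

    @property
    def atom(self) -> float:
        if self.family != "point_mass":
            raise ExposureError("atom defined only for point_mass")
        return self.mean

    def density(self, x) -> np.ndarray | float:
        """Truncated density at x; raises outside the support.

        For ``point_mass`` the density is a Dirac atom and has no finite
        pointwise value; integrals against it are handled analytically by
        callers (``quadrature of g(x)·P(x)`` returns ``g(atom)``).
        """
        l, m = self.support
        xarr = np.asarray(x, dtype=float)
        if np.any(xarr < l) or np.any(xarr > m):
            raise ExposureError(f"x outside support [{l}, {m}]")
        if self.family == "point_mass":
            raise ExposureError(
                "point_mass has no pointwise density; use the atom directly")
        if self.family == "categorical":
            raise ExposureError(
                "categorical exposure has probability masses, not a density")
        out = self._frozen().pdf(xarr) / self._trunc_mass()
        return out if out.ndim else float(out)

    def cdf(self, x) -> np.ndarray | float:
        l, m = self.support
        if self.family == "point_mass":
            return np.where(np.asarray(x, dtype=float) >= self.atom, 1.0, 0.0)
        d = self._frozen()
        lo = d.cdf(l)
        out = np.clip((d.cdf(x) - lo) / self._trunc_mass(), 0.0, 1.0)
        return out if np.ndim(out) else float(out)

    def quantile(self, q) -> np.ndarray | float:
        """Inverse CDF of the truncated distribution; q must lie in (0, 1)."""
        qarr = np.asarray(q, dtype=float)
        if np.any(qarr <= 0.0) or np.any(qarr >= 1.0):
            raise ExposureError("quantile level must lie strictly in (0, 1)")
        if self.family == "point_mass":
            out = np.full_like(qarr, self.atom, dtype=float)
            return out if out.ndim else float(out)
        if self.family == "categorical":
            raise ExposureError("quantile undefined for categorical exposure")
        d = self._frozen()
        l, m = self.support
        lo = d.cdf(l)
        out = d.ppf(lo + qarr * self._trunc_mass())
        out = np.clip(out, l, m)
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n samples from the truncated distribution (inverse-CDF)."""
        if self.family == "point_mass":
            return np.full(n, self.atom)
        if self.family == "categorical":
            vals = self.category_values or tuple(range(len(self.categories)))
            idx = rng.choice(len(vals), size=n, p=np.asarray(self.prevalences))
            return np.asarray(vals, dtype=float)[idx]
        u = rng.uniform(0.0, 1.0, size=n)
        d = self._frozen()
        l, m = self.support
        lo = d.cdf(l)
        return np.clip(d.ppf(lo + u * self._trunc_mass()), l, m)

    def analytic_moments(self) -> tuple[float, float]:
        """Pre-truncation (mean, sd) of the fitted family."""
        if self.family == "point_mass":
            return (self.mean, 0.0)
        if self.family == "categorical":
            vals = np.asarray(self.category_values, dtype=float)
            p = np.asarray(self.prevalences)
            mu = float(vals @ p)
            return (mu, float(np.sqrt(((vals - mu) ** 2) @ p)))
        d = self._frozen()
        return (float(d.mean()), float(d.std()))


def mom_params(mean, sd, family: str) -> dict[str, np.ndarray]:
    """Vectorised method-of-moments parameters for a continuous family.

    Accepts scalar or array mean/sd; used by the draw-level PAF path where
    each uncertainty draw shifts the stratum mean.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if family == "normal":
        return {"mu": mean, "sigma": np.broadcast_to(sd, mean.shape).copy()}
    if family == "lognormal":
        if np.any(mean <= 0):
            raise ExposureError("lognormal requires mean > 0")
        sigma2 = np.log1p((sd / mean) ** 2)
        return {"mu": np.log(mean) - sigma2 / 2.0, "sigma": np.sqrt(sigma2)}
    if family == "gamma":
        if np.any(mean <= 0):
            raise ExposureError("gamma requires mean > 0")
        return {"shape": (mean / sd) ** 2, "scale": sd ** 2 / mean}
    raise ExposureError(f"mom_params does not handle family {family!r}")


def fit_mom(mean: float, sd: float, family: str,
            support: tuple[float, float] | None = None,
            lower_bound: float | None = None) -> ExposureDistribution:
    """Fit an exposure distribution to (mean, sd) by the method of moments.

    ``sd = 0`` collapses to a point mass regardless of the requested family.
    The fitted family reproduces (mean, sd) exactly before truncation;
    truncation to ``support`` only renormalises the density.

    Parameters
    ----------
    lower_bound
        Physical floor for the default support (0 for lognormal/gamma).
    """
    if sd < 0:
        raise ExposureError("sd must be non-negative")
    if family not in _CONTINUOUS_FAMILIES + ("point_mass",):
        raise ExposureError(f"fit_mom does not handle family {family!r}")

    if sd == 0 or family == "point_mass":
        if support is None:
            support = default_support(mean, 0.0)
        if not support[0] <= mean <= support[1]:
            raise ExposureError(f"mean {mean} outside support {support}")
        return ExposureDistribution("point_mass", mean, 0.0, support)

    params = {k: float(v) for k, v in mom_params(mean, sd, family).items()}
    if family == "normal":
        floor = -np.inf if lower_bound is None else lower_bound
    else:  # lognormal / gamma live on the positive half-line
        floor = 0.0 if lower_bound is None else max(lower_bound, 0.0)

    if support is None:
        support = default_support(mean, sd, lower_bound=floor)
    if not support[0] <= mean <= support[1]:
        raise ExposureError(f"mean {mean} outside support {support}")
    return ExposureDistribution(family, float(mean), float(sd),
                                (float(support[0]), float(support[1])), params)


def categorical_exposure(categories: Sequence[str],
                         prevalences: Sequence[float],
                         values: Sequence[float] | None = None,
                         risk: str | None = None,
                         stratum: tuple | None = None) -> ExposureDistribution:
    """Build a categorical exposure (e.g. never/current smoker prevalences)."""
    prev = tuple(float(p) for p in prevalences)
    vals = tuple(float(v) for v in values) if values is not None else \
        tuple(float(i) for i in range(len(categories)))
    mean = float(np.dot(vals, prev))
    sd = float(np.sqrt(np.dot((np.asarray(vals) - mean) ** 2, prev)))
    return ExposureDistribution(
        "categorical", mean, sd, (min(vals), max(vals)),
        categories=tuple(categories), prevalences=prev,
        category_values=vals, risk=risk, stratum=stratum)
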