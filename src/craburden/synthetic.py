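"""Self-contained synthetic "GBD-like" world with known ground-truth PAFs.

Downstream stages (exposure fitting, PAF quadrature, attributable burden,
trends, SDI gradients) are tested against data whose generating process is
fully known.  The generator emits the same tables a results-tool extract
would provide — stratified exposure means/SDs or category prevalences,
per-cause total DALYs with uncertainty draws, and a sociodemographic index
per location-year — plus a :class:`GroundTruth` holding the PAF implied by
the generating parameters for every (risk, cause, stratum) cell, computed
by the generator's own dense trapezoid quadrature (or closed form for
discrete exposures), independently of the PAF engine under test.

The default world is desk-scale: 10 locations × 2 years × 8 age bands ×
2 sexes, three risks with distinct mechanics (a BMI-like harmful continuous
exposure, a smoking-like categorical exposure, and a fruit-intake-like
protective exposure whose TMREL is the 85th exposure percentile), and three
cancer causes.  Exposures follow an SDI gradient with configurable sign and
strength through a Gaussian copula on location-level development.

Draw-level noise: exposure means (and category prevalences, on the logit
scale) and total DALYs are perturbed multiplicatively with small lognormal
noise so every table carries 95% uncertainty intervals; all noise flows
from one seeded generator, so a fixed seed reproduces the world exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposures import ExposureDistribution, categorical_exposure, fit_mom
from .risks import (RelativeRiskCurve, RiskOutcomePair, RiskOutcomeRegistry,
                    TMRELSpec, resolve_tmrel)
from .sdi import assign_quintiles, compute_sdi

__all__ = [
    "WorldError",
    "RiskSpec",
    "WorldConfig",
    "GroundTruth",
    "SyntheticWorld",
    "default_risk_specs",
    "default_config",
    "build_registry",
    "generate_world",
    "ground_truth_paf",
]

_TRAPZ_POINTS = 20_001  # generator-side quadrature resolution

DEFAULT_AGE_GROUPS = ("40-44", "45-49", "50-54", "55-59",
                      "60-64", "65-69", "70-74", "75-79")
DEFAULT_CAUSES = ("lung_cancer", "colorectal_cancer", "breast_cancer")
SEXES = ("Male", "Female")


class WorldError(ValueError):
    pass


@dataclass(frozen=True)
class RiskSpec:
    """Generating mechanics for one synthetic risk factor.

    ``sdi_rho`` sets the Gaussian-copula correlation between a location's
    development score and its exposure level (sign gives the direction of
    the gradient).  For continuous risks ``base_mean``/``sd_frac`` define
    the stratum exposure distribution; for categorical risks ``base_logit``
    sets the exposed prevalence.  ``cause_betas`` (log RR per unit) or
    ``cause_rrs`` (per-category RR) define one curve per affected cause.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    family: str = "lognormal"
    base_mean: float = 0.0
    sd_frac: float = 0.15
    base_logit: float = 0.0
    sdi_rho: float = 0.8
    sdi_slope: float = 1.0
    sex_shift: Mapping[str, float] = field(default_factory=dict)
    age_slope: float = 0.0
    cause_betas: Mapping[str, float] = field(default_factory=dict)
    cause_rrs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    tmrel_rule: str = "fixed_zero"
    tmrel_value: float | None = None
    tmrel_category: str = "unexposed"
    categories: tuple[str, ...] = ("unexposed", "exposed")
    shape: str = "monotone_increasing"
    reference: float = 0.0

    @property
    def causes(self) -> tuple[str, ...]:
        src = self.cause_betas if self.kind == "continuous" else self.cause_rrs
        return tuple(src.keys())


def default_risk_specs() -> tuple[RiskSpec, ...]:
    """Three mechanically distinct risks mirroring common level-2 factors."""
    bmi = RiskSpec(
        name="high_bmi_like", kind="continuous", family="lognormal",
        base_mean=26.0, sd_frac=0.15, sdi_rho=0.7, sdi_slope=2.5,
        sex_shift={"Male": 0.4, "Female": -0.4}, age_slope=0.15,
        cause_betas={"colorectal_cancer": np.log(1.10) / 5.0,
                     "breast_cancer": np.log(1.12) / 5.0},
        tmrel_rule="explicit_value", tmrel_value=21.0, reference=21.0,
        shape="monotone_increasing")
    tobacco = RiskSpec(
        name="smoking_like", kind="categorical",
        base_logit=-1.1, sdi_rho=0.8, sdi_slope=0.9,
        sex_shift={"Male": 0.5, "Female": -0.5},
        cause_rrs={"lung_cancer": {"unexposed": 1.0, "exposed": 15.0},
                   "colorectal_cancer": {"unexposed": 1.0, "exposed": 1.4}},
        tmrel_rule="fixed_zero", tmrel_category="unexposed",
        categories=("unexposed", "exposed"), shape="monotone_increasing")
    fruit = RiskSpec(
        name="fruit_intake_like", kind="continuous", family="gamma",
        base_mean=180.0, sd_frac=0.35, sdi_rho=0.6, sdi_slope=60.0,
        sex_shift={"Male": -10.0, "Female": 10.0},
        cause_betas={"colorectal_cancer": -np.log(1.05) / 100.0},
        tmrel_rule="percentile_85", reference=0.0,
        shape="monotone_decreasing")
    return (bmi, tobacco, fruit)


@dataclass(frozen=True)
class WorldConfig:
    """Dimensions and noise levels of the synthetic world."""

    n_locations: int = 10
    years: tuple[int, ...] = (1990, 2019)
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    sexes: tuple[str, ...] = SEXES
    risks: tuple[RiskSpec, ...] = ()
    causes: tuple[str, ...] = DEFAULT_CAUSES
    draws: int = 1000
    seed: int = 17
    exposure_draw_cv: float = 0.02
    prevalence_logit_sd: float = 0.05
    burden_draw_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise WorldError("n_locations must be at least 1")
        if self.draws < 1:
            raise WorldError("draws must be at least 1")
        if not self.years or not self.age_groups or not self.causes:
            raise WorldError("years, age_groups and causes must be non-empty")
        starts = [int(a.split("-")[0].rstrip("+")) for a in self.age_groups]
        if sorted(starts) != starts or len(set(starts)) != len(starts):
            raise WorldError("age bands must be ordered and non-overlapping")

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(f"loc_{i:02d}" for i in range(1, self.n_locations + 1))


def default_config(seed: int = 17, draws: int = 1000, **kw) -> WorldConfig:
    return WorldConfig(risks=default_risk_specs(), seed=seed, draws=draws,
                       **kw)


@dataclass
class GroundTruth:
    """Generator-side truth for every stratum the world emits."""

    true_paf: dict[tuple, float]
    true_exposure_params: dict[tuple, dict]
    true_sdi: dict[tuple[str, int], float]

    def paf(self, risk: str, cause: str, stratum: tuple) -> float:
        key = (risk, cause) + tuple(stratum)
        try:
            return self.true_paf[key]
        except KeyError:
            raise WorldError(f"unknown stratum {key}") from None


def ground_truth_paf(risk: str, cause: str, stratum: tuple,
                     truth: GroundTruth) -> float:
    return truth.paf(risk, cause, stratum)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    exposures: pd.DataFrame
    burden: pd.DataFrame
    sdi: pd.DataFrame
    truth: GroundTruth
    registry: RiskOutcomeRegistry


# -- generator-side PAF (independent quadrature) ---------------------------

def _truth_paf_continuous(dist: ExposureDistribution,
                          curve: RelativeRiskCurve, tmrel: float) -> float:
    """Dense-trapezoid PAF, the generator's own quadrature."""
    if dist.family == "point_mass":
        mean_rr = float(curve.rr(dist.atom))
    else:
        l, m = dist.support
        grid = np.linspace(l, m, _TRAPZ_POINTS)
        mean_rr = float(np.trapezoid(
            np.asarray(curve.rr(grid)) * dist.density(grid), grid))
    rr_t = float(curve.rr(tmrel))
    return (mean_rr - rr_t) / mean_rr


def _truth_paf_categorical(prevalences: Sequence[float],
                           rrs: Sequence[float], tmrel_idx: int) -> float:
    p = np.asarray(prevalences, dtype=float)
    r = np.asarray(rrs, dtype=float)
    mean_rr = float(p @ r)
    return (mean_rr - float(r[tmrel_idx])) / mean_rr


# -- registry --------------------------------------------------------------

def build_registry(risks: Sequence[RiskSpec]) -> RiskOutcomeRegistry:
    """Risk–outcome registry (curves + TMREL rules) for the given specs."""
    reg = RiskOutcomeRegistry()
    for spec in risks:
        if spec.kind == "continuous":
            for cause, beta in spec.cause_betas.items():
                curve = RelativeRiskCurve(
                    risk=spec.name, cause=cause, form="log_linear",
                    shape=spec.shape, beta=float(beta),
                    reference=spec.reference)
                reg.add(RiskOutcomePair(
                    spec.name, cause, curve,
                    TMRELSpec(spec.tmrel_rule, spec.tmrel_value)))
        elif spec.kind == "categorical":
            for cause, rrs in spec.cause_rrs.items():
                curve = RelativeRiskCurve(
                    risk=spec.name, cause=cause, form="categorical",
                    shape=spec.shape, category_rrs=dict(rrs))
                reg.add(RiskOutcomePair(
                    spec.name, cause, curve,
                    TMRELSpec("explicit_value", 0.0)))
        else:
            raise WorldError(f"unknown risk kind {spec.kind!r}")
    return reg


# -- world generation ------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate exposure, burden and SDI tables plus ground truth.

    Deterministic under a fixed seed: identical configs produce identical
    tables byte-for-byte when serialised.
    """
    if not config.risks:
        raise WorldError("config lists no risks")
    for spec in config.risks:
        for cause in spec.causes:
            if cause not in config.causes:
                raise WorldError(
                    f"risk {spec.name} targets unknown cause {cause!r}")

    rng = np.random.default_rng(config.seed)
    locs = config.locations
    n_loc = len(locs)
    registry = build_registry(config.risks)

    # --- SDI: location-level development scores with a mild secular trend
    z_dev = np.sort(rng.normal(size=n_loc))  # ordered so loc index ~ development
    sdi_rows = []
    true_sdi: dict[tuple[str, int], float] = {}
    year_span = max(config.years) - min(config.years) or 1
    for li, loc in enumerate(locs):
        comp_noise = rng.normal(scale=0.04, size=3)
        for year in config.years:
            t = (year - min(config.years)) / year_span
            level = _sigmoid(0.8 * z_dev[li] + 0.35 * t - 0.1)
            comps = np.clip(level + comp_noise, 0.02, 0.98)
            sdi_val = compute_sdi(*comps)
            sdi_rows.append({"location": loc, "year": year,
                             "tfu25": comps[0], "edu15": comps[1],
                             "ldi": comps[2], "sdi": sdi_val})
            true_sdi[(loc, year)] = sdi_val
    sdi_df = pd.DataFrame(sdi_rows)
    ref_year = max(config.years)
    ref = sdi_df[sdi_df["year"] == ref_year].set_index("location")["sdi"]
    if n_loc >= 5:
        quintiles = assign_quintiles(ref.to_dict())
        sdi_df["quintile"] = sdi_df["location"].map(quintiles)
    else:
        sdi_df["quintile"] = None

    # --- populations and total DALYs per cause-stratum
    age_idx = {a: i for i, a in enumerate(config.age_groups)}
    pop_rows, burden_rows = [], []
    base_rate = {c: 120.0 * (1.3 ** i)
                 for i, c in enumerate(config.causes)}  # per 100k, age 40-44
    for loc in locs:
        loc_scale = float(np.exp(rng.normal(np.log(2e5), 0.4)))
        for year in config.years:
            growth = 1.0 + 0.3 * (year - min(config.years)) / year_span
            for sex in config.sexes:
                for age in config.age_groups:
                    pop = loc_scale * growth * (0.95 ** age_idx[age]) * 0.5
                    pop_rows.append((loc, year, sex, age, pop))
                    for cause in config.causes:
                        sex_f = 0.25 if (cause == "breast_cancer"
                                         and sex == "Male") else 1.0
                        rate = (base_rate[cause] * (1.35 ** age_idx[age])
                                * sex_f * float(np.exp(rng.normal(0, 0.15))))
                        value = rate * pop / 1e5  # DALY person-years
                        burden_rows.append({
                            "measure": "DALYs", "metric": "Number",
                            "cause": cause, "location": loc, "year": year,
                            "sex": sex, "age_group": age,
                            "value": value, "population": pop})
    burden_df = pd.DataFrame(burden_rows)

    # burden draws: multiplicative lognormal, mean-preserving
    cv = config.burden_draw_cv
    sig_b = np.sqrt(np.log1p(cv * cv))
    noise = np.exp(rng.normal(-0.5 * sig_b ** 2, sig_b,
                              size=(len(burden_df), config.draws)))
    bdraws = burden_df["value"].to_numpy()[:, None] * noise
    burden_df = pd.concat(
        [burden_df,
         pd.DataFrame(bdraws, columns=[f"draw_{d}"
                                       for d in range(config.draws)])],
        axis=1)

    # --- exposures, with SDI-correlated location drivers per risk
    z_rank = (np.argsort(np.argsort(z_dev)) + 0.5) / n_loc
    z_sdi = _norm_ppf(z_rank)  # normal scores of development rank
    exp_rows = []
    truth_paf: dict[tuple, float] = {}
    truth_params: dict[tuple, dict] = {}
    cv_e = config.exposure_draw_cv
    sig_e = np.sqrt(np.log1p(cv_e * cv_e))

    for spec in config.risks:
        rho = float(np.clip(spec.sdi_rho, -0.999, 0.999))
        eps = rng.normal(size=n_loc)
        driver = rho * z_sdi + np.sqrt(1.0 - rho * rho) * eps
        for li, loc in enumerate(locs):
            for year in config.years:
                t = (year - min(config.years)) / year_span
                for sex in config.sexes:
                    for age in config.age_groups:
                        stratum = (loc, year, sex, age)
                        key = (spec.name,) + stratum
                        shift = spec.sex_shift.get(sex, 0.0)
                        if spec.kind == "continuous":
                            mean = (spec.base_mean
                                    + spec.sdi_slope * driver[li]
                                    + shift + spec.age_slope * age_idx[age]
                                    + 0.3 * spec.sdi_slope * t)
                            mean = max(mean, 0.05 * spec.base_mean)
                            sd = spec.sd_frac * mean
                            dist = fit_mom(mean, sd, spec.family)
                            truth_params[key] = {
                                "family": spec.family, "mean": mean,
                                "sd": sd, "support": dist.support}
                            mdraws = mean * np.exp(rng.normal(
                                -0.5 * sig_e ** 2, sig_e, size=config.draws))
                            row = {"risk": spec.name, "location": loc,
                                   "year": year, "sex": sex,
                                   "age_group": age, "metric": "mean",
                                   "category": "", "val": mean}
                            row.update({f"draw_{d}": mdraws[d]
                                        for d in range(config.draws)})
                            exp_rows.append(row)
                            sd_row = {"risk": spec.name, "location": loc,
                                      "year": year, "sex": sex,
                                      "age_group": age, "metric": "sd",
                                      "category": "", "val": sd}
                            sd_row.update({f"draw_{d}": sd
                                           for d in range(config.draws)})
                            exp_rows.append(sd_row)
                            for cause in spec.causes:
                                pair = registry.get(spec.name, cause)
                                tm = resolve_tmrel(pair.tmrel, pair.curve,
                                                   dist)
                                truth_paf[(spec.name, cause) + stratum] = \
                                    _truth_paf_continuous(dist, pair.curve, tm)
                        else:
                            logit = (spec.base_logit
                                     + spec.sdi_slope * driver[li]
                                     + shift + 0.2 * spec.sdi_slope * t)
                            prev = float(_sigmoid(logit))
                            truth_params[key] = {"family": "categorical",
                                                 "prevalence": prev}
                            pdraws = _sigmoid(logit + rng.normal(
                                0.0, config.prevalence_logit_sd,
                                size=config.draws))
                            row = {"risk": spec.name, "location": loc,
                                   "year": year, "sex": sex,
                                   "age_group": age, "metric": "prevalence",
                                   "category": spec.categories[1],
                                   "val": prev}
                            row.update({f"draw_{d}": pdraws[d]
                                        for d in range(config.draws)})
                            exp_rows.append(row)
                            for cause in spec.causes:
                                rrs = [spec.cause_rrs[cause][c]
                                       for c in spec.categories]
                                truth_paf[(spec.name, cause) + stratum] = \
                                    _truth_paf_categorical(
                                        [1.0 - prev, prev], rrs, 0)
    exposures_df = pd.DataFrame(exp_rows)

    truth = GroundTruth(truth_paf, truth_params, true_sdi)
    return SyntheticWorld(config, exposures_df, burden_df, sdi_df, truth,
                          registry)


def _norm_ppf(q):
    from scipy.stats import norm
    return norm.ppf(np.asarray(q, dtype=float))
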