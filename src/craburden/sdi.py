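"""Sociodemographic index (SDI) construction and PAF–SDI analysis.

The SDI composites three indices each scaled to [0, 1] — total fertility
under age 25 (inverted so higher is better), mean years of education at
15+, and lag-distributed income per capita — as their geometric mean,
multiplied by 100 to run from 0 (least developed) to 100 (most developed).
Locations are split into five equal-count quintiles on a reference year's
SDI.  The association between a risk factor's PAF and development is
summarised by a Spearman rank correlation and by a loess-style local linear
smooth giving the expected PAF at each SDI unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "SDIError",
    "SDIRecord",
    "QUINTILE_LABELS",
    "compute_sdi",
    "assign_quintiles",
    "spearman_paf_sdi",
    "expected_paf_curve",
]

QUINTILE_LABELS = ("low", "low-middle", "middle", "high-middle", "high")

_EXACT_PERM_MAX_N = 10
_LOESS_SPAN = 0.5


class SDIError(ValueError):
    pass


@dataclass(frozen=True)
class SDIRecord:
    """One location-year's SDI components, composite, and quintile."""

    location: str
    year: int
    tfu25: float
    edu15: float
    ldi: float
    sdi: float
    quintile: str | None = None


def compute_sdi(tfu25: float, edu15: float, ldi: float) -> float:
    """100 × geometric mean of the three component indices (each in [0, 1])."""
    comps = np.asarray([tfu25, edu15, ldi], dtype=float)
    if np.any(comps < 0) or np.any(comps > 1):
        raise SDIError(f"components must lie in [0, 1], got {comps.tolist()}")
    return float(100.0 * comps.prod() ** (1.0 / 3.0))


def assign_quintiles(sdi_by_location: dict[str, float]) -> dict[str, str]:
    """Equal-count quintile labels by SDI rank, low to high.

    Ranks are by ascending SDI with ties broken by location identifier
    order, so the assignment is deterministic.  Quintile boundaries fall at
    ranks round(i·n/5), e.g. 41/82/122/163 for 204 locations.
    """
    n = len(sdi_by_location)
    if n < 5:
        raise SDIError(f"need at least 5 locations for quintiles, got {n}")
    order = sorted(sdi_by_location, key=lambda k: (sdi_by_location[k], k))
    bounds = [int(np.floor(i * n / 5 + 0.5)) for i in range(1, 5)]
    labels: dict[str, str] = {}
    for rank, loc in enumerate(order, start=1):
        q = sum(rank > b for b in bounds)
        labels[loc] = QUINTILE_LABELS[q]
    return labels


def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return np.nan
    return float((rx @ ry) / denom)


def _perm_tally(chunk, ryc, sx, obs, count, total):
    arr = np.asarray(chunk, dtype=float)
    arr = arr - arr.mean(axis=1, keepdims=True)
    r = (arr @ ryc) / sx
    return count + int(np.count_nonzero(np.abs(r) >= obs)), total + len(chunk)


def spearman_paf_sdi(paf, sdi) -> tuple[float, float]:
    """Spearman rank correlation between per-location PAFs and SDI.

    Returns (rho, p).  For n ≤ 10 the two-sided p-value is exact, from full
    enumeration of rank permutations; above that, the large-sample t
    approximation is used.  Ties take average ranks.
    """
    x = np.asarray(paf, dtype=float)
    y = np.asarray(sdi, dtype=float)
    if x.shape != y.shape:
        raise SDIError("paf and sdi series must pair one-to-one")
    n = x.size
    if n < 4:
        raise SDIError("need at least 4 paired observations")

    rho = _rank_pearson(x, y)
    if n <= _EXACT_PERM_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        ryc = ry - ry.mean()
        obs = abs(rho) - 1e-12
        count = 0
        total = 0
        sx = np.sqrt(((rx - rx.mean()) ** 2).sum() * (ryc @ ryc))
        chunk: list[tuple[float, ...]] = []
        for perm in permutations(rx):
            chunk.append(perm)
            if len(chunk) == 100_000:
                count, total = _perm_tally(chunk, ryc, sx, obs, count, total)
                chunk = []
        if chunk:
            count, total = _perm_tally(chunk, ryc, sx, obs, count, total)
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(min(p, 1.0))


def expected_paf_curve(paf, sdi,
                       grid: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Loess-style expected PAF at each SDI unit.

    Local linear regression (lowess, span 0.5) evaluated on a unit-step SDI
    grid spanning the observed range.  Returns (grid, expected_paf).
    Linear signals are reproduced exactly; the smooth stays within the
    observed PAF range on constant data.
    """
    x = np.asarray(sdi, dtype=float)
    y = np.asarray(paf, dtype=float)
    if x.shape != y.shape:
        raise SDIError("paf and sdi series must pair one-to-one")
    if x.size < 10:
        raise SDIError("need at least 10 observations for the smooth")
    if grid is None:
        grid = np.arange(np.ceil(x.min()), np.floor(x.max()) + 1.0)
    grid = np.asarray(grid, dtype=float)
    smoothed = lowess(y, x, frac=_LOESS_SPAN, xvals=grid, return_sorted=False)
    return grid, np.asarray(smoothed, dtype=float)
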