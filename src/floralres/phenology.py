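"""Season-integral metrics for flower cover, flower density and visitation.

An indeterminate flowering crop is scored repeatedly between first open
flower and harvest: percent flower ground cover, open-flower density
(flowers ha⁻¹) and pollinator counts per observer-minute in six insect
categories.  The season-level metrics are areas under these curves over the
observed anthesis window:

* flower coverage time ``%t`` — integral of percent cover (percent·days),
* pollinator visitation time ``pvt`` — integral of the total visitation
  rate (insect·min⁻¹·observer⁻¹·days),
* visitation intensity ``pvt / %t`` — insects per unit of flower area-time,
* ``∑f ha⁻¹`` — cumulative flowers produced per hectare over the season.

All integrals use the trapezoid rule on the observed grid only; nothing is
extrapolated beyond the first or last observation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "INSECT_CATEGORIES",
    "SeasonSeries",
    "SeasonSummary",
    "integrate_series",
    "visitation_rate",
    "season_flower_sum",
    "visitation_intensity",
    "relative_percent",
    "honeybee_fraction",
    "season_summary",
    "mean_series",
]

#: insect categories scored during timed walks, in reporting order
INSECT_CATEGORIES = ("honey_bee", "bumble_bee", "other_bee", "fly", "butterfly", "other")

PLANTING_ORDER = ("early", "mid", "late")


@dataclass(frozen=True)
class SeasonSeries:
    """Time-indexed cover / density / visitation curves for one treatment."""

    days: np.ndarray  #: day-of-year grid, strictly increasing
    cover: np.ndarray  #: percent flower ground cover per sampled day
    flower_density: np.ndarray  #: open flowers per hectare per sampled day
    visitation: pd.DataFrame  #: rate per category (insects min⁻¹ observer⁻¹), rows = days
    treatment: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        cover = np.asarray(self.cover, dtype=float)
        dens = np.asarray(self.flower_density, dtype=float)
        if days.ndim != 1 or np.any(np.diff(days) <= 0):
            raise InputError("days must be 1-d and strictly increasing")
        if not (cover.shape == days.shape == dens.shape):
            raise InputError("cover and flower_density must match the day grid")
        if np.any((cover < 0) | (cover > 100)):
            raise InputError("cover must lie in [0, 100] percent")
        if np.any(dens < 0):
            raise InputError("flower density must be non-negative")
        vis = self.visitation
        if list(vis.columns) != list(INSECT_CATEGORIES) or len(vis) != days.size:
            raise InputError("visitation must have one row per day and the six standard categories")
        if (vis.to_numpy() < 0).any():
            raise InputError("visitation rates must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "cover", cover)
        object.__setattr__(self, "flower_density", dens)

    @property
    def total_visitation(self) -> np.ndarray:
        """Total visitation rate (all categories summed) per sampled day."""
        return self.visitation.to_numpy().sum(axis=1)


@dataclass(frozen=True)
class SeasonSummary:
    """Season roll-up for one year × planting time."""

    coverage_time: float  #: %t, percent·days
    pvt: float  #: visitation-rate·days
    intensity: float  #: pvt / %t
    flower_sum: float  #: flowers ha⁻¹ season⁻¹
    honeybee_fraction: float  #: season-aggregate honey-bee share of visits
    treatment: str = ""
    year: int = 0


def integrate_series(days, values) -> float:
    """Trapezoidal area under ``values`` over the observed ``days`` window."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.ndim != 1 or days.size < 2:
        raise InputError("need at least two samples to integrate")
    if days.shape != values.shape:
        raise InputError("days and values must have equal length")
    if np.any(np.diff(days) <= 0):
        raise InputError("days must be strictly increasing (no duplicates)")
    return float(np.trapezoid(values, days))


def visitation_rate(counts, observers: int, minutes: float) -> pd.Series:
    """Per-category counts normalised to insects per minute per observer."""
    if observers < 1:
        raise InputError("observers must be at least 1")
    if minutes <= 0:
        raise InputError("minutes must be positive")
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise InputError("counts must be non-negative")
    return s / (observers * minutes)


def season_flower_sum(days, flower_density) -> float:
    """Cumulative flowers ha⁻¹ over the season: AUC of the density curve."""
    return integrate_series(days, flower_density)


def visitation_intensity(pvt: float, coverage_time: float) -> float:
    """Insects per unit flower area-time: ``pvt / %t``.

    Undefined at zero coverage time (no flowers to visit); reported to two
    decimals in summary tables.
    """
    if coverage_time <= 0:
        raise InputError("visitation intensity undefined for non-positive coverage time")
    return float(pvt) / float(coverage_time)


def relative_percent(value_a: float, value_b: float) -> float:
    """``100 * a / b``; summary tables round it to whole percent."""
    if value_b <= 0:
        raise InputError("relative percent undefined for non-positive reference value")
    return 100.0 * float(value_a) / float(value_b)


def honeybee_fraction(visitation: pd.DataFrame, days=None) -> tuple[np.ndarray, float]:
    """Honey-bee share of visits per observation and for the whole season.

    Per observation: honey-bee rate over total rate, NaN when no insects at
    all were seen (such days drop out of the aggregate on their own — they
    add zero to both integrals).  Season aggregate: ratio of the day-grid
    integrals of the honey-bee and total rates when ``days`` is given,
    otherwise the ratio of plain sums.
    """
    hb = visitation["honey_bee"].to_numpy(dtype=float)
    total = visitation.to_numpy(dtype=float).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_obs = np.where(total > 0, hb / total, np.nan)
    if days is not None:
        total_int = integrate_series(days, total)
        agg = integrate_series(days, hb) / total_int if total_int > 0 else float("nan")
    else:
        agg = hb.sum() / total.sum() if total.sum() > 0 else float("nan")
    return per_obs, float(agg)


def season_summary(series: SeasonSeries) -> SeasonSummary:
    """Roll one treatment's curves up into the season-integral metrics."""
    ct = integrate_series(series.days, series.cover)
    pvt = integrate_series(series.days, series.total_visitation)
    intensity = visitation_intensity(pvt, ct) if ct > 0 else float("nan")
    fsum = season_flower_sum(series.days, series.flower_density)
    _, hb = honeybee_fraction(series.visitation, days=series.days)
    return SeasonSummary(coverage_time=ct, pvt=pvt, intensity=intensity,
                         flower_sum=fsum, honeybee_fraction=hb,
                         treatment=series.treatment, year=series.year)


def mean_series(series_list: list[SeasonSeries]) -> SeasonSeries:
    """Average replicate plots onto their (shared) date grid.

    Replicates must have identical day grids; curves are averaged pointwise
    before integration, mirroring how treatment-mean curves are plotted.
    By linearity of the trapezoid rule this commutes with integration.
    """
    if not series_list:
        raise InputError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.days, first.days):
            raise InputError("replicate series must share a common date grid")
    cover = np.mean([s.cover for s in series_list], axis=0)
    dens = np.mean([s.flower_density for s in series_list], axis=0)
    vis = sum(s.visitation.to_numpy(dtype=float) for s in series_list) / len(series_list)
    vis_df = pd.DataFrame(vis, columns=list(INSECT_CATEGORIES))
    return replace(first, cover=cover, flower_density=dens, visitation=vis_df)
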