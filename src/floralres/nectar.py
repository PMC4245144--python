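"""Nectar sucrose energetics: from microcapillary readings to hive support.

Standing nectar is removed from flowers at three daily time points (0900,
1200 and 1500 h), the flowers are bagged against insects, and after two
hours the accumulated nectar is drawn into a 1, 5 or 10 µL microcapillary.
The nectar volume follows from the column length as a fraction of the
capillary length; its sugar content follows from the refractometer reading
(°Brix, percent sucrose w/w) through the standard quadratic concentration
curve

    c(C) = 0.00226 + 0.00937 C + 0.0000585 C²   [mg sucrose per µL nectar]

so that a volume ``v`` µL at ``C`` °Bx holds ``1000 · v · c(C)`` µg of
sucrose.  Daily per-flower production is approximated as the sum of the
three 2-h interval means (pooled over sampling dates); multiplying by the
season's cumulative flower count per hectare gives potential sucrose per
hectare, and dividing by a colony's annual sugar requirement (100–200 kg)
gives the number of honey-bee hives a hectare could in principle support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "INTERVALS",
    "CAPILLARY_SIZES_UL",
    "NectarRecord",
    "SucroseBudget",
    "nectar_volume",
    "sucrose_concentration",
    "sucrose_mass",
    "interval_means",
    "daily_flower_sucrose",
    "season_sucrose_per_ha",
    "hives_supported",
    "sucrose_budget",
]

#: the three standing-crop exclusion intervals (local time)
INTERVALS = ("0900-1100", "1200-1400", "1500-1700")

#: microcapillary sizes in use, µL
CAPILLARY_SIZES_UL = (1.0, 5.0, 10.0)

#: annual sugar requirement of a healthy honey-bee colony, kg (low, high)
HIVE_SUGAR_NEED_KG = (100.0, 200.0)

UG_PER_KG = 1.0e9


@dataclass(frozen=True)
class NectarRecord:
    """One microcapillary extraction from one flower in one interval."""

    flower_id: str
    interval: str
    capillary_volume: float  #: µL, one of 1, 5, 10
    capillary_length: float  #: mm
    column_length: float  #: mm of nectar column
    brix: float  #: °Bx, percent sucrose

    def __post_init__(self) -> None:
        if self.interval not in INTERVALS:
            raise InputError(f"unknown interval {self.interval!r}")
        if self.capillary_volume not in CAPILLARY_SIZES_UL:
            raise InputError("capillary volume must be 1, 5 or 10 µL")
        if self.capillary_length <= 0:
            raise InputError("capillary length must be positive")
        if not 0 <= self.column_length <= self.capillary_length:
            raise InputError("column length must lie in [0, capillary length]")
        if not 0 <= self.brix <= 85:
            raise InputError("°Brix must lie in [0, 85]")

    @property
    def volume_ul(self) -> float:
        return nectar_volume(self.column_length, self.capillary_length, self.capillary_volume)

    @property
    def sucrose_ug(self) -> float:
        return sucrose_mass(self.volume_ul, self.brix)


def nectar_volume(column_length_mm, capillary_length_mm, capillary_volume_ul):
    """Nectar volume in µL: column length over capillary length times capacity."""
    col = np.asarray(column_length_mm, dtype=float)
    cap = np.asarray(capillary_length_mm, dtype=float)
    vol = np.asarray(capillary_volume_ul, dtype=float)
    if np.any(cap <= 0):
        raise InputError("capillary length must be positive")
    if np.any(col < 0) or np.any(col > cap):
        raise InputError("column length must lie in [0, capillary length]")
    out = col / cap * vol
    return float(out) if out.ndim == 0 else out


def sucrose_concentration(brix):
    """Sucrose concentration in mg per µL of nectar at the given °Bx."""
    c = np.asarray(brix, dtype=float)
    if np.any((c < 0) | (c > 85)):
        raise InputError("°Brix must lie in [0, 85]")
    out = 0.00226 + 0.00937 * c + 0.0000585 * c * c
    return float(out) if out.ndim == 0 else out


def sucrose_mass(volume_ul, brix):
    """Sucrose mass in µg contained in ``volume_ul`` of nectar at ``brix`` °Bx.

    Linear in volume at fixed concentration and strictly increasing in both
    arguments (for positive volume).
    """
    v = np.asarray(volume_ul, dtype=float)
    if np.any(v < 0):
        raise InputError("volume must be non-negative")
    out = v * 1000.0 * sucrose_concentration(brix)
    return float(out) if out.ndim == 0 else out


def interval_means(records: pd.DataFrame) -> pd.Series:
    """Mean sucrose (µg per 2 h) per interval, pooled over flowers and dates.

    Expects the nectar record schema columns ``interval``,
    ``capillary_volume_ul``, ``capillary_length_mm``, ``column_length_mm``
    and ``brix``.  Pooling is an unweighted mean over all records of an
    interval, across sampling dates.
    """
    required = {"interval", "capillary_volume_ul", "capillary_length_mm",
                "column_length_mm", "brix"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"nectar records missing columns: {sorted(missing)}")
    unknown = set(records["interval"]) - set(INTERVALS)
    if unknown:
        raise InputError(f"unknown intervals: {sorted(unknown)}")
    vol = nectar_volume(records["column_length_mm"].to_numpy(),
                        records["capillary_length_mm"].to_numpy(),
                        records["capillary_volume_ul"].to_numpy())
    mass = sucrose_mass(vol, records["brix"].to_numpy())
    out = pd.Series(mass, index=records.index).groupby(records["interval"]).mean()
    return out.reindex(INTERVALS)


def daily_flower_sucrose(means) -> float:
    """Daily per-flower sucrose (µg d⁻¹): sum of the three interval means."""
    m = np.asarray(means, dtype=float)
    if m.shape != (3,):
        raise InputError("exactly three interval means are required")
    if np.any(np.isnan(m)):
        raise InputError("interval means must not be missing")
    if np.any(m < 0):
        raise InputError("interval means must be non-negative")
    return float(m.sum())


def season_sucrose_per_ha(flower_sum: float, daily_ug: float) -> float:
    """Potential sucrose per hectare-season in kg: ``∑f ha⁻¹ × µg d⁻¹ × 10⁻⁹``.

    Unrounded; summary tables report it to the nearest kg.
    """
    if flower_sum < 0 or daily_ug < 0:
        raise InputError("inputs must be non-negative")
    return float(flower_sum) * float(daily_ug) / UG_PER_KG


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def hives_supported(season_sucrose_kg: float,
                    annual_need_low: float = HIVE_SUGAR_NEED_KG[0],
                    annual_need_high: float = HIVE_SUGAR_NEED_KG[1]) -> tuple[int, int]:
    """Honey-bee colonies supportable for a year by the hectare's sucrose.

    Returns ``(hives at the high requirement, hives at the low requirement)``
    — the conservative and the optimistic colony counts — each rounded to
    the nearest whole hive.
    """
    if annual_need_low <= 0 or annual_need_high <= 0:
        raise InputError("annual sugar needs must be positive")
    if annual_need_low >= annual_need_high:
        raise InputError("annual_need_low must be below annual_need_high")
    if season_sucrose_kg < 0:
        raise InputError("season sucrose must be non-negative")
    return (_round_half_up(season_sucrose_kg / annual_need_high),
            _round_half_up(season_sucrose_kg / annual_need_low))


@dataclass(frozen=True)
class SucroseBudget:
    """Per-flower and per-hectare sucrose budget for one treatment."""

    interval_means: tuple[float, float, float]  #: µg per 2 h, one per interval
    daily_per_flower: float  #: µg d⁻¹
    season_per_ha: float  #: kg ha⁻¹ season⁻¹
    hives_min: int
    hives_max: int


def sucrose_budget(records: pd.DataFrame, flower_sum: float,
                   annual_need_low: float = HIVE_SUGAR_NEED_KG[0],
                   annual_need_high: float = HIVE_SUGAR_NEED_KG[1]) -> SucroseBudget:
    """Full nectar chain: records → interval means → daily → ha-season → hives."""
    means = interval_means(records)
    daily = daily_flower_sucrose(means.to_numpy())
    season = season_sucrose_per_ha(flower_sum, daily)
    hmin, hmax = hives_supported(season, annual_need_low, annual_need_high)
    return SucroseBudget(interval_means=tuple(float(v) for v in means),
                         daily_per_flower=daily, season_per_ha=season,
                         hives_min=hmin, hives_max=hmax)
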