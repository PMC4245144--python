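"""Published summary values from a three-year echium sowing-date field trial.

A spring- versus summer-sowing experiment with oilseed echium
(*Echium plantagineum* L.) run 2011–2013 in west-central Minnesota provides
the reference numbers used throughout the examples and cross-checks:
per-treatment flowering dynamics and seed yields, season-integral flower
and visitation metrics, the measured daily per-flower nectar sucrose, and
the crop-economics constants.  These are inputs to the pipeline (and
worked-example expectations), not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "field_trials",
    "season_metrics",
    "FLOWER_SUMS_2013",
    "DAILY_SUCROSE_UG",
    "HIVE_SUGAR_NEED_KG",
    "SEED_PRICE_USD_PER_KG",
    "NET_GROSS_RATIO",
    "REFERENCE_NET_RETURNS",
    "SOYBEAN_PLANTS_PER_HA",
    "SOYBEAN_FLOWERS_PER_PLANT",
]

#: cumulative flowers ha⁻¹ over anthesis in 2013 by sowing treatment.
#: The late value is the one consistent with the trial's sucrose figure
#: (its summary table shows 0.98 billion from independent rounding).
FLOWER_SUMS_2013 = {"early": 1.01e9, "mid": 4.59e9, "late": 0.96e9}

#: measured daily nectar sucrose production of a single echium flower, µg d⁻¹
DAILY_SUCROSE_UG = 635.0

#: annual sugar requirement of a healthy honey-bee colony, kg yr⁻¹ (low, high)
HIVE_SUGAR_NEED_KG = (100.0, 200.0)

#: contract price for echium seed, $ kg⁻¹
SEED_PRICE_USD_PER_KG = 5.30

#: net return as a fraction of gross for the regional commodity crops (2012)
NET_GROSS_RATIO = 0.32

#: 2012 median net returns for the regional commodity crops, $ ha⁻¹
REFERENCE_NET_RETURNS = {"corn": 894.0, "soybean": 526.0}

#: a very prolific soybean stand used as the flower-production comparator
SOYBEAN_PLANTS_PER_HA = 5.0e5
SOYBEAN_FLOWERS_PER_PLANT = 800.0


def field_trials() -> pd.DataFrame:
    """Per-treatment flowering dynamics and seed yields, one row per site-year.

    Columns: year, planting_time, days_to_first_flower (d),
    anthesis_duration (d), rainfall_mm (sowing→harvest),
    thermal_time_cd (cumulative °d), seed_yield_kg_ha.
    """
    rows = [
        (2011, "early", 42, 70, 304, 2352, 773),
        (2011, "late", 41, 69, 245, 2015, 27),
        (2012, "early", 54, 55, 247, 2179, 327),
        (2012, "late", 55, 34, 148, 1992, 85),
        (2013, "early", 44, 57, 292, 2003, 430),
        (2013, "mid", 36, 54, 238, 1978, 387),
        (2013, "late", 46, 48, 145, 1867, 258),
    ]
    return pd.DataFrame(rows, columns=[
        "year", "planting_time", "days_to_first_flower", "anthesis_duration",
        "rainfall_mm", "thermal_time_cd", "seed_yield_kg_ha"])


def season_metrics() -> pd.DataFrame:
    """Season-integral metrics per year × planting time.

    Columns: year, planting_time, coverage_time (%t, percent·days), pvt
    (visitation-rate·days), intensity (pvt %t⁻¹), flower_sum_billion
    (∑f ha⁻¹ / 10⁹, 2013 only) and sucrose_kg_ha (kg ha⁻¹ season⁻¹,
    2013 only).
    """
    rows = [
        (2011, "early", 1577, 271, 0.17, None, None),
        (2011, "late", 765, 356, 0.47, None, None),
        (2012, "early", 769, 376, 0.50, None, None),
        (2012, "late", 535, 897, 1.68, None, None),
        (2013, "early", 1113, 1787, 1.61, 1.01, 641),
        (2013, "mid", 929, 1774, 1.91, 4.59, 2911),
        (2013, "late", 972, 2662, 2.74, 0.98, 609),
    ]
    return pd.DataFrame(rows, columns=[
        "year", "planting_time", "coverage_time", "pvt", "intensity",
        "flower_sum_billion", "sucrose_kg_ha"])
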