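"""Gross/net return and break-even yield arithmetic for an alternative oilseed.

A specialty oilseed pays a contract price per kg of seed; whether it can
compete with the region's commodity rotation comes down to simple
arithmetic: gross return is yield × price, net return is assumed to be the
same fraction of gross as for the commodity crops, and the break-even yield
against a commodity's net return N is ``N / ratio / price``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError

__all__ = ["EconConfig", "gross_return", "net_return", "breakeven_yield", "yield_summary"]


@dataclass(frozen=True)
class EconConfig:
    """Prices, the net:gross ratio and commodity reference net returns ($ ha⁻¹)."""

    seed_price: float = 5.30  #: contract seed price, $ kg⁻¹
    net_gross_ratio: float = 0.32  #: net return as a fraction of gross
    reference_net_returns: Mapping[str, float] = field(
        default_factory=lambda: {"corn": 894.0, "soybean": 526.0})

    def __post_init__(self) -> None:
        if self.seed_price <= 0:
            raise InputError("seed price must be positive")
        if not 0 < self.net_gross_ratio <= 1:
            raise InputError("net:gross ratio must lie in (0, 1]")


def gross_return(yield_kg_ha: float, price: float = 5.30) -> float:
    """Gross return in $ ha⁻¹: yield × price (reported to the nearest dollar)."""
    if yield_kg_ha < 0:
        raise InputError("yield must be non-negative")
    if price <= 0:
        raise InputError("price must be positive")
    return float(yield_kg_ha) * float(price)


def net_return(gross: float, ratio: float = 0.32) -> float:
    """Net return assuming the commodity-crop net:gross ratio."""
    if not 0 < ratio <= 1:
        raise InputError("ratio must lie in (0, 1]")
    if gross < 0:
        raise InputError("gross return must be non-negative")
    return float(gross) * float(ratio)


def breakeven_yield(target_net: float, ratio: float = 0.32, price: float = 5.30) -> float:
    """Seed yield (kg ha⁻¹) whose net return matches ``target_net`` $ ha⁻¹.

    ``target_net / ratio / price``, reported to the nearest kg.
    """
    if target_net <= 0 or ratio <= 0 or price <= 0:
        raise InputError("all inputs must be positive")
    return float(target_net) / float(ratio) / float(price)


def yield_summary(yields: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Unweighted mean seed yield per planting class (kg ha⁻¹, unrounded).

    ``yields`` maps a planting class (e.g. ``early``/``mid``/``late``) to
    the per-site-year yields in that class.
    """
    out: dict[str, float] = {}
    for cls, vals in yields.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            raise InputError(f"planting class {cls!r} has no yields")
        if np.any(arr < 0):
            raise InputError(f"negative yield in class {cls!r}")
        out[cls] = float(arr.mean())
    return out
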