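"""Plotless (distance-based) estimation of open-flower density.

Field crews record, at each of a set of sample points along transects, the
distance to the nearest open flower, and from that flower the distance to
its nearest neighbouring open flower.  Both searches stop at a fixed field
limit (default 0.15 m), beyond which the observation is censored.  This
module turns such joint point-to-flower / flower-to-neighbour distance
samples into a corrected flower density.

Under complete spatial randomness (CSR) with intensity ``lam`` the squared
nearest-object distance is exponential: ``P(d > r) = exp(-lam * pi * r^2)``.
The point-distance and neighbour-distance estimators below are the maximum
likelihood estimators of ``lam`` for that censored-exponential model, with
censoring at a truncation radius ``R``:

    D = m / (pi * (sum_i d_i^2 + (n - m) * R^2))

where the ``m`` uncensored distances not exceeding ``R`` enter with their
squared value and every other search contributes its fully searched disc
``pi * R^2``.

The neighbour estimator needs one geometric refinement.  The flower whose
neighbour is sought was itself found as the nearest flower to a sample
point at distance ``d``, so the disc of radius ``d`` around the sample
point is already known to be empty; the part of the neighbour search disc
overlapping it cannot contain the neighbour.  Ignoring this inflates
neighbour distances and biases the density low by roughly a third even
under CSR.  The estimator therefore uses effective searched areas

    A(r; d) = pi * r^2 - lens(r, d)

(``lens`` being the overlap of a radius-``r`` disc centred on the flower
with the empty radius-``d`` disc whose boundary the flower sits on), and
the Poisson maximum-likelihood estimate D_N = m2 / sum_j A_j with censored
searches contributing ``A(R; d_j)``.

On clustered patterns the two estimators err in opposite directions --
point distances over-sample the empty space between clumps (density biased
low) while neighbour distances are dominated by the tight within-clump
spacing (density biased high).  The corrected point density is their
geometric mean,

    D_C = sqrt(D_P * D_N),

which cancels the leading multiplicative biases and is validated here by
parameter recovery on simulated clustered patterns rather than against any
particular legacy software.

The truncation radius is chosen per sampling date so that roughly 30% of
the longest point distances are excluded (they still contribute searched
area), which stabilises the estimator against the heavy right tail of
nearest-object distances on clumped patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, EstimationWarning, InputError

__all__ = [
    "DistanceSample",
    "DensityEstimate",
    "select_truncation_radius",
    "estimate_point_density",
    "estimate_neighbor_density",
    "corrected_point_density",
    "bootstrap_ci",
    "se_from_ci",
    "estimate_density",
    "M2_PER_HA",
]

#: square metres per hectare; per-hectare densities are ``per-m2 * M2_PER_HA``
M2_PER_HA = 1.0e4

#: default fraction of the longest point distances excluded by truncation
DEFAULT_EXCLUDE_FRACTION = 0.30


@dataclass(frozen=True)
class DistanceSample:
    """Joint point-to-flower and flower-to-neighbour distances for one date.

    Arrays are aligned per sample point.  A censored point distance means no
    flower was found within ``field_limit`` of the sample point; its
    neighbour entries are then censored as well.  Distances are in metres.
    """

    point_distances: np.ndarray  #: metres; NaN where censored
    point_censored: np.ndarray  #: bool per sample point
    neighbor_distances: np.ndarray  #: metres; NaN where censored or point censored
    neighbor_censored: np.ndarray  #: bool; True whenever no neighbour was found
    field_limit: float = 0.15
    date: int | None = field(default=None)  #: day of year, if known

    def __post_init__(self) -> None:
        pd_ = np.asarray(self.point_distances, dtype=float)
        pc = np.asarray(self.point_censored, dtype=bool)
        nd = np.asarray(self.neighbor_distances, dtype=float)
        nc = np.asarray(self.neighbor_censored, dtype=bool)
        if not (pd_.shape == pc.shape == nd.shape == nc.shape) or pd_.ndim != 1:
            raise InputError("distance arrays must be 1-d and of equal length")
        if self.field_limit <= 0:
            raise InputError("field_limit must be positive")
        for d, cens, what in ((pd_, pc, "point"), (nd, nc, "neighbor")):
            obs = d[~cens]
            if obs.size and (np.any(obs < 0) or np.any(obs > self.field_limit + 1e-12)):
                raise InputError(f"uncensored {what} distances must lie in [0, field_limit]")
        if np.any(~nc & pc):
            raise InputError("a censored point cannot carry an uncensored neighbor distance")
        object.__setattr__(self, "point_distances", pd_)
        object.__setattr__(self, "point_censored", pc)
        object.__setattr__(self, "neighbor_distances", nd)
        object.__setattr__(self, "neighbor_censored", nc)

    @property
    def n_points(self) -> int:
        """Total number of sample points (censored or not)."""
        return int(self.point_distances.size)

    @property
    def n_found(self) -> int:
        """Number of sample points at which a flower was found."""
        return int(np.count_nonzero(~self.point_censored))


@dataclass(frozen=True)
class DensityEstimate:
    """Point, neighbour and corrected densities with uncertainty.

    Densities ``d_*`` are flowers per m²; ``per_ha``, the confidence limits
    and the standard error are flowers per hectare.
    """

    d_point: float
    d_neighbor: float
    d_corrected: float
    per_ha: float
    ci_low: float
    ci_high: float
    se: float
    trunc_radius: float
    n_used: int
    level: float = 0.95
    date: int | None = None


def select_truncation_radius(point_distances, exclude_fraction: float = DEFAULT_EXCLUDE_FRACTION) -> float:
    """Truncation radius excluding the stated fraction of longest point distances.

    Returns the ``1 - exclude_fraction`` empirical quantile (linear
    interpolation between order statistics) of the uncensored point
    distances.  Distances strictly greater than the radius are excluded from
    the squared-distance sum downstream but still contribute searched area.
    NaN entries are treated as censored and ignored.
    """
    if not 0.0 <= exclude_fraction < 1.0:
        raise InputError("exclude_fraction must lie in [0, 1)")
    d = np.asarray(point_distances, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise EstimationError("all point distances censored; cannot select truncation radius")
    return float(np.quantile(d, 1.0 - exclude_fraction, method="linear"))


def _truncated_density(sq_sum: float, m: int, n_searches: int, radius: float) -> float:
    # censored-exponential MLE: m detections over total searched area
    area = np.pi * (sq_sum + (n_searches - m) * radius * radius)
    return float(m / area)


def _point_density_arrays(pd_: np.ndarray, pc: np.ndarray, radius: float) -> float:
    within = ~pc & (np.nan_to_num(pd_, nan=np.inf) <= radius)
    m = int(np.count_nonzero(within))
    if m == 0:
        return 0.0
    return _truncated_density(float(np.sum(pd_[within] ** 2)), m, pd_.size, radius)


def _lens_area(r: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Overlap area of discs of radii ``r`` and ``d`` whose centres are ``d`` apart."""
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    out = np.where(r >= 2.0 * d, np.pi * d * d, 0.0)
    partial = (r < 2.0 * d) & (r > 0) & (d > 0)
    if np.any(partial):
        rp, dp_ = r[partial], d[partial]
        a1 = rp * rp * np.arccos(np.clip(rp / (2.0 * dp_), -1.0, 1.0))
        a2 = dp_ * dp_ * np.arccos(np.clip(1.0 - rp * rp / (2.0 * dp_ * dp_), -1.0, 1.0))
        a3 = 0.5 * rp * np.sqrt(np.maximum(4.0 * dp_ * dp_ - rp * rp, 0.0))
        out[partial] = a1 + a2 - a3
    return out


def _neighbor_searched_area(r: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Effective neighbour search area up to radius ``r`` for a flower found
    at point distance ``d``: the disc minus the known-empty lens."""
    r = np.asarray(r, dtype=float)
    return np.pi * r * r - _lens_area(r, d)


def _neighbor_density_arrays(pd_: np.ndarray, pc: np.ndarray, nd: np.ndarray,
                             nc: np.ndarray, radius: float) -> float:
    found = ~pc
    if not np.any(found):
        return 0.0
    d = pd_[found]
    r = nd[found]
    uncensored = ~nc[found] & (np.nan_to_num(r, nan=np.inf) <= radius)
    m2 = int(np.count_nonzero(uncensored))
    if m2 == 0:
        return 0.0
    searched = np.where(uncensored, np.nan, radius)
    searched[uncensored] = r[uncensored]
    total_area = float(np.sum(_neighbor_searched_area(searched, d)))
    return m2 / total_area


def _check_radius(sample: DistanceSample, trunc_radius: float) -> None:
    if not 0 < trunc_radius <= sample.field_limit + 1e-12:
        raise InputError("trunc_radius must be positive and not exceed the field limit")


def estimate_point_density(sample: DistanceSample, trunc_radius: float) -> float:
    """Point-to-flower density (flowers per m²) with truncation at ``trunc_radius``.

    ``D_P = m / (pi * (sum d_i^2 + (n - m) R^2))`` over the ``m`` uncensored
    point distances not exceeding ``R``; censored points and points beyond
    ``R`` contribute the fully searched disc ``pi R^2``.  With no detections
    at all the estimate is 0 and an :class:`EstimationWarning` is emitted.
    """
    _check_radius(sample, trunc_radius)
    if sample.n_points < 1:
        raise InputError("sample must contain at least one point")
    d = _point_density_arrays(sample.point_distances, sample.point_censored, trunc_radius)
    if d == 0.0:
        warnings.warn("no uncensored point distances within radius; density set to 0",
                      EstimationWarning, stacklevel=2)
    return d


def estimate_neighbor_density(sample: DistanceSample, trunc_radius: float) -> float:
    """Flower-to-nearest-neighbour density (flowers per m²), truncated at ``trunc_radius``.

    Censored searched-area estimator over the neighbour distances of the
    flowers that were found: ``D_N = m2 / sum_j A(min(r_j, R); d_j)`` with
    ``m2`` uncensored neighbour distances within ``R`` and ``A(r; d)`` the
    neighbour search disc minus the lens already known to be empty from the
    point search that located the flower at distance ``d``.
    """
    _check_radius(sample, trunc_radius)
    d = _neighbor_density_arrays(sample.point_distances, sample.point_censored,
                                 sample.neighbor_distances,
                                 sample.neighbor_censored, trunc_radius)
    if d == 0.0:
        warnings.warn("no uncensored neighbor distances within radius; density set to 0",
                      EstimationWarning, stacklevel=2)
    return d


def corrected_point_density(d_point: float, d_neighbor: float) -> float:
    """Clustering-corrected density: the geometric mean of the two estimators.

    Equals either input when they agree and always lies between them; on
    clustered patterns the opposite-signed multiplicative biases of the
    point and neighbour estimators largely cancel.
    """
    if d_point < 0 or d_neighbor < 0:
        raise InputError("densities must be non-negative")
    return float(np.sqrt(d_point * d_neighbor))


def _corrected_arrays(pd_: np.ndarray, pc: np.ndarray, nd: np.ndarray, nc: np.ndarray,
                      exclude_fraction: float) -> float:
    obs = pd_[~pc]
    if obs.size == 0:
        return 0.0
    radius = float(np.quantile(obs, 1.0 - exclude_fraction, method="linear"))
    if radius <= 0.0:
        return 0.0
    dp = _point_density_arrays(pd_, pc, radius)
    dn = _neighbor_density_arrays(pd_, pc, nd, nc, radius)
    return float(np.sqrt(dp * dn))


def bootstrap_ci(sample: DistanceSample, level: float = 0.95, n_boot: int = 1000,
                 seed: int | None = None,
                 exclude_fraction: float = DEFAULT_EXCLUDE_FRACTION) -> tuple[float, float]:
    """Percentile bootstrap interval for the corrected density (flowers per m²).

    Sample points are resampled with replacement as units, each carrying its
    attached neighbour observation; the truncation radius is re-selected on
    every resample.  Reproducible for a fixed ``seed``.
    """
    if n_boot < 100:
        raise InputError("n_boot must be at least 100")
    if not 0.0 < level < 1.0:
        raise InputError("level must lie in (0, 1)")
    if sample.n_found == 0:
        raise EstimationError("sample is fully censored; bootstrap undefined")
    rng = np.random.default_rng(seed)
    n = sample.n_points
    pd_, pc = sample.point_distances, sample.point_censored
    nd, nc = sample.neighbor_distances, sample.neighbor_censored
    idx = rng.integers(0, n, size=(n_boot, n))
    vals = np.empty(n_boot)
    for b in range(n_boot):
        i = idx[b]
        vals[b] = _corrected_arrays(pd_[i], pc[i], nd[i], nc[i], exclude_fraction)
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def se_from_ci(ci_low: float, ci_high: float, n_points: int, level: float = 0.95) -> float:
    """Standard error backed out of a confidence interval.

    ``SE = (ci_high - ci_low) / (2 t)`` with ``t`` the two-sided critical
    value at the given level and ``n_points - 1`` degrees of freedom.
    """
    if ci_high < ci_low:
        raise InputError("ci_high must not be below ci_low")
    if n_points < 2:
        raise InputError("n_points must be at least 2")
    if not 0.0 < level < 1.0:
        raise InputError("level must lie in (0, 1)")
    t = stats.t.ppf(0.5 + level / 2.0, df=n_points - 1)
    return float((ci_high - ci_low) / (2.0 * t))


def estimate_density(sample: DistanceSample,
                     exclude_fraction: float = DEFAULT_EXCLUDE_FRACTION,
                     level: float = 0.95, n_boot: int = 1000,
                     seed: int | None = None) -> DensityEstimate:
    """Full corrected-density workflow for one sampling date.

    Selects the truncation radius from the pooled point distances, computes
    the point, neighbour and corrected densities, bootstraps the confidence
    interval and derives the standard error from it.  Per-hectare quantities
    are the per-m² ones times 10^4, with no rounding.
    """
    radius = select_truncation_radius(
        np.where(sample.point_censored, np.nan, sample.point_distances), exclude_fraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EstimationWarning)
        dp = estimate_point_density(sample, radius)
        dn = estimate_neighbor_density(sample, radius)
    dc = corrected_point_density(dp, dn)
    lo, hi = bootstrap_ci(sample, level=level, n_boot=n_boot, seed=seed,
                          exclude_fraction=exclude_fraction)
    lo_ha, hi_ha = lo * M2_PER_HA, hi * M2_PER_HA
    se = se_from_ci(lo_ha, hi_ha, sample.n_points, level=level)
    within = ~sample.point_censored & (
        np.nan_to_num(sample.point_distances, nan=np.inf) <= radius)
    return DensityEstimate(
        d_point=dp, d_neighbor=dn, d_corrected=dc, per_ha=dc * M2_PER_HA,
        ci_low=lo_ha, ci_high=hi_ha, se=se, trunc_radius=radius,
        n_used=int(np.count_nonzero(within)), level=level, date=sample.date)
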