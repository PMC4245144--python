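"""Synthetic field generator for the whole analysis chain.

Emulates the five record types a sowing-date flowering trial produces —
spatial open-flower patterns, transect distance samples, phenology and
visitation time series, and microcapillary nectar records — with the
statistical structure the estimators assume, so every downstream stage can
be validated by parameter recovery on data with known truth.

Spatial patterns come in two flavours: homogeneous Poisson (complete
spatial randomness, the null model under which simple distance estimators
are unbiased) and Thomas cluster processes (Poisson parents, each with a
Poisson number of Gaussian-scattered offspring) to exercise the clustering
correction.  Distance sampling mimics the field protocol: transect ropes
with pre-marked points, nearest-open-flower and nearest-neighbour searches,
both censored at a fixed field limit.

Seasonal curves use a scaled beta-density shape over the anthesis window —
zero at first flower and harvest, a single interior peak — matching the
observed unimodal cover dynamics (peak near 40% cover two to three weeks
after first flower).  Observation noise is multiplicative lognormal for
cover and flower density (positive-valued scores) and Poisson for insect
counts; ``noise_cv = 0`` switches every generator to its exact noise-free
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .density import DistanceSample
from .errors import InputError, LayoutError
from .nectar import CAPILLARY_SIZES_UL, INTERVALS, sucrose_concentration
from .phenology import INSECT_CATEGORIES, SeasonSeries

__all__ = [
    "PLOT_DIMENSIONS",
    "FlowerPattern",
    "PhenologyParams",
    "simulate_poisson_pattern",
    "simulate_thomas_pattern",
    "sample_transects",
    "bloom_curve",
    "simulate_phenology",
    "simulate_nectar_records",
]

#: default plot footprint (width, length) in metres
PLOT_DIMENSIONS = (3.1, 12.2)

# beta-shape concentration: a + b = 2 + _SHAPE; larger -> sharper peak
_SHAPE = 4.0

# how non-honey-bee visits split among the remaining categories
# (bumble bee, other bee, fly, butterfly, other); hoverflies and other
# flies dominate the shoulders of the season
_OTHER_CATEGORY_WEIGHTS = np.array([0.20, 0.10, 0.40, 0.05, 0.25])

#: generator convention: all microcapillaries are cut to the same length
_CAPILLARY_LENGTH_MM = 64.0

#: default nectar sampling dates (two mid-anthesis days)
_NECTAR_DATES = ("2013-07-16", "2013-08-07")


@dataclass(frozen=True)
class FlowerPattern:
    """Open-flower positions within one plot, with known truth if simulated."""

    plot_width: float  #: m
    plot_length: float  #: m
    coords: np.ndarray  #: (n, 2) positions in m
    true_density: float | None = None  #: flowers per m², when simulated

    def __post_init__(self) -> None:
        if self.plot_width <= 0 or self.plot_length <= 0:
            raise InputError("plot dimensions must be positive")
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if coords.size and (
            np.any(coords < -1e-9)
            or np.any(coords[:, 0] > self.plot_width + 1e-9)
            or np.any(coords[:, 1] > self.plot_length + 1e-9)
        ):
            raise InputError("all flower coordinates must lie inside the plot")
        if self.true_density is not None and self.true_density < 0:
            raise InputError("true density must be non-negative")
        object.__setattr__(self, "coords", coords)

    @property
    def area(self) -> float:
        """Plot area in m²."""
        return self.plot_width * self.plot_length

    @property
    def n_flowers(self) -> int:
        return int(self.coords.shape[0])

    @property
    def realized_density(self) -> float:
        """Realised flowers per m² (count over area)."""
        return self.n_flowers / self.area


@dataclass(frozen=True)
class PhenologyParams:
    """Season-shape parameters for one sowing treatment.

    Defaults describe a spring-sown crop in the upper Midwest: first flower
    ~45 d after sowing, ~55 d of anthesis, cover peaking near 40% about two
    and a half weeks into flowering, and honey bees making up about half of
    all insect visits.
    """

    days_to_first_flower: float = 45.0  #: d after sowing
    anthesis_duration: float = 55.0  #: d, first flower to harvest
    peak_cover: float = 40.0  #: percent ground cover at the seasonal peak
    peak_day_offset: float = 17.0  #: d after first flower at which curves peak
    peak_density: float = 3.0e7  #: open flowers ha⁻¹ at the peak
    honeybee_share: float = 0.50  #: expected honey-bee fraction of visits
    peak_visitation: float = 35.0  #: insects min⁻¹ observer⁻¹ at the peak
    sowing_doy: int = 135  #: day of year of sowing (mid-May)
    noise_cv: float = 0.15  #: CV of lognormal observation noise; 0 = noise-free
    observers: int = 2  #: people counting per walk
    minutes: float = 2.0  #: duration of one observation walk

    def __post_init__(self) -> None:
        if not 0 <= self.peak_cover <= 100:
            raise InputError("peak cover must lie in [0, 100]")
        if self.days_to_first_flower <= 0 or self.anthesis_duration <= 0:
            raise InputError("durations must be positive")
        if not 0 < self.peak_day_offset < self.anthesis_duration:
            raise InputError("peak_day_offset must fall inside the anthesis window")
        if not 0 <= self.honeybee_share <= 1:
            raise InputError("honeybee share must lie in [0, 1]")
        if min(self.peak_density, self.peak_visitation, self.noise_cv) < 0:
            raise InputError("rates and noise_cv must be non-negative")
        if self.observers < 1 or self.minutes <= 0:
            raise InputError("observers must be >= 1 and minutes > 0")


def _check_plot(plot) -> tuple[float, float]:
    w, l = float(plot[0]), float(plot[1])
    if w <= 0 or l <= 0:
        raise InputError("plot dimensions must be positive")
    return w, l


def simulate_poisson_pattern(density: float, plot=PLOT_DIMENSIONS,
                             seed: int | None = None) -> FlowerPattern:
    """Homogeneous Poisson (CSR) flower pattern with the given intensity (m⁻²)."""
    if density < 0:
        raise InputError("density must be non-negative")
    w, l = _check_plot(plot)
    rng = np.random.default_rng(seed)
    n = rng.poisson(density * w * l)
    coords = rng.uniform((0.0, 0.0), (w, l), size=(n, 2))
    return FlowerPattern(plot_width=w, plot_length=l, coords=coords, true_density=density)


def simulate_thomas_pattern(parent_density: float, mean_offspring: float,
                            cluster_sd: float, plot=PLOT_DIMENSIONS,
                            seed: int | None = None) -> FlowerPattern:
    """Thomas cluster process: Poisson parents with Gaussian-scattered offspring.

    Offspring falling outside the plot are dropped; ``true_density`` records
    the nominal intensity ``parent_density * mean_offspring`` before that
    edge loss.
    """
    if min(parent_density, mean_offspring, cluster_sd) < 0:
        raise InputError("all Thomas parameters must be non-negative")
    w, l = _check_plot(plot)
    rng = np.random.default_rng(seed)
    n_parents = rng.poisson(parent_density * w * l)
    parents = rng.uniform((0.0, 0.0), (w, l), size=(n_parents, 2))
    counts = rng.poisson(mean_offspring, size=n_parents)
    centers = np.repeat(parents, counts, axis=0)
    offspring = centers + rng.normal(0.0, cluster_sd, size=centers.shape)
    inside = ((offspring[:, 0] >= 0) & (offspring[:, 0] <= w)
              & (offspring[:, 1] >= 0) & (offspring[:, 1] <= l))
    return FlowerPattern(plot_width=w, plot_length=l, coords=offspring[inside],
                         true_density=parent_density * mean_offspring)


def sample_transects(pattern: FlowerPattern, n_transects: int = 3,
                     points_per_transect: int = 6, point_spacing: float = 0.30,
                     field_limit: float = 0.15, seed: int | None = None,
                     date: int | None = None) -> DistanceSample:
    """Distance-sample a flower pattern with randomly placed transect ropes.

    Each transect carries ``points_per_transect`` pre-marked points
    ``point_spacing`` apart; it is laid parallel to the plot's long axis at
    a uniformly random position, fully inside the plot.  At each point the
    nearest open flower is sought within ``field_limit``; when found, that
    flower's nearest other flower is sought within the same limit.  Failed
    searches are censored.
    """
    if n_transects < 1 or points_per_transect < 1:
        raise InputError("need at least one transect and one point per transect")
    if point_spacing <= 0 or field_limit <= 0:
        raise InputError("spacing and field limit must be positive")
    t_len = (points_per_transect - 1) * point_spacing
    w, l = pattern.plot_width, pattern.plot_length
    if t_len > max(w, l):
        raise LayoutError(f"transect of {t_len:.2f} m does not fit in a {w}x{l} m plot")
    along_axis = 1 if l >= w else 0  # lay the rope along the long axis
    dims = (w, l)
    rng = np.random.default_rng(seed)
    pts = np.empty((n_transects * points_per_transect, 2))
    offsets = np.arange(points_per_transect) * point_spacing
    for t in range(n_transects):
        start_along = rng.uniform(0.0, dims[along_axis] - t_len)
        across = rng.uniform(0.0, dims[1 - along_axis])
        row = slice(t * points_per_transect, (t + 1) * points_per_transect)
        pts[row, along_axis] = start_along + offsets
        pts[row, 1 - along_axis] = across
    n_pts = pts.shape[0]
    if pattern.n_flowers == 0:
        nan = np.full(n_pts, np.nan)
        yes = np.ones(n_pts, dtype=bool)
        return DistanceSample(nan, yes, nan.copy(), yes.copy(),
                              field_limit=field_limit, date=date)
    tree = cKDTree(pattern.coords)
    d_point, idx = tree.query(pts)
    point_cens = d_point > field_limit
    point_dist = np.where(point_cens, np.nan, d_point)
    nb_dist = np.full(n_pts, np.nan)
    nb_cens = np.ones(n_pts, dtype=bool)
    found = np.flatnonzero(~point_cens)
    if found.size and pattern.n_flowers >= 2:
        d2, _ = tree.query(pattern.coords[idx[found]], k=2)
        nearest_other = d2[:, 1]
        ok = nearest_other <= field_limit
        nb_dist[found[ok]] = nearest_other[ok]
        nb_cens[found[ok]] = False
    return DistanceSample(point_dist, point_cens, nb_dist, nb_cens,
                          field_limit=field_limit, date=date)


def bloom_curve(params: PhenologyParams, t) -> np.ndarray:
    """Noise-free unimodal season shape in [0, 1] at ``t`` days after first flower.

    A rescaled beta density over the anthesis window whose mode sits exactly
    at ``peak_day_offset`` and whose maximum is exactly 1 there.
    """
    t = np.asarray(t, dtype=float)
    T = params.anthesis_duration
    u = np.clip(t / T, 0.0, 1.0)
    um = params.peak_day_offset / T
    a = 1.0 + _SHAPE * um
    b = 1.0 + _SHAPE * (1.0 - um)
    peak = um ** (a - 1.0) * (1.0 - um) ** (b - 1.0)
    return u ** (a - 1.0) * (1.0 - u) ** (b - 1.0) / peak


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _category_probs(share: float) -> np.ndarray:
    return np.concatenate([[share], (1.0 - share) * _OTHER_CATEGORY_WEIGHTS])


def simulate_phenology(params: PhenologyParams, sampling_interval: float = 1.0,
                       seed: int | None = None, treatment: str = "",
                       year: int = 0) -> SeasonSeries:
    """Simulate one treatment's cover, density and visitation curves.

    The day grid runs from first flower to harvest inclusive (it always
    contains both endpoints, so the series spans exactly the anthesis
    duration).  Cover and flower density get multiplicative lognormal noise
    with CV ``params.noise_cv``; insect counts are Poisson with the
    noise-free rate as mean and are split multinomially into the six
    categories with the honey-bee share as specified.  ``noise_cv = 0``
    produces the exact noise-free curves, including exact category splits.
    """
    if sampling_interval < 1.0:
        raise InputError("sampling interval must be at least one day")
    rng = np.random.default_rng(seed)
    T = params.anthesis_duration
    offsets = np.arange(0.0, T, sampling_interval)
    if offsets[-1] < T:
        offsets = np.append(offsets, T)
    first_flower = params.sowing_doy + params.days_to_first_flower
    days = first_flower + offsets
    base = bloom_curve(params, offsets)
    n = days.size
    cover = np.clip(params.peak_cover * base * _lognormal_factors(rng, params.noise_cv, n),
                    0.0, 100.0)
    dens = params.peak_density * base * _lognormal_factors(rng, params.noise_cv, n)
    total_rate = params.peak_visitation * base
    probs = _category_probs(params.honeybee_share)
    if params.noise_cv == 0.0:
        rates = np.outer(total_rate, probs)
    else:
        effort = params.observers * params.minutes
        counts = np.vstack([
            rng.multinomial(rng.poisson(r * effort), probs) for r in total_rate])
        rates = counts / effort
    vis = pd.DataFrame(rates, columns=list(INSECT_CATEGORIES))
    return SeasonSeries(days=days, cover=cover, flower_density=dens,
                        visitation=vis, treatment=treatment, year=year)


def simulate_nectar_records(n_flowers: int = 10,
                            interval_means=(180.0, 280.0, 175.0),
                            brix_mean: float = 30.0, noise_cv: float = 0.15,
                            seed: int | None = None,
                            dates=_NECTAR_DATES) -> pd.DataFrame:
    """Simulate microcapillary nectar records with known interval means.

    For each date × interval, ``n_flowers`` flowers are drawn whose implied
    2-h sucrose mass is the interval mean times mean-one lognormal noise
    (exactly the mean when ``noise_cv = 0``).  The °Brix reading is held at
    ``brix_mean`` and the capillary column length is back-computed so that
    the standard volume and concentration arithmetic recovers the intended
    sucrose mass; the smallest capillary that holds the volume is used.
    Default interval means sum to 635 µg d⁻¹ with the midday interval
    highest.
    """
    means = np.asarray(interval_means, dtype=float)
    if means.shape != (3,):
        raise InputError("exactly three interval means are required")
    if np.any(means < 0) or noise_cv < 0 or n_flowers < 1:
        raise InputError("means and noise_cv must be non-negative, n_flowers >= 1")
    if not 0 <= brix_mean <= 85:
        raise InputError("°Brix must lie in [0, 85]")
    rng = np.random.default_rng(seed)
    conc = sucrose_concentration(brix_mean)  # mg/µL
    rows = []
    for date in dates:
        for interval, mean_ug in zip(INTERVALS, means):
            masses = mean_ug * _lognormal_factors(rng, noise_cv, n_flowers)
            for j, mass in enumerate(masses):
                volume = 0.0 if (brix_mean == 0.0 or mass == 0.0) else mass / (1000.0 * conc)
                cap = next((c for c in CAPILLARY_SIZES_UL if volume <= c),
                           CAPILLARY_SIZES_UL[-1])
                volume = min(volume, cap)  # an overfull capillary reads full
                rows.append({
                    "flower_id": f"{date}-{interval}-f{j:02d}",
                    "date": date,
                    "interval": interval,
                    "capillary_volume_ul": cap,
                    "capillary_length_mm": _CAPILLARY_LENGTH_MM,
                    "column_length_mm": volume / cap * _CAPILLARY_LENGTH_MM,
                    "brix": brix_mean,
                })
    return pd.DataFrame(rows)
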