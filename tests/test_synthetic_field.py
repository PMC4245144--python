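"""Tests for the synthetic field generators (patterns, transects, seasons, nectar)."""

import numpy as np
import pandas as pd
import pytest

from floralres.errors import InputError, LayoutError
from floralres.nectar import daily_flower_sucrose, interval_means
from floralres.phenology import INSECT_CATEGORIES
from floralres.synthetic_field import (FlowerPattern, PhenologyParams, bloom_curve,
                                       sample_transects, simulate_nectar_records,
                                       simulate_phenology, simulate_poisson_pattern,
                                       simulate_thomas_pattern)


class TestPoissonPattern:
    def test_zero_density_empty(self):
        assert simulate_poisson_pattern(0.0, seed=1).n_flowers == 0

    def test_count_matches_intensity(self):
        """Counts over many seeds match the Poisson mean and variance (λ·A)."""
        lam, plot = 100.0, (3.1, 12.2)
        mean = lam * plot[0] * plot[1]  # 3782
        counts = np.array([simulate_poisson_pattern(lam, plot, seed=s).n_flowers
                           for s in range(200)])
        # sample mean within 3 SD of the Poisson mean
        assert abs(counts.mean() - mean) < 3 * np.sqrt(mean / 200)
        # mean and variance agree within Monte-Carlo error (var of s² ~ 2m²/n)
        assert abs(counts.var(ddof=1) - mean) < 4 * mean * np.sqrt(2 / 200)

    def test_determinism(self):
        a = simulate_poisson_pattern(1.0, (1.0, 1.0), seed=7)
        b = simulate_poisson_pattern(1.0, (1.0, 1.0), seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_coords_inside_plot(self):
        p = simulate_poisson_pattern(50.0, (2.0, 3.0), seed=0)
        assert p.coords[:, 0].min() >= 0 and p.coords[:, 0].max() <= 2.0
        assert p.coords[:, 1].min() >= 0 and p.coords[:, 1].max() <= 3.0

    def test_input_validation(self):
        with pytest.raises(InputError):
            simulate_poisson_pattern(-1.0, seed=0)
        with pytest.raises(InputError):
            simulate_poisson_pattern(1.0, (0.0, 1.0), seed=0)


class TestThomasPattern:
    def test_zero_offspring_empty(self):
        assert simulate_thomas_pattern(2.0, 0.0, 0.1, seed=1).n_flowers == 0

    def test_true_density_recorded_before_edge_loss(self):
        p = simulate_thomas_pattern(2.0, 50.0, 0.1, seed=1)
        assert p.true_density == pytest.approx(100.0)

    def test_large_scatter_approaches_csr(self):
        """Huge cluster scatter washes clustering out: nearest-neighbour
        distances match the CSR expectation 1/(2·sqrt(λ))."""
        from scipy.spatial import cKDTree
        nn, lam_hat = [], []
        for s in range(40):
            p = simulate_thomas_pattern(30.0, 100.0, 15.0, seed=s)
            d, _ = cKDTree(p.coords).query(p.coords, k=2)
            nn.append(d[:, 1].mean())
            lam_hat.append(p.realized_density)
        expect = 1.0 / (2.0 * np.sqrt(np.mean(lam_hat)))
        assert np.mean(nn) == pytest.approx(expect, rel=0.05)

    def test_tight_clumps_overdispersed(self):
        """Quadrat-count variance/mean ratio exceeds 1 for tight clusters."""
        vmrs = []
        for s in range(20):
            p = simulate_thomas_pattern(0.5, 20.0, 0.05, seed=s)
            counts, _, _ = np.histogram2d(p.coords[:, 0], p.coords[:, 1],
                                          bins=[6, 24], range=[[0, 3.1], [0, 12.2]])
            vmrs.append(counts.var() / counts.mean())
        assert np.mean(vmrs) > 1.5

    def test_determinism(self):
        a = simulate_thomas_pattern(1.0, 10.0, 0.1, seed=3)
        b = simulate_thomas_pattern(1.0, 10.0, 0.1, seed=3)
        assert np.array_equal(a.coords, b.coords)


class TestTransectSampling:
    def test_empty_pattern_all_censored(self):
        p = FlowerPattern(3.1, 12.2, np.empty((0, 2)))
        s = sample_transects(p, seed=0)
        assert s.n_points == 18
        assert s.point_censored.all() and s.neighbor_censored.all()

    def test_single_flower_found_neighbor_censored(self):
        # tiny plot: the single point must land within the field limit
        p = FlowerPattern(0.01, 0.01, np.array([[0.005, 0.005]]))
        s = sample_transects(p, n_transects=1, points_per_transect=1, seed=0)
        assert not s.point_censored[0]
        assert s.point_distances[0] <= np.hypot(0.01, 0.01)
        assert s.neighbor_censored[0]

    def test_dense_pattern_rarely_censored(self):
        # P(no flower within 0.15) = exp(-500*pi*0.15^2) ≈ 2e-16
        p = simulate_poisson_pattern(500.0, seed=2)
        s = sample_transects(p, n_transects=12, seed=2)
        assert s.point_censored.mean() < 0.05

    def test_censoring_probability_matches_csr(self):
        """Censoring frequency equals exp(−λπr²) within binomial error."""
        lam, r = 30.0, 0.05
        p_cens = np.exp(-lam * np.pi * r * r)  # ≈ 0.79
        flags = []
        for s in range(40):
            pat = simulate_poisson_pattern(lam, seed=s)
            samp = sample_transects(pat, n_transects=12, field_limit=r, seed=s)
            flags.append(samp.point_censored)
        frac = np.concatenate(flags).mean()
        n = len(flags) * flags[0].size
        assert abs(frac - p_cens) < 4 * np.sqrt(p_cens * (1 - p_cens) / n)

    def test_transect_must_fit_in_plot(self):
        p = FlowerPattern(1.0, 1.0, np.empty((0, 2)))
        with pytest.raises(LayoutError):
            sample_transects(p, points_per_transect=6, point_spacing=0.30, seed=0)

    def test_determinism(self):
        p = simulate_poisson_pattern(100.0, seed=5)
        a = sample_transects(p, seed=8)
        b = sample_transects(p, seed=8)
        assert np.array_equal(a.point_distances, b.point_distances, equal_nan=True)


class TestPhenologySimulator:
    def test_noise_free_peak_is_exact(self):
        params = PhenologyParams(peak_cover=40.0, peak_day_offset=17.0,
                                 anthesis_duration=55.0, noise_cv=0.0)
        series = simulate_phenology(params, sampling_interval=1.0, seed=0)
        k = int(np.argmax(series.cover))
        assert series.cover[k] == pytest.approx(40.0)
        assert series.days[k] - series.days[0] == pytest.approx(17.0)

    def test_series_spans_anthesis_duration(self):
        params = PhenologyParams(anthesis_duration=55.0)
        series = simulate_phenology(params, sampling_interval=3.0, seed=1)
        assert series.days[-1] - series.days[0] == pytest.approx(55.0)

    def test_honeybee_share_recovered_under_noise(self):
        params = PhenologyParams(honeybee_share=0.5, noise_cv=0.15)
        series = simulate_phenology(params, seed=4)
        effort = params.observers * params.minutes
        counts = series.visitation.to_numpy() * effort
        total = counts.sum()
        frac = counts[:, 0].sum() / total
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_noise_free_category_split_exact(self):
        params = PhenologyParams(honeybee_share=0.42, noise_cv=0.0)
        series = simulate_phenology(params, seed=0)
        rates = series.visitation.to_numpy()
        total = rates.sum(axis=1)
        np.testing.assert_allclose(rates[total > 0, 0] / total[total > 0], 0.42)

    def test_honeybee_rate_bounded_by_half_of_peak(self):
        # with 70 insects/min at peak and a 50% share, honey bees stay <= 35
        params = PhenologyParams(peak_visitation=70.0, honeybee_share=0.5, noise_cv=0.0)
        series = simulate_phenology(params, seed=0)
        assert series.visitation["honey_bee"].max() <= 35.0 + 1e-12

    def test_bloom_curve_unimodal_zero_at_ends(self):
        params = PhenologyParams()
        t = np.linspace(0, params.anthesis_duration, 200)
        y = bloom_curve(params, t)
        assert y[0] == 0.0 and y[-1] == 0.0
        assert bloom_curve(params, params.peak_day_offset) == pytest.approx(1.0)
        assert y.max() <= 1.0
        k = int(np.argmax(y))
        assert np.all(np.diff(y[:k]) >= 0) and np.all(np.diff(y[k:]) <= 0)

    def test_determinism(self):
        params = PhenologyParams()
        a = simulate_phenology(params, seed=12)
        b = simulate_phenology(params, seed=12)
        assert np.array_equal(a.cover, b.cover)
        assert a.visitation.equals(b.visitation)


class TestNectarSimulator:
    def test_noise_free_means_recovered(self):
        rec = simulate_nectar_records(n_flowers=10, noise_cv=0.0, seed=0)
        means = interval_means(rec)
        np.testing.assert_allclose(means.to_numpy(), [180.0, 280.0, 175.0], rtol=1e-12)
        assert daily_flower_sucrose(means.to_numpy()) == pytest.approx(635.0, rel=1e-12)

    def test_zero_brix_zero_sucrose(self):
        rec = simulate_nectar_records(n_flowers=5, brix_mean=0.0, noise_cv=0.0, seed=0)
        means = interval_means(rec)
        np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-15)

    def test_schema_columns_and_ranges(self):
        rec = simulate_nectar_records(seed=3)
        assert set(rec.columns) >= {"flower_id", "date", "interval",
                                    "capillary_volume_ul", "capillary_length_mm",
                                    "column_length_mm", "brix"}
        assert (rec["column_length_mm"] <= rec["capillary_length_mm"]).all()
        assert rec["capillary_volume_ul"].isin([1.0, 5.0, 10.0]).all()

    def test_determinism(self):
        a = simulate_nectar_records(seed=6)
        b = simulate_nectar_records(seed=6)
        pd.testing.assert_frame_equal(a, b)
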