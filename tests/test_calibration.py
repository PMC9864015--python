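"""Exponential fits, conversion coefficient, thresholds, fractions, yields."""

import numpy as np
import pytest

import focitrack as ft
from focitrack.calibration import REFERENCE_COEFFICIENT_UM2
from focitrack.errors import ConfigError, DataError, NumericalError
from focitrack.histogram import Histogram1D


def _exact_exponential_hist(rate=1.0, width=0.05, n_bins=200):
    """Histogram whose frequencies are the exact bin masses of Exp(rate)."""
    edges = np.arange(0, (n_bins + 1) * width, width)
    mass = np.exp(-rate * edges[:-1]) - np.exp(-rate * edges[1:])
    return Histogram1D(bin_edges=edges, frequencies=mass / mass.sum())


class TestFitExponential:
    def test_exact_exponential_recovers_unit_rate(self):
        fit = ft.fit_exponential(_exact_exponential_hist(rate=1.0))
        assert fit.rate == pytest.approx(1.0, rel=0.02)
        assert fit.r_squared > 0.999

    def test_flat_histogram_flags_poor_fit(self):
        edges = np.linspace(0, 1, 11)
        hist = Histogram1D(bin_edges=edges, frequencies=np.full(10, 0.1))
        fit = ft.fit_exponential(hist)
        assert fit.rate < 0.05
        assert fit.r_squared < 0.5

    def test_axis_scaling_divides_rate(self):
        h1 = _exact_exponential_hist(rate=2.0, width=0.05)
        s = 4.0
        h2 = Histogram1D(bin_edges=h1.bin_edges * s, frequencies=h1.frequencies)
        r1 = ft.fit_exponential(h1).rate
        r2 = ft.fit_exponential(h2).rate
        assert r2 == pytest.approx(r1 / s, rel=1e-6)

    def test_too_few_bins_rejected(self):
        hist = Histogram1D(
            bin_edges=np.array([0.0, 1.0, 2.0, 3.0]),
            frequencies=np.array([0.5, 0.5, 0.0]),
        )
        with pytest.raises(NumericalError):
            ft.fit_exponential(hist)


class TestFitConversionCoefficient:
    def test_identity_scaling(self):
        rng = np.random.default_rng(1)
        sizes = rng.exponential(4.0, 20_000)
        edges = np.arange(1.5, np.ceil(sizes.max()) + 1.5)
        cluster = Histogram1D.from_samples(sizes[sizes >= 1.5], bin_edges=edges)
        areas = sizes / 1.0  # identity mapping
        area_hist = Histogram1D.from_samples(areas, bin_width=0.5)
        fit = ft.fit_conversion_coefficient(area_hist, cluster)
        assert fit.coefficient == pytest.approx(1.0, rel=0.02)

    def test_area_scaling_equivariance(self):
        areas, cluster = ft.synthetic_calibration_pair(20_000, seed=3)
        h1 = Histogram1D.from_samples(areas, bin_width=0.1)
        c1 = ft.fit_conversion_coefficient(h1, cluster).coefficient
        s = 2.0
        h2 = Histogram1D.from_samples(areas * s, bin_width=0.1 * s)
        c2 = ft.fit_conversion_coefficient(h2, cluster).coefficient
        assert c2 == pytest.approx(c1 / s, rel=0.01)

    def test_recovers_generative_coefficient(self):
        areas, cluster = ft.synthetic_calibration_pair(10_000, seed=0)
        fit = ft.fit_conversion_coefficient(
            Histogram1D.from_samples(areas, bin_width=0.1), cluster
        )
        assert fit.coefficient == pytest.approx(REFERENCE_COEFFICIENT_UM2, rel=0.05)
        assert fit.sd >= 0
        assert fit.r_squared > 0.9

    def test_round_trip_recovery_50_seed_average(self):
        """Calibration round trip: |mean(c_hat) - c*| / c* < 5% over 50 seeds."""
        cs = []
        for s in range(50):
            areas, cluster = ft.synthetic_calibration_pair(10_000, seed=s)
            fit = ft.fit_conversion_coefficient(
                Histogram1D.from_samples(areas, bin_width=0.1), cluster
            )
            cs.append(fit.coefficient)
        assert abs(np.mean(cs) - REFERENCE_COEFFICIENT_UM2) / REFERENCE_COEFFICIENT_UM2 < 0.05

    def test_empty_dsb_tail_rejected(self):
        area_hist = _exact_exponential_hist()
        cluster = ft.ClusterSizeDistribution(counts={0: 10, 1: 5})
        with pytest.raises(DataError):
            ft.fit_conversion_coefficient(area_hist, cluster)


class TestThresholds:
    def test_convert_threshold_direct_division(self):
        fit = ft.ConversionFit(coefficient=14.0, sd=0.0, r_squared=1.0)
        assert ft.convert_threshold(14, fit) == pytest.approx(1.0)

    def test_convert_threshold_reference_coefficient(self):
        fit = ft.ConversionFit(coefficient=13.2, sd=0.268, r_squared=0.98)
        assert ft.convert_threshold(14, fit) == pytest.approx(14 / 13.2)
        assert ft.convert_threshold(14, fit) == pytest.approx(1.0606, abs=1e-4)

    def test_doubling_coefficient_halves_threshold(self):
        f1 = ft.ConversionFit(coefficient=10.0, sd=0.0, r_squared=1.0)
        f2 = ft.ConversionFit(coefficient=20.0, sd=0.0, r_squared=1.0)
        assert ft.convert_threshold(14, f2) == pytest.approx(
            ft.convert_threshold(14, f1) / 2
        )

    def test_threshold_below_two_rejected(self):
        fit = ft.ConversionFit(coefficient=10.0, sd=0.0, r_squared=1.0)
        with pytest.raises(ConfigError):
            ft.convert_threshold(1, fit)

    def test_determine_event_threshold_boundaries(self):
        dist = ft.ClusterSizeDistribution(counts={2: 5, 3: 3, 7: 2})
        t_all, frac_all = ft.determine_event_threshold(dist, 1.0)
        assert t_all == 2 and frac_all == 1.0
        t_none, frac_none = ft.determine_event_threshold(dist, 0.0)
        assert t_none == 8 and frac_none == 0.0

    def test_determine_event_threshold_geometric_quantile(self):
        q = 0.7
        counts = {n: int(round(1e6 * q**n)) for n in range(2, 40)}
        dist = ft.ClusterSizeDistribution(counts=counts)
        target = 0.2
        t, achieved = ft.determine_event_threshold(dist, target)
        # analytic: tail fraction ~ q^(T-2); smallest T with q^(T-2) <= 0.2
        t_analytic = 2 + int(np.ceil(np.log(target) / np.log(q)))
        assert t == t_analytic
        assert achieved <= target

    def test_threshold_consistency_between_axes(self):
        """Classifying areas at the converted threshold equals classifying the
        underlying cluster sizes at the event threshold."""
        rng = np.random.default_rng(17)
        sizes = rng.exponential(5.0, 20_000)
        areas, cluster = (
            sizes / REFERENCE_COEFFICIENT_UM2,
            None,
        )
        edges = np.arange(1.5, np.ceil(sizes.max()) + 1.5)
        cluster = Histogram1D.from_samples(sizes[sizes >= 1.5], bin_edges=edges)
        fit = ft.fit_conversion_coefficient(
            Histogram1D.from_samples(areas, bin_width=0.1), cluster
        )
        t = 14
        area_thr = ft.convert_threshold(t, fit)
        f_area = ft.classify_foci(areas, area_thr)["complex"]
        f_size = np.mean(sizes >= t * REFERENCE_COEFFICIENT_UM2 / fit.coefficient)
        assert f_area == pytest.approx(f_size, abs=1e-9)


class TestClassifyAndYields:
    def test_all_below_threshold(self):
        fr = ft.classify_foci([0.1, 0.2, 0.3], 1.0)
        assert fr == {"simple": 1.0, "complex": 0.0}

    def test_half_split(self):
        fr = ft.classify_foci([0.5, 1.5], 1.0)
        assert fr["complex"] == pytest.approx(0.5)
        assert fr["simple"] + fr["complex"] == pytest.approx(1.0, abs=1e-12)

    def test_exponential_tail_fraction(self):
        rate, thr = 3.3, 1.0
        rng = np.random.default_rng(21)
        areas = rng.exponential(1 / rate, 10_000)
        fr = ft.classify_foci(areas, thr)
        assert fr["complex"] == pytest.approx(np.exp(-rate * thr), abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            ft.classify_foci([], 1.0)

    def test_yields_direct(self):
        y = ft.estimate_yields(10.0, {"simple": 0.8, "complex": 0.2})
        assert y == {"simple": 8.0, "complex": 2.0}

    def test_zero_foci(self):
        y = ft.estimate_yields(0.0, {"simple": 0.6, "complex": 0.4})
        assert y == {"simple": 0.0, "complex": 0.0}

    def test_yields_conserve_total(self):
        fr = {"simple": 0.37, "complex": 0.63}
        y = ft.estimate_yields(12.5, fr)
        assert sum(y.values()) == pytest.approx(12.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            ft.estimate_yields(-1.0, {"simple": 1.0, "complex": 0.0})
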