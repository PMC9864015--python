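"""Cluster-size scoring, linkage counting, complexity classes, yields."""

import numpy as np
import pytest

import focitrack as ft
from focitrack.cluster_scoring import ComplexityClass
from focitrack.errors import ConfigError, DataError
from focitrack.track_sim import ElectronTrack, InelasticEvent


def _track(points):
    return ElectronTrack(
        primary_energy=1e3,
        events=[InelasticEvent(tuple(p), "ionization", 12.6) for p in points],
        e_dep=1e3,
    )


class TestScoreClusterSizes:
    def test_far_event_excluded(self):
        track = _track([(0, 0, 0), (100, 0, 0)])
        dist = ft.score_cluster_sizes(
            track, cube_side=5.03, n_cubes=1, centers=np.array([[0.0, 0.0, 0.0]])
        )
        assert dist.counts == {1: 1}

    def test_three_events_in_one_cube(self):
        track = _track([(0, 0, 0), (1, 1, 0), (-1, 0, 1)])
        dist = ft.score_cluster_sizes(
            track, cube_side=5.03, n_cubes=1, centers=np.array([[0.0, 0.0, 0.0]])
        )
        assert dist.counts == {3: 1}

    def test_counts_match_brute_force_point_in_box(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-20, 20, size=(50, 3))
        track = _track(pts)
        centers = rng.uniform(-20, 20, size=(200, 3))
        side = 5.03
        dist = ft.score_cluster_sizes(track, side, 200, centers=centers)
        # independent nested-loop oracle
        expected = {}
        for c in centers:
            o = c - side / 2
            n_in = sum(
                1
                for p in pts
                if all(o[k] <= p[k] < o[k] + side for k in range(3))
            )
            expected[n_in] = expected.get(n_in, 0) + 1
        assert dist.counts == expected

    def test_frequencies_sum_to_n_cubes(self, track_10kev):
        dist = ft.score_cluster_sizes(track_10kev, n_cubes=500, seed=1)
        assert sum(dist.counts.values()) == 500

    def test_empty_track_flagged(self):
        empty = ElectronTrack(primary_energy=0.5, events=[], e_dep=0.5)
        dist = ft.score_cluster_sizes(empty, n_cubes=10, seed=0)
        assert dist.empty_track
        assert dist.counts == {}

    def test_half_open_upper_face_excluded(self):
        # event exactly on the upper face of the cube is outside
        side = 4.0
        track = _track([(side / 2, 0, 0), (0, 0, 0)])
        dist = ft.score_cluster_sizes(
            track, side, 1, centers=np.array([[0.0, 0.0, 0.0]])
        )
        assert dist.counts == {1: 1}

    def test_rigid_motion_invariance_statistical(self, track_10kev):
        """Rotating + translating the track leaves the cluster-size law
        unchanged (statistical comparison at n_cubes = 10^4)."""
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = ElectronTrack(
            primary_energy=track_10kev.primary_energy,
            events=[
                InelasticEvent(
                    tuple(rot @ np.array(e.position) + np.array([50.0, -30.0, 10.0])),
                    e.kind,
                    e.energy_deposit,
                )
                for e in track_10kev.events
            ],
            e_dep=track_10kev.e_dep,
        )
        d1 = ft.score_cluster_sizes(track_10kev, n_cubes=10_000, seed=5)
        d2 = ft.score_cluster_sizes(moved, n_cubes=10_000, seed=5)
        p1 = d1.relative()
        p2 = d2.relative()
        sizes = set(p1) | set(p2)
        tv = 0.5 * sum(abs(p1.get(s, 0) - p2.get(s, 0)) for s in sizes)
        assert tv < 0.05
        m1 = sum(s * f for s, f in p1.items())
        m2 = sum(s * f for s, f in p2.items())
        assert m2 == pytest.approx(m1, rel=0.05)


class TestCountLinkages:
    def test_pair_within_radius(self):
        ev = [InelasticEvent(p, "ionization", 10.0) for p in [(0, 0, 0), (1, 0, 0)]]
        assert ft.count_linkages(ev, 3.4) == 1

    def test_three_mutual_pairs(self):
        ev = [
            InelasticEvent(p, "excitation", 10.0)
            for p in [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        ]
        assert ft.count_linkages(ev, 3.4) == 3

    def test_single_or_empty(self):
        assert ft.count_linkages([], 3.4) == 0
        assert ft.count_linkages([InelasticEvent((0, 0, 0), "ionization", 5.0)]) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 20, size=(500, 3))
        fast = ft.count_linkages(pts, 3.4)
        brute = sum(
            np.linalg.norm(pts[i] - pts[j]) <= 3.4
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        )
        assert fast == brute

    def test_bad_radius(self):
        with pytest.raises(ConfigError):
            ft.count_linkages([], 0.0)


class TestClassifySite:
    def test_partition_is_exhaustive_and_matches_boundaries(self):
        def reference(n):
            if n < 2:
                return ComplexityClass.NO_DSB
            if n < 14:
                return ComplexityClass.SIMPLE
            if n < 26:
                return ComplexityClass.DSB_PLUS
            if n < 38:
                return ComplexityClass.DSB_PLUS_PLUS
            return ComplexityClass.HIGHER

        for n in range(0, 51):
            assert ft.classify_site(n) is reference(n)

    def test_boundary_examples(self):
        assert ft.classify_site(1) is ComplexityClass.NO_DSB
        assert ft.classify_site(13) is ComplexityClass.SIMPLE
        assert ft.classify_site(14) is ComplexityClass.DSB_PLUS
        assert ft.classify_site(26) is ComplexityClass.DSB_PLUS_PLUS
        assert ft.classify_site(38) is ComplexityClass.HIGHER

    def test_negative_rejected(self):
        with pytest.raises(ConfigError):
            ft.classify_site(-1)


class TestComplexityFractions:
    def test_all_simple(self):
        dist = ft.ClusterSizeDistribution(counts={5: 10})
        fr = ft.complexity_fractions(dist)
        assert fr[ComplexityClass.SIMPLE] == 1.0
        assert ft.complex_fraction(dist) == 0.0

    def test_direct_ratio(self):
        dist = ft.ClusterSizeDistribution(counts={2: 3, 14: 1})
        fr = ft.complexity_fractions(dist)
        assert fr[ComplexityClass.SIMPLE] == pytest.approx(0.75)
        assert fr[ComplexityClass.DSB_PLUS] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self, track_10kev):
        dist = ft.score_cluster_sizes(track_10kev, n_cubes=2000, seed=9)
        fr = ft.complexity_fractions(dist)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_geometric_law_matches_analytic_tail_masses(self):
        # counts proportional to q^n for n = 2..60: class masses are
        # geometric partial sums, known in closed form
        q = 0.8
        counts = {n: int(round(1e6 * q**n)) for n in range(2, 61)}
        dist = ft.ClusterSizeDistribution(counts=counts)
        fr = ft.complexity_fractions(dist)

        def tail(lo, hi):
            return sum(counts.get(n, 0) for n in range(lo, hi))

        total = tail(2, 61)
        assert fr[ComplexityClass.SIMPLE] == pytest.approx(tail(2, 14) / total)
        assert fr[ComplexityClass.DSB_PLUS] == pytest.approx(tail(14, 26) / total)
        assert fr[ComplexityClass.DSB_PLUS_PLUS] == pytest.approx(tail(26, 38) / total)

    def test_no_dsb_bearing_cubes(self):
        dist = ft.ClusterSizeDistribution(counts={0: 5, 1: 5})
        assert ft.complexity_fractions(dist) == {}
        with pytest.raises(DataError):
            ft.complex_fraction(dist)


class TestDsbYield:
    def test_zero_linkages(self):
        assert ft.dsb_yield(0, 1e3).y_dsb == 0.0

    def test_direct_substitution(self):
        # k=2, N_link=6, E_dep=3 keV -> Y = 2*6/3 = 4
        assert ft.dsb_yield(6, 3e3, k_dsb=2.0).y_dsb == pytest.approx(4.0)

    def test_linearity_and_homogeneity(self):
        y1 = ft.dsb_yield(10, 5e3).y_dsb
        assert ft.dsb_yield(20, 5e3).y_dsb == pytest.approx(2 * y1)
        assert ft.dsb_yield(30, 15e3).y_dsb == pytest.approx(ft.dsb_yield(10, 5e3).y_dsb)

    def test_non_positive_edep_rejected(self):
        with pytest.raises(ConfigError):
            ft.dsb_yield(1, 0.0)


class TestSpectrumAverage:
    def test_constant_value(self):
        spec = ft.ElectronSpectrum.from_arrays([10, 20, 30], [1, 2, 1])
        assert ft.spectrum_average({10: 7.0, 30: 7.0}, spec) == pytest.approx(7.0)

    def test_delta_spectrum(self):
        spec = ft.ElectronSpectrum.from_arrays([15.0], [1.0])
        assert ft.spectrum_average({10: 1.0, 20: 3.0}, spec) == pytest.approx(2.0)

    def test_linear_value_on_uniform_grid_exact(self):
        # f uniform on [0, 2], Y = a + b E: integral = a + b
        spec = ft.ElectronSpectrum.from_arrays([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        values = {0.0: 1.0, 1.0: 3.0, 2.0: 5.0}  # Y = 1 + 2E
        assert ft.spectrum_average(values, spec) == pytest.approx(3.0, abs=1e-12)

    def test_disjoint_support_rejected(self):
        spec = ft.ElectronSpectrum.from_arrays([100.0, 200.0], [1.0, 1.0])
        with pytest.raises(ConfigError):
            ft.spectrum_average({1.0: 5.0, 2.0: 6.0}, spec)
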