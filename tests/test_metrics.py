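"""Comparison statistics: profiles, R factors, FSC, orientation
probabilities, consensus and eccentricity."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from spisort.containers import IntensityVolume, LabelSet
from spisort.metrics import (
    ProbabilityMatrix,
    consensus,
    eccentricity_analysis,
    fibonacci_sphere,
    fsc,
    make_orientation_grid,
    orientation_probabilities,
    orientation_sphere_map,
    pmax_stats,
    r_factor,
    radial_profile,
)
from spisort.preprocess import adu_to_photons
from spisort.simdata import DetectorGeometry, render_single_hit


class TestRadialProfile:
    def test_constant_intensity_gives_constant_profile(self, geometry):
        curve = radial_profile(np.full((64, 64), 3.0), geometry, n_bins=10)
        vals = curve.values[curve.counts > 0]
        assert np.allclose(vals, 3.0)

    def test_masked_pixels_excluded_and_empty_shells_nan(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[28:36, 28:36] = True  # kill the central shells
        geom = DetectorGeometry(mask=mask)
        data = np.ones((64, 64))
        curve = radial_profile(data, geom, n_bins=40)
        assert np.isnan(curve.values[0])
        assert curve.counts[0] == 0

    def test_volume_profile_uses_calibration(self, ground_truth_volume):
        curve = radial_profile(ground_truth_volume, n_bins=20)
        r_max = (ground_truth_volume.shape[0] // 2 + 1)
        assert curve.q_edges[-1] <= r_max * ground_truth_volume.q_calibration * 1.8


class TestRFactor:
    def test_identical_volumes_zero_everywhere(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0.5, 2.0, (16, 16, 16))
        overall, curve = r_factor(vol, vol)
        assert overall == 0.0
        assert np.allclose(curve.values[curve.counts > 0], 0.0)

    def test_doubled_intensity_closed_form(self):
        # amplitudes scale by sqrt(2): R = 2 (sqrt2 - 1) / (sqrt2 + 1)
        rng = np.random.default_rng(1)
        vol = rng.uniform(0.5, 2.0, (16, 16, 16))
        overall, curve = r_factor(vol, 2.0 * vol)
        expected = 2.0 * (math.sqrt(2) - 1) / (math.sqrt(2) + 1)
        assert overall == pytest.approx(expected, rel=1e-12)
        assert np.allclose(curve.values[curve.counts > 0], expected)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 2, (12, 12, 12))
        b = rng.uniform(0, 2, (12, 12, 12))
        assert r_factor(a, b)[0] == pytest.approx(r_factor(b, a)[0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            r_factor(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)))


class TestFSC:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(16, 16, 16))
        curve, _ = fsc(a, a)
        assert np.allclose(curve.values[curve.counts > 0], 1.0)

    def test_negated_map_gives_minus_one(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(16, 16, 16))
        curve, _ = fsc(a, -a)
        assert np.allclose(curve.values[curve.counts > 0], -1.0)

    def test_independent_noise_within_null_band(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        curve, _ = fsc(a, b, n_shells=12)
        thr = 3.0 / np.sqrt(np.maximum(curve.counts, 1))
        ok = np.abs(curve.values[curve.counts > 0]) < thr[curve.counts > 0]
        assert ok.mean() >= 0.95

    def test_resolution_crossing_reported(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(16, 16, 16))
        smooth = gaussian_filter(a, 2.0)
        noisy = smooth + 0.5 * rng.normal(size=a.shape)
        curve, res = fsc(smooth, noisy, n_shells=8)
        if res is not None:
            q = 1.0 / res
            assert curve.q_edges[0] <= q <= curve.q_edges[-1]


@pytest.fixture(scope="module")
def prob_matrix(ground_truth_volume, geometry):
    grid = make_orientation_grid(30, 4)
    rng = np.random.default_rng(2)
    true_j = [5, 41, 77]
    patterns = []
    for j in true_j:
        fr = render_single_hit(ground_truth_volume, grid[j], geometry,
                               50000.0, rng)
        patterns.append(adu_to_photons(fr, geometry.gain))
    return (orientation_probabilities(patterns, ground_truth_volume,
                                      grid, geometry), grid, true_j)


class TestOrientationProbabilities:
    def test_rows_sum_to_one(self, prob_matrix):
        mat, _, _ = prob_matrix
        assert np.allclose(mat.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_rendered_pattern_recovers_its_orientation(self, prob_matrix):
        # a Friedel partner can split the mass, so the true orientation
        # carries at least (nearly) half of it
        mat, _, true_j = prob_matrix
        for row, j in zip(mat.probabilities, true_j):
            assert row[j] >= 0.45
            assert row.argmax() == j or row[row.argmax()] <= row[j] + 1e-9

    def test_single_orientation_grid_certain(self, ground_truth_volume, geometry):
        grid = make_orientation_grid(1, 1)
        rng = np.random.default_rng(3)
        fr = render_single_hit(ground_truth_volume, grid[0], geometry,
                               10000.0, rng)
        mat = orientation_probabilities([adu_to_photons(fr, geometry.gain)],
                                        ground_truth_volume, grid, geometry)
        assert mat.probabilities[0, 0] == pytest.approx(1.0)


class TestPmaxStats:
    def test_one_hot_rows_have_no_uncertain_patterns(self):
        probs = np.eye(4)
        grid = np.tile([1.0, 0, 0, 0], (4, 1))
        mat = ProbabilityMatrix(probabilities=probs, orientation_grid=grid)
        stats = pmax_stats(mat, low_cutoff=0.5)
        assert stats["fraction_uncertain"] == 0.0

    def test_uniform_rows_all_uncertain(self):
        n = 100_000
        probs = np.full((2, n), 1.0 / n)
        grid = np.tile([1.0, 0, 0, 0], (n, 1))
        mat = ProbabilityMatrix(probabilities=probs, orientation_grid=grid)
        stats = pmax_stats(mat, low_cutoff=1e-4)
        assert stats["fraction_uncertain"] == 1.0
        assert stats["baseline"] == pytest.approx(1e-5)

    def test_baseline_is_reciprocal_orientation_count(self):
        probs = np.full((1, 400), 1.0 / 400)
        grid = np.tile([1.0, 0, 0, 0], (400, 1))
        stats = pmax_stats(ProbabilityMatrix(probabilities=probs,
                                             orientation_grid=grid))
        assert stats["baseline"] == 1.0 / 400


class TestOrientationSphereMap:
    def test_shared_orientation_gives_single_point(self):
        grid = make_orientation_grid(20, 1)
        probs = np.zeros((5, 20))
        probs[:, 7] = 1.0
        mat = ProbabilityMatrix(probabilities=probs, orientation_grid=grid)
        pts, weights = orientation_sphere_map(mat, top_n=1)
        assert np.count_nonzero(weights) == 1
        assert weights.max() == pytest.approx(5.0)

    def test_total_weight_bounded_by_pattern_count(self):
        rng = np.random.default_rng(7)
        grid = make_orientation_grid(15, 2)
        raw = rng.uniform(size=(6, 30))
        probs = raw / raw.sum(axis=1, keepdims=True)
        mat = ProbabilityMatrix(probabilities=probs, orientation_grid=grid)
        _, weights = orientation_sphere_map(mat, top_n=10)
        assert weights.sum() <= 6.0 + 1e-9

    def test_inplane_angles_collapse_to_same_axis(self):
        grid = make_orientation_grid(10, 4)
        probs = np.full((1, 40), 1.0 / 40)
        mat = ProbabilityMatrix(probabilities=probs, orientation_grid=grid)
        pts, _ = orientation_sphere_map(mat, top_n=40)
        assert len(pts) == 10  # in-plane rotation discarded


class TestConsensus:
    @staticmethod
    def _label_set(positives, universe):
        ids = np.array([str(i) for i in universe], dtype=object)
        scores = np.array([1.0 if i in positives else 0.0 for i in universe])
        return LabelSet(ids=ids, scores=scores)

    def test_identical_sets(self):
        u = range(6)
        a = self._label_set({0, 1, 2}, u)
        counts, common = consensus([a, self._label_set({0, 1, 2}, u)])
        assert counts["A_B"] == 3
        assert counts["A"] == counts["B"] == 0
        assert len(common) == 3

    def test_disjoint_sets_empty_triple(self):
        u = range(9)
        sets = [self._label_set({0, 1}, u), self._label_set({3, 4}, u),
                self._label_set({6, 7}, u)]
        counts, common = consensus(sets)
        assert counts["A_B_C"] == 0
        assert len(common) == 0

    def test_hand_worked_triple_example(self):
        u = range(1, 7)
        sets = [self._label_set({1, 2, 3}, u), self._label_set({2, 3, 4}, u),
                self._label_set({3, 4, 5}, u)]
        counts, common = consensus(sets)
        assert len(counts) == 7
        assert list(common.ids) == ["3"]
        # full pairwise intersections recovered from exclusive regions
        assert counts["A_B"] + counts["A_B_C"] == 2
        assert counts["A_C"] + counts["A_B_C"] == 1
        assert counts["B_C"] + counts["A_B_C"] == 2
        assert counts["A_B_C"] == 1

    def test_triple_bounded_by_pairwise(self):
        rng = np.random.default_rng(8)
        u = range(30)
        sets = [self._label_set(set(rng.choice(30, 12, replace=False)), u)
                for _ in range(3)]
        counts, _ = consensus(sets)
        triple = counts["A_B_C"]
        assert triple <= counts["A_B"] + triple
        assert triple <= counts["A_C"] + triple
        assert triple <= counts["B_C"] + triple

    def test_mismatched_universe_rejected(self):
        a = self._label_set({0}, range(4))
        b = self._label_set({0}, range(5))
        with pytest.raises(ValueError, match="different patterns"):
            consensus([a, b])


class TestEccentricity:
    def test_smoothed_ball_is_nearly_circular(self):
        n = 96
        ax = np.arange(n) - n // 2
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = gaussian_filter(
            ((zz ** 2 + yy ** 2 + xx ** 2) <= 40 ** 2).astype(float), 1.5)
        result = eccentricity_analysis(ball, n_planes=60)
        assert result["mean"] < 0.05

    def test_two_to_one_ellipsoid_long_axis_sections(self):
        n = 64
        ax = np.arange(n) - n // 2
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        ell = ((zz / 28.0) ** 2 + (yy / 14.0) ** 2 + (xx / 14.0) ** 2 <= 1.0)
        result = eccentricity_analysis(ell.astype(float), n_planes=100)
        # e = c/a = sqrt(1 - 1/4) for a 2:1 section
        assert 0.8 <= result["max"] <= 0.9

    def test_empty_map_yields_no_fits(self):
        result = eccentricity_analysis(np.zeros((16, 16, 16)), n_planes=10)
        assert len(result["eccentricities"]) == 0
        assert math.isnan(result["mean"])


class TestFibonacciSphere:
    def test_unit_vectors(self):
        pts = fibonacci_sphere(64)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_nearest_neighbour_spacing_near_uniform(self):
        n = 100
        pts = fibonacci_sphere(n)
        d, _ = cKDTree(pts).query(pts, k=2)
        angles = 2.0 * np.arcsin(d[:, 1] / 2.0)
        expected = math.sqrt(4.0 * math.pi / n)
        ratio = angles / expected
        assert ratio.min() >= 0.7
        assert ratio.max() <= 1.3
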