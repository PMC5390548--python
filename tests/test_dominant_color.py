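"""Dominant-color clustering: seeding, Lloyd refinement, split/merge."""

import itertools

import numpy as np
import pytest

from tonguecbir.colorspace import rgb_to_hsv
from tonguecbir.dominant_color import (
    GlaParams,
    MainColorDescriptor,
    _lloyd,
    _to_unit,
    area_probabilities,
    assign_pixels,
    dcd_distance,
    extract_main_colors,
    initial_palette,
    merge_clusters,
    split_clusters,
    summarize_clusters,
    traditional_main_colors,
    update_centers,
)
from tonguecbir.fixtures import PhantomSpec, make_phantom

from conftest import solid_rgb


def hsv_image(pixels):
    """Wrap a pixel list into a 1xN HSV raster."""
    return np.asarray(pixels, dtype=float).reshape(1, -1, 3)


class TestAreaProbabilities:
    def test_solid_red(self):
        img = hsv_image([(0.0, 0.8, 0.8)] * 4)
        p = area_probabilities(img)
        assert p[3] == 1.0 and p.sum() == 1.0

    def test_mixed_counts(self):
        # areas {black, black, red, green} -> (0.5, 0, 0, 0.25, 0, 0.25, ...)
        img = hsv_image(
            [(0.0, 0.0, 0.1), (0.0, 0.0, 0.1), (0.0, 0.5, 0.5), (90.0, 0.8, 0.6)]
        )
        np.testing.assert_allclose(
            area_probabilities(img), [0.5, 0, 0, 0.25, 0, 0.25, 0, 0, 0]
        )

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            area_probabilities(np.empty((0, 0, 3)))


class TestInitialPalette:
    def test_solid_image_single_center(self):
        img = hsv_image([(120.0, 0.8, 0.8)] * 10)
        k, centers = initial_palette(img)
        assert k == 1
        np.testing.assert_allclose(centers[0], (120.0, 0.8, 0.8), atol=1e-9)

    def test_two_areas_above_threshold(self):
        img = hsv_image([(120.0, 0.8, 0.8)] * 6 + [(220.0, 0.8, 0.8)] * 4)
        k, _ = initial_palette(img)
        assert k == 2

    def test_fifteen_percent_rule(self):
        # area fractions (0.5 black, 0.3 gray, 0.1 white, 0.1 red): k = 2
        pixels = (
            [(0.0, 0.0, 0.1)] * 5
            + [(0.0, 0.05, 0.5)] * 3
            + [(0.0, 0.05, 0.95)] * 1
            + [(10.0, 0.5, 0.5)] * 1
        )
        k, _ = initial_palette(hsv_image(pixels))
        assert k == 2

    def test_fallback_when_nothing_exceeds_threshold(self):
        img = hsv_image([(120.0, 0.8, 0.8)] * 10)
        k, _ = initial_palette(img, GlaParams(area_threshold=0.999999))
        assert k == 1


class TestAssignUpdate:
    def test_pixel_at_center_gets_its_label(self):
        centers = [(10.0, 0.5, 0.5), (200.0, 0.5, 0.5)]
        labels = assign_pixels(hsv_image([(200.0, 0.5, 0.5)]), centers)
        assert labels.reshape(-1)[0] == 1

    def test_hue_distance_is_circular(self):
        centers = [(10.0, 0.5, 0.5), (180.0, 0.5, 0.5)]
        labels = assign_pixels(hsv_image([(350.0, 0.5, 0.5)]), centers)
        assert labels.reshape(-1)[0] == 0  # 20 degrees away, not 170

    def test_single_center_labels_all_zero(self):
        labels = assign_pixels(
            hsv_image([(0.0, 0.1, 0.1), (120.0, 0.9, 0.9)]), [(60.0, 0.5, 0.5)]
        )
        assert np.all(labels == 0)

    def test_update_identical_pixels(self):
        img = hsv_image([(45.0, 0.3, 0.7)] * 5)
        centers = update_centers(img, np.zeros(5, dtype=int))
        np.testing.assert_allclose(centers[0], (45.0, 0.3, 0.7), atol=1e-9)

    def test_update_saturation_mean(self):
        img = hsv_image([(45.0, 0.2, 0.7), (45.0, 0.4, 0.7)])
        centers = update_centers(img, np.zeros(2, dtype=int))
        assert centers[0, 1] == pytest.approx(0.3)

    def test_update_circular_hue_mean(self):
        img = hsv_image([(350.0, 0.5, 0.5), (10.0, 0.5, 0.5)])
        centers = update_centers(img, np.zeros(2, dtype=int))
        assert centers[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_update_drops_empty_clusters(self):
        img = hsv_image([(45.0, 0.3, 0.7)] * 3)
        centers = update_centers(img, np.array([2, 2, 2]))
        assert centers.shape == (1, 3)


class TestSplitMerge:
    def test_tight_cluster_not_split(self):
        img = hsv_image([(120.0, 0.8, 0.8)] * 8)
        labels = np.zeros(8, dtype=int)
        out = split_clusters(img, labels, [(120.0, 0.8, 0.8)], split_threshold=0.01)
        assert out.shape == (1, 3)

    def test_two_planted_colors_recovered_after_split(self):
        # one cluster holding two well-separated colors: split + Lloyd
        # converges onto the planted pair
        pix = [(40.0, 0.8, 0.8)] * 6 + [(200.0, 0.8, 0.8)] * 6
        img = hsv_image(pix)
        center = update_centers(img, np.zeros(12, dtype=int))
        labels = assign_pixels(img, center)
        grown = split_clusters(img, labels, center, split_threshold=0.01)
        assert grown.shape == (2, 3)
        params = GlaParams()
        final, _, _, _ = _lloyd(
            _to_unit(img.reshape(-1, 3)), _to_unit(grown), params
        )
        hues = sorted((final[:, 0] % 1.0) * 360.0)
        np.testing.assert_allclose(hues, [40.0, 200.0], atol=1e-6)

    def test_merge_identical_centers_pools_counts(self):
        centers, counts = merge_clusters(
            [(120.0, 0.5, 0.5), (120.0, 0.5, 0.5)], [30, 10], merge_threshold=0.1
        )
        assert len(counts) == 1 and counts[0] == 40
        np.testing.assert_allclose(centers[0], (120.0, 0.5, 0.5), atol=1e-9)

    def test_merge_leaves_distant_centers(self):
        centers, counts = merge_clusters(
            [(0.0, 0.8, 0.8), (180.0, 0.8, 0.8)], [5, 5], merge_threshold=0.1
        )
        assert len(counts) == 2

    def test_merge_count_weighted_mean(self):
        centers, _ = merge_clusters(
            [(45.0, 0.2, 0.5), (45.0, 0.6, 0.5)], [10, 30], merge_threshold=1.0
        )
        assert centers[0, 1] == pytest.approx(0.5)  # (10*0.2 + 30*0.6)/40

    def test_summaries_report_counts_and_errors(self):
        img = hsv_image([(120.0, 0.8, 0.8)] * 4)
        clusters = summarize_clusters(img, np.zeros(4, dtype=int), [(120.0, 0.8, 0.8)])
        assert clusters[0].pixel_count == 4
        assert clusters[0].within_error == pytest.approx(0.0, abs=1e-12)


class TestExtractMainColors:
    def test_solid_image(self):
        desc = extract_main_colors(solid_rgb(120.0, 0.8, 0.8))
        assert desc.k == 1
        assert desc.fractions[0] == 1.0
        assert abs(desc.colors[0, 0] - 120.0) < 1.0

    def test_three_planted_colors_recovered(self):
        spec = PhantomSpec(
            palette=(
                ((0.0, 0.8, 0.8), 0.5),
                ((120.0, 0.8, 0.8), 0.3),
                ((240.0, 0.8, 0.8), 0.2),
            ),
            size=(64, 64),
            noise_sigma=2.0,
            seed=7,
        )
        desc = extract_main_colors(make_phantom(spec))
        assert desc.k == 3
        np.testing.assert_allclose(desc.fractions, [0.5, 0.3, 0.2], atol=0.02)
        hue_err = np.abs((desc.colors[:, 0] - [0.0, 120.0, 240.0] + 180) % 360 - 180)
        assert hue_err.max() < 1.0
        assert np.abs(desc.colors[:, 1:] - 0.8).max() < 0.01

    def test_colors_closer_than_merge_threshold_collapse(self):
        # hues 10 and 20 seed two clusters (red/yellow regions) whose
        # weighted distance 0.039 < T2 = 0.1, so they merge to k = 1
        spec = PhantomSpec(
            palette=(((10.0, 0.8, 0.8), 0.5), ((20.0, 0.8, 0.8), 0.5)),
            size=(32, 32),
        )
        desc = extract_main_colors(make_phantom(spec))
        assert desc.k == 1

    def test_fractions_sum_to_one(self):
        spec = PhantomSpec(
            palette=(((40.0, 0.7, 0.7), 0.6), ((260.0, 0.7, 0.7), 0.4)),
            size=(32, 32),
            noise_sigma=3.0,
            seed=3,
        )
        desc = extract_main_colors(make_phantom(spec))
        assert desc.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(desc.fractions) <= 1e-12)


def test_lloyd_objective_never_increases(rng):
    img = rng.integers(0, 256, size=(24, 24, 3))
    hsv = rgb_to_hsv(img)
    params = GlaParams()
    _, centers = initial_palette(hsv, params)
    _, _, _, objectives = _lloyd(
        _to_unit(hsv.reshape(-1, 3)), _to_unit(centers), params
    )
    diffs = np.diff(objectives)
    assert np.all(diffs <= 1e-12)


def test_lloyd_reaches_exhaustive_two_partition_optimum():
    """On a tiny planted raster the final objective equals the global
    minimum over every 2-partition (brute-force enumeration oracle)."""
    # hues kept in (0, 0.5) so plain arithmetic means are exact centroids
    pts = np.array(
        [
            [0.10, 0.8, 0.8],
            [0.11, 0.78, 0.82],
            [0.09, 0.81, 0.79],
            [0.12, 0.8, 0.8],
            [0.30, 0.5, 0.6],
            [0.31, 0.52, 0.58],
            [0.29, 0.5, 0.61],
            [0.32, 0.49, 0.6],
        ]
    )
    w = (2.0, 1.0, 1.0)

    def brute_objective(mask):
        total = 0.0
        for sel in (mask, ~mask):
            m = pts[sel]
            c = m.mean(axis=0)
            total += (np.asarray(w) * (m - c) ** 2).sum()
        return total / len(pts)

    best = min(
        brute_objective(np.array(bits, dtype=bool))
        for bits in itertools.product([0, 1], repeat=len(pts))
        if 0 < sum(bits) < len(pts)
    )
    init = np.array([[0.10, 0.8, 0.8], [0.30, 0.5, 0.6]])
    centers, labels, _, objectives = _lloyd(pts, init, GlaParams())
    assert objectives[-1] == pytest.approx(best, abs=1e-9)


def test_planted_palette_recovery_over_seeds():
    """k exact and fractions within ±0.02 across 20 seeded replicates."""
    planted = [(0.5, 10.0), (0.3, 130.0), (0.2, 250.0)]
    for seed in range(20):
        spec = PhantomSpec(
            palette=tuple(((h, 0.75, 0.75), f) for f, h in planted),
            size=(48, 48),
            noise_sigma=2.5,
            seed=seed,
        )
        desc = extract_main_colors(make_phantom(spec))
        assert desc.k == 3, f"seed {seed}: k={desc.k}"
        np.testing.assert_allclose(desc.fractions, [0.5, 0.3, 0.2], atol=0.02)


class TestTraditionalMainColors:
    def test_solid(self):
        hsv = rgb_to_hsv(solid_rgb(120.0, 0.8, 0.8))
        desc = traditional_main_colors(hsv)
        assert desc.k == 1 and desc.fractions[0] == 1.0

    def test_five_percent_cutoff(self):
        # fractions (0.9, 0.06, 0.04): only two areas retained
        pixels = (
            [(120.0, 0.8, 0.8)] * 90
            + [(220.0, 0.8, 0.8)] * 6
            + [(280.0, 0.8, 0.8)] * 4
        )
        desc = traditional_main_colors(hsv_image(pixels))
        assert desc.k == 2
        assert desc.fractions.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(desc.fractions, [0.9375, 0.0625])

    def test_all_areas_retained_when_uniformly_spread(self):
        reps = [
            (0.0, 0.0, 0.1),   # black
            (0.0, 0.05, 0.5),  # gray
            (0.0, 0.05, 0.95), # white
            (0.0, 0.5, 0.5),
            (45.0, 0.5, 0.5),
            (100.0, 0.5, 0.5),
            (170.0, 0.5, 0.5),
            (220.0, 0.5, 0.5),
            (280.0, 0.5, 0.5),
        ]
        desc = traditional_main_colors(hsv_image(reps))
        assert desc.k == 9


class TestDcdDistance:
    def make(self, hues, fracs):
        colors = np.array([[h, 0.8, 0.8] for h in hues])
        fracs = np.asarray(fracs, dtype=float)
        order = np.argsort(-fracs, kind="stable")
        return MainColorDescriptor(colors[order], fracs[order])

    def test_identity(self):
        f = self.make([120.0, 240.0], [0.6, 0.4])
        assert dcd_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_far_centers_give_sqrt_two(self):
        f1 = self.make([0.0], [1.0])
        f2 = self.make([180.0], [1.0])
        assert dcd_distance(f1, f2) == pytest.approx(np.sqrt(2.0))

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            k1, k2 = rng.integers(1, 4, size=2)
            f1 = self.make(
                rng.uniform(0, 360, k1), rng.dirichlet(np.ones(k1))
            )
            f2 = self.make(
                rng.uniform(0, 360, k2), rng.dirichlet(np.ones(k2))
            )
            d12 = dcd_distance(f1, f2)
            assert d12 >= 0.0
            assert d12 == pytest.approx(dcd_distance(f2, f1), abs=1e-12)
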