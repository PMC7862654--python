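import numpy as np
import pytest
from scipy.spatial import ConvexHull

from ibt.spatial import (block_peaks, channel_correlation_matrix,
                         delaunay_neighborhoods, euclid_hierarchical,
                         fcm_states, kmeans3d, peak_pairwise_distances,
                         peak_rate)
from ibt.stack import AcquisitionGeometry


def planted_modes_volume(seed=0, n_per_mode=400):
    rng = np.random.default_rng(seed)
    modes = (0.1, 0.5, 0.9)
    values = np.concatenate([rng.normal(m, 0.02, n_per_mode) for m in modes])
    truth = np.repeat(np.arange(3), n_per_mode)
    perm = rng.permutation(values.size)
    return values[perm].reshape(30, 40), truth[perm]


class TestFcm:
    def test_recovers_three_planted_intensity_modes(self):
        volume, truth = planted_modes_volume()
        out = fcm_states(volume, C=3)
        agreement = np.mean(out.labels.ravel() == truth)
        assert agreement >= 0.99
        assert np.allclose(out.centroids, [0.1, 0.5, 0.9], atol=0.05)
        assert out.converged

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            fcm_states(np.ones((5, 5)), C=3)

    def test_memberships_form_probability_simplex(self):
        volume, _ = planted_modes_volume(seed=2)
        out = fcm_states(volume, C=3)
        assert np.all(out.memberships >= 0)
        assert np.all(out.memberships <= 1)
        assert np.allclose(out.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_affine_rescaling_preserves_hard_labels(self):
        volume, _ = planted_modes_volume(seed=3)
        a = fcm_states(volume, C=3)
        b = fcm_states(volume * 10.0 + 3.0, C=3)
        assert np.array_equal(a.labels, b.labels)

    def test_states_ordered_by_ascending_intensity(self):
        volume, _ = planted_modes_volume(seed=4)
        out = fcm_states(volume, C=3)
        assert np.all(np.diff(out.centroids) > 0)
        assert out.state_names == ("very-low", "decondensed", "compacted")


def blob_cubes(seed=0, C=6, M=3, side=12):
    """M-channel volume with C disjoint single-channel blobs."""
    rng = np.random.default_rng(seed)
    cubes = rng.normal(0.0, 0.02, (M, 2, side, side)).clip(0)
    truth = np.zeros((2, side, side), dtype=int)
    coords = [(0, 2, 2), (0, 2, 8), (1, 2, 2), (1, 8, 2), (0, 8, 8), (1, 8, 8)]
    for k, (z, y, x) in enumerate(coords):
        ch = k % M
        cubes[ch, z, y:y + 3, x:x + 3] += 1.0 + 0.3 * k
        truth[z, y:y + 3, x:x + 3] = k + 1
    return cubes, truth


class TestKmeans:
    def test_fixed_seed_deterministic(self):
        cubes, _ = blob_cubes()
        a = kmeans3d(cubes, C=6, seed=3)
        b = kmeans3d(cubes, C=6, seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.zscore_means, b.zscore_means, equal_nan=True)

    def test_recovers_planted_blobs(self):
        from sklearn.metrics import rand_score
        cubes, truth = blob_cubes(seed=1)
        out = kmeans3d(cubes, C=7, seed=0)  # 6 blobs + background
        assert rand_score(truth.ravel(), out.labels.ravel()) >= 0.95

    def test_single_cluster_zscore_means_are_zero(self):
        cubes, _ = blob_cubes(seed=2)
        out = kmeans3d(cubes, C=1, seed=0)
        assert np.all(out.labels == 0)
        assert np.allclose(out.zscore_means, 0.0, atol=1e-9)

    def test_zscore_matrix_shape(self):
        cubes, _ = blob_cubes(seed=3, M=3)
        out = kmeans3d(cubes, C=4, seed=0)
        assert out.zscore_means.shape == (4, 3)


class TestBlockPeaks:
    def test_flat_image_no_peaks(self):
        out = block_peaks(np.ones((40, 40)), block=20)
        assert len(out.intensities) == 0
        assert out.n_blocks == 4

    def test_one_injected_spot_per_block(self):
        rng = np.random.default_rng(5)
        img = rng.random((40, 40)) * 0.1
        for by, bx in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            img[by * 20 + 10, bx * 20 + 10] = 50.0
        out = block_peaks(img, block=20)
        assert len(out.intensities) == 4
        rate = peak_rate(img, block=20)
        assert rate["mean_peaks_per_block"] == pytest.approx(1.0)

    def test_dimmer_image_yields_fewer_peaks(self):
        # halving the planted source density mirrors a drug-treated image
        def spotted(seed, n_spots):
            rng = np.random.default_rng(seed)
            img = rng.gamma(2.0, 0.05, (80, 80))
            ys, xs = rng.integers(2, 78, n_spots), rng.integers(2, 78, n_spots)
            img[ys, xs] += rng.uniform(5, 10, n_spots)
            return img

        untreated = peak_rate(spotted(11, 60), block=20)["mean_peaks_per_block"]
        treated = peak_rate(spotted(12, 30), block=20)["mean_peaks_per_block"]
        assert treated < untreated

    def test_incomplete_edge_blocks_dropped_and_counted(self):
        out = block_peaks(np.zeros((50, 45)), block=20)
        assert out.n_blocks == 4   # 2 x 2 complete blocks
        assert out.n_dropped_blocks == 5

    def test_image_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            block_peaks(np.zeros((10, 10)), block=20)


class TestPairwiseDistances:
    GEOM = AcquisitionGeometry(3.2, 3.2, 64, 64, z_step_nm=5.0)

    def make_peaks(self, positions):
        from ibt.spatial import PeakSet
        pos = np.asarray(positions, dtype=float)
        return PeakSet(positions=pos, intensities=np.ones(len(pos)),
                       block_ids=np.zeros(len(pos), dtype=int),
                       n_blocks=1, n_dropped_blocks=0)

    def test_two_peaks_four_pixels_apart(self):
        peaks = self.make_peaks([(10, 10, 0), (14, 10, 0)])
        out = peak_pairwise_distances(peaks, self.GEOM)
        assert out["n_pairs"] == 1
        assert out["distances_nm"][0] == pytest.approx(200.0)  # 4 * 50 nm

    def test_matches_exhaustive_double_loop(self, rng):
        pts = rng.uniform(0, 60, (5, 3))
        peaks = self.make_peaks(pts)
        out = peak_pairwise_distances(peaks, self.GEOM)
        scale = np.array([self.GEOM.dx_nm, self.GEOM.dy_nm,
                          self.GEOM.z_step_nm])
        oracle = sorted(
            np.sqrt((((pts[i] - pts[j]) * scale) ** 2).sum())
            for i in range(5) for j in range(i + 1, 5))
        assert np.allclose(sorted(out["distances_nm"]), oracle)
        assert out["n_pairs"] == 10

    def test_duplicate_peak_flags_zero_distance(self):
        peaks = self.make_peaks([(5, 5, 0), (5, 5, 0)])
        with pytest.warns(UserWarning, match="zero distance"):
            out = peak_pairwise_distances(peaks, self.GEOM)
        assert out["n_zero"] == 1

    def test_single_peak_empty_result(self):
        out = peak_pairwise_distances(self.make_peaks([(1, 1, 0)]), self.GEOM)
        assert out["n_pairs"] == 0


class TestHierarchical:
    def test_planted_split_recovered_exactly(self, rng):
        a = rng.normal(0.0, 1.0, (40, 3))
        b = rng.normal(50.0, 1.0, (40, 3))
        out = euclid_hierarchical(a, b, n_clusters=2)
        labels = out["cut_labels"]
        assert len(np.unique(labels[out["origin"] == 0])) == 1
        assert len(np.unique(labels[out["origin"] == 1])) == 1
        assert labels[0] != labels[-1]

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        pts = rng.random((15, 3))
        out = euclid_hierarchical(pts, pts + 2.0)
        d = out["distance_matrix"]
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_subsampling_cap_respected(self, rng):
        a = rng.random((3000, 3))
        out = euclid_hierarchical(a, a[:10], max_voxels=100, seed=1)
        assert out["distance_matrix"].shape == (110, 110)


class TestCorrelationMatrix:
    def test_diagonal_ones_and_duplicate_channel(self, rng):
        x = rng.random((2, 8, 8, 8))
        cubes = np.concatenate([x, x[:1]], axis=0)  # channel 2 duplicates 0
        out = channel_correlation_matrix(cubes)
        corr = out["correlation"]
        assert np.allclose(np.diag(corr), 1.0)
        assert corr[0, 2] == pytest.approx(1.0)

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(3)
        cubes = rng.normal(size=(2, 64, 64, 64))
        r = channel_correlation_matrix(cubes)["correlation"][0, 1]
        assert abs(r) < 0.05

    def test_constant_channel_flagged(self, rng):
        cubes = np.stack([np.ones((4, 4, 4)), rng.random((4, 4, 4)),
                          rng.random((4, 4, 4))])
        out = channel_correlation_matrix(cubes)
        assert out["constant_channels"] == [0]
        assert np.isnan(out["correlation"][0, 1])

    def test_association_clipped_nonnegative(self, rng):
        cubes = rng.normal(size=(3, 6, 6, 6))
        assert np.all(channel_correlation_matrix(cubes)["association"] >= 0)


class TestDelaunay:
    def test_four_uniform_blocks_give_two_triangles(self):
        img = np.ones((1, 4, 4))  # one channel, 2x2 blocks of 2x2 px
        graph = delaunay_neighborhoods(img, block=2)
        assert len(graph.centroids) == 4
        assert len(graph.simplices) == 2

    def test_block_signals_conserve_image_total(self, rng):
        img = rng.random((2, 8, 8)) + 0.01
        graph = delaunay_neighborhoods(img, block=4)
        assert graph.block_signals.sum(axis=0) == \
            pytest.approx(img.reshape(2, -1).sum(axis=1))

    def test_cube_corner_tetrahedra_match_volume_oracle(self, rng):
        # 8 blocks at cube corners: simplex volumes must tile the hull
        cubes = np.zeros((1, 4, 4, 4))
        for z in (0, 3):
            for y in (0, 3):
                for x in (0, 3):
                    cubes[0, z, y, x] = 1.0
        graph = delaunay_neighborhoods(cubes, block=2, three_d=True)
        assert len(graph.centroids) == 8

        def simplex_volume(pts):
            v = pts[1:] - pts[0]
            return abs(np.linalg.det(v)) / 6.0

        total = sum(simplex_volume(graph.centroids[s])
                    for s in graph.simplices)
        hull = ConvexHull(graph.centroids)
        assert total == pytest.approx(hull.volume, rel=1e-9)

    def test_zero_blocks_dropped(self):
        img = np.zeros((1, 6, 6))
        img[0, :2, :2] = 1.0
        img[0, :2, 4:] = 1.0
        img[0, 4:, :2] = 1.0
        graph = delaunay_neighborhoods(img, block=2)
        assert graph.n_dropped_blocks == 6
        assert len(graph.centroids) == 3

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            delaunay_neighborhoods(np.zeros((1, 4, 4)), block=2)
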