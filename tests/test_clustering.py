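"""Joint position+depth loss, seeded K-means, merging, adaptive K."""

import numpy as np
import pytest

import fruitpick as fp
from fruitpick.instance_clustering import (
    ClusteringConfig,
    adaptive_kmeans,
    clustering_loss,
    extract_fruit_pixels,
    instances_from_state,
    merge_close_centers,
    run_kmeans,
)


def blob(center, n, spread, depth, rng):
    pos = rng.normal(center, spread, size=(n, 2))
    d = rng.normal(depth, 0.5, size=(n, 1))
    return np.hstack([pos, d])


class TestLoss:
    def test_two_samples_one_center_alpha_one(self):
        samples = [(0, 0, 0), (0, 2, 2)]
        assert clustering_loss(samples, [(0, 1, 1)], [0, 0], alpha=1.0) == pytest.approx(4.0)

    def test_alpha_zero_keeps_position_term_only(self):
        samples = [(0, 0, 0), (0, 2, 2)]
        assert clustering_loss(samples, [(0, 1, 1)], [0, 0], alpha=0.0) == pytest.approx(2.0)

    def test_every_sample_its_own_center_is_zero(self):
        samples = [(0, 0, 5), (3, 4, 9)]
        assert clustering_loss(samples, samples, [0, 1], alpha=1.0) == 0.0


class TestExtract:
    def test_no_mature_pixels_gives_empty(self):
        sem = fp.SemanticMap(np.zeros((8, 8), dtype=np.uint8))
        depth = fp.DepthMap(np.full((8, 8), 500, dtype=np.uint16))
        assert len(extract_fruit_pixels(sem, depth, ClusteringConfig())) == 0

    def test_single_block_collapses_to_one_sample(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[:4, :4] = 1
        depth = fp.DepthMap(np.full((8, 8), 500, dtype=np.uint16))
        samples = extract_fruit_pixels(
            fp.SemanticMap(labels), depth, ClusteringConfig(downsample_factor=4)
        )
        assert samples.shape == (1, 3)
        assert tuple(samples[0]) == (0.0, 0.0, 50.0)  # depth in cm working units

    def test_invalid_depth_pixels_are_dropped(self):
        labels = np.ones((4, 4), dtype=np.uint8)
        depth = np.full((4, 4), 500, dtype=np.uint16)
        depth[:2, :2] = 0  # whole top-left block invalid
        samples = extract_fruit_pixels(
            fp.SemanticMap(labels),
            fp.DepthMap(depth),
            ClusteringConfig(downsample_factor=2),
        )
        assert len(samples) == 3

    def test_misaligned_maps_rejected(self):
        with pytest.raises(ValueError):
            extract_fruit_pixels(
                fp.SemanticMap(np.zeros((4, 4))),
                fp.DepthMap(np.zeros((5, 5))),
                ClusteringConfig(),
            )


class TestRunKmeans:
    def test_k_equals_n_gives_zero_loss(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0, 100, (6, 3))
        st = run_kmeans(samples, k=6, seed=1)
        assert st.loss == pytest.approx(0.0)
        assert len(set(st.assignment)) == 6

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            run_kmeans(np.zeros((3, 3)), k=4)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_distant_blobs_split_cleanly(self, seed):
        rng = np.random.default_rng(42)
        samples = np.vstack(
            [blob((0, 0), 40, 2.0, 50, rng), blob((0, 100), 40, 2.0, 50, rng)]
        )
        st = run_kmeans(samples, k=2, seed=seed)
        left = st.assignment[:40]
        right = st.assignment[40:]
        assert len(set(left)) == 1 and len(set(right)) == 1
        assert left[0] != right[0]

    @pytest.mark.parametrize("seed", range(20))
    def test_loss_never_increases_across_iterations(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.uniform(0, 60, (rng.integers(20, 80), 3))
        st = run_kmeans(samples, k=4, seed=seed, track_history=True)
        assert all(a >= b - 1e-9 for a, b in zip(st.history, st.history[1:]))

    def test_alpha_zero_matches_position_only_kmeans_oracle(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        samples = rng.uniform(0, 100, (60, 3))
        init = samples[rng.choice(60, 4, replace=False)]
        ours = run_kmeans(samples, k=4, alpha=0.0, init_centers=init, max_iter=200)
        ref = KMeans(
            n_clusters=4, init=init[:, :2], n_init=1, max_iter=200, tol=0.0
        ).fit(samples[:, :2])
        assert np.array_equal(ours.assignment, ref.labels_)

    def test_identical_inputs_reproduce_identical_states(self):
        rng = np.random.default_rng(9)
        samples = rng.uniform(0, 50, (40, 3))
        a = run_kmeans(samples, 3, seed=5)
        b = run_kmeans(samples, 3, seed=5)
        assert np.array_equal(a.assignment, b.assignment)
        assert np.array_equal(a.centers, b.centers)
        assert a.loss == b.loss


class TestMerge:
    def test_distant_centers_untouched(self):
        samples = np.array([(0, 0, 0), (0, 100, 0)], dtype=float)
        st = run_kmeans(samples, 2, seed=0)
        merged = merge_close_centers(st, samples, merge_dist=12, alpha=1.0)
        assert merged.K == 2

    def test_close_pair_merges_to_member_mean(self):
        samples = np.array([(0, 0, 0), (0, 1, 0), (50, 50, 0)], dtype=float)
        st = run_kmeans(samples, 3, seed=0)
        merged = merge_close_centers(st, samples, merge_dist=12, alpha=1.0)
        assert merged.K == 2
        centers = sorted(map(tuple, np.round(merged.centers, 6)))
        assert (0.0, 0.5, 0.0) in centers

    def test_mutually_close_centers_collapse_transitively(self):
        samples = np.array([(0, 0, 0), (0, 5, 0), (0, 10, 0)], dtype=float)
        st = run_kmeans(samples, 3, seed=0)
        merged = merge_close_centers(st, samples, merge_dist=12, alpha=1.0)
        assert merged.K == 1


class TestAdaptive:
    def test_single_sample_degenerates_to_one_cluster(self):
        st = adaptive_kmeans(np.array([[3.0, 4.0, 50.0]]), ClusteringConfig())
        assert st.K == 1 and st.loss == 0.0

    def test_compact_blob_collapses_from_k0_to_one(self):
        rng = np.random.default_rng(1)
        samples = blob((10, 10), 80, 2.0, 60, rng)
        st = adaptive_kmeans(samples, ClusteringConfig(min_cluster_size=0))
        assert st.K == 1

    def test_three_far_blobs_recovered(self):
        rng = np.random.default_rng(2)
        samples = np.vstack(
            [
                blob((0, 0), 60, 2.0, 40, rng),
                blob((0, 150), 60, 2.0, 70, rng),
                blob((150, 75), 60, 2.0, 100, rng),
            ]
        )
        st = adaptive_kmeans(samples, ClusteringConfig(min_cluster_size=0))
        assert st.K == 3

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            adaptive_kmeans(np.empty((0, 3)), ClusteringConfig())

    @pytest.mark.parametrize("seed", [11, 29])
    def test_scene_recovery_end_to_end(self, seed):
        spec = fp.SceneSpec(min_separation=200.0)
        rgb, depth, sem, gt = fp.generate_scene(spec, seed=seed)
        samples = extract_fruit_pixels(sem, depth, ClusteringConfig())
        st = adaptive_kmeans(samples, ClusteringConfig())
        assert st.K == len(gt.fruits)


class TestInstances:
    def _scene_two_depth_fruits(self):
        """Two vertically-adjacent half-disks, separated only by depth."""
        h, w = 80, 80
        labels = np.zeros((h, w), dtype=np.uint8)
        depth = np.zeros((h, w), dtype=np.uint16)
        rr, cc = np.mgrid[0:h, 0:w]
        top = (rr - 30) ** 2 + (cc - 40) ** 2 <= 20**2
        bottom = (rr - 50) ** 2 + (cc - 40) ** 2 <= 20**2
        labels[top | bottom] = 1
        depth[top] = 500
        depth[bottom & ~top] = 900
        return fp.SemanticMap(labels), fp.DepthMap(depth), top, bottom

    def test_masks_partition_the_mature_mask(self):
        sem, depth, _, _ = self._scene_two_depth_fruits()
        cfg = ClusteringConfig(downsample_factor=2)
        st = adaptive_kmeans(extract_fruit_pixels(sem, depth, cfg), cfg)
        instances = instances_from_state(st, sem, depth, cfg)
        union = np.zeros(sem.shape, dtype=int)
        for inst in instances:
            union += inst.mask
        assert np.array_equal(union > 0, sem.labels == 1)
        assert union.max() == 1  # disjoint

    def test_depth_separates_overlapping_fruits(self):
        sem, depth, top, bottom = self._scene_two_depth_fruits()
        cfg = ClusteringConfig(downsample_factor=2)
        st = adaptive_kmeans(extract_fruit_pixels(sem, depth, cfg), cfg)
        assert st.K == 2
        instances = instances_from_state(st, sem, depth, cfg)
        # each instance should be depth-pure, not a positional split
        for inst in instances:
            d = depth.depth[inst.mask]
            d = d[d > 0]
            assert (d == d[0]).all()

    def test_single_cluster_keeps_whole_mature_mask(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[5:15, 5:15] = 1
        depth = fp.DepthMap(np.full((20, 20), 600, dtype=np.uint16))
        sem = fp.SemanticMap(labels)
        cfg = ClusteringConfig(downsample_factor=2)
        st = adaptive_kmeans(extract_fruit_pixels(sem, depth, cfg), cfg)
        instances = instances_from_state(st, sem, depth, cfg)
        assert len(instances) == 1
        assert np.array_equal(instances[0].mask, labels == 1)
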