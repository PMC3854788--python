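"""Seed detection and Voronoi-style front-propagation segmentation.

The segmentation is checked against an independent exhaustive oracle: a
per-seed single-source Dijkstra over every foreground voxel, with the
same traversal-cost definition and the same smaller-seed tie rule, kept
deliberately separate from the implementation under test.
"""

import heapq
import itertools

import numpy as np
import pytest

import spotquant as sq
from spotquant.segmentation import (
    DEFAULT_LAMBDA,
    filter_seeds,
    matched_foreground_threshold,
    resolve_foreground_threshold,
)
from spotquant.synthetic import true_labels_on_grid

from conftest import normalized_grid, run_recovery_scene, small_scene_spec


# --------------------------------------------------------------------------
# oracle: brute-force multi-source geodesic labeling
# --------------------------------------------------------------------------

def oracle_labels(data, seeds, threshold, lam=DEFAULT_LAMBDA):
    """Exhaustive per-seed Dijkstra; assign argmin cost, ties to smaller seed.

    Traversal cost of entering voxel w: step length × (1 + λ(1 − I(w))).
    """
    shape = data.shape
    fg = data >= threshold
    moves = [
        (dz, dy, dx, np.sqrt(dz * dz + dy * dy + dx * dx))
        for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    best = {}
    for si, seed in enumerate(seeds):
        dist = {tuple(seed): 0.0}
        heap = [(0.0, tuple(seed))]
        while heap:
            d, v = heapq.heappop(heap)
            if d > dist.get(v, np.inf):
                continue
            for dz, dy, dx, ln in moves:
                w = (v[0] + dz, v[1] + dy, v[2] + dx)
                if not all(0 <= w[i] < shape[i] for i in range(3)):
                    continue
                if not fg[w]:
                    continue
                nd = d + ln * (1.0 + lam * (1.0 - data[w]))
                if nd < dist.get(w, np.inf):
                    dist[w] = nd
                    heapq.heappush(heap, (nd, w))
        for v, d in dist.items():
            cur = best.get(v)
            if cur is None or d < cur[0] or (d == cur[0] and si < cur[1]):
                best[v] = (d, si)
    labels = np.zeros(shape, dtype=np.int32)
    for v, (_, si) in best.items():
        labels[v] = si + 1
    return labels


def random_foreground_grid(rng, shape):
    """A smooth random field with a few bright blobs, as a normalized grid."""
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.random(shape), 1.2)
    return normalized_grid(data)


class TestDetectSeeds:
    def test_constant_grid_yields_no_seeds(self):
        grid = sq.VoxelGrid(np.ones((6, 6, 6)), (0.2,) * 3, normalized=True)
        assert len(sq.detect_seeds(grid, h_min=0.1)) == 0

    def test_recovers_well_separated_gaussians(self):
        spec = small_scene_spec(seed=8, n_spots=5)
        grid, truth = sq.generate_stack(spec)
        pre = sq.preprocess_stack(grid)
        seeds = sq.detect_seeds(pre, min_separation_um=0.6)
        seeds = filter_seeds(pre, seeds, resolve_foreground_threshold(pre, None))
        assert len(seeds) == 5
        centers_vox = truth.spot_centers_um / 0.2
        for c in centers_vox:
            err = min(np.abs(np.asarray(s) - c).max() for s in seeds.seeds)
            assert err <= 1.0

    def test_translation_equivariance(self):
        z, y, x = np.mgrid[0:14, 0:14, 0:14].astype(float)
        blob = lambda c: np.exp(-(((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) / 6.0))
        g0 = normalized_grid(0.05 + blob((6, 6, 6)))
        g1 = normalized_grid(0.05 + blob((6, 8, 7)))
        s0 = sq.detect_seeds(g0, h_min=0.1).seeds
        s1 = sq.detect_seeds(g1, h_min=0.1).seeds
        assert len(s0) == len(s1) == 1
        assert tuple(np.subtract(s1[0], s0[0])) == (0, 2, 1)

    def test_plateau_contributes_single_centroid_seed(self):
        data = np.full((5, 5, 7), 0.2)
        data[2, 2, 2:5] = 0.9  # 3-voxel plateau along x
        grid = sq.VoxelGrid(data / 0.9, (0.2,) * 3, normalized=True)
        seeds = sq.detect_seeds(grid, h_min=0.1)
        assert seeds.seeds == [(2, 2, 3)]

    def test_close_maxima_merge_keeping_brighter(self):
        data = np.full((3, 5, 9), 0.1)
        data[1, 2, 2] = 0.8
        data[1, 2, 4] = 1.0  # 0.4 µm away at 0.2 µm spacing
        grid = sq.VoxelGrid(data, (0.2,) * 3, normalized=True)
        seeds = sq.detect_seeds(grid, h_min=0.1, min_separation_um=0.5)
        assert seeds.seeds == [(1, 2, 4)]
        far = sq.detect_seeds(grid, h_min=0.1, min_separation_um=0.3)
        assert len(far) == 2


class TestSegmentSpots:
    def test_single_seed_claims_connected_foreground(self):
        grid = random_foreground_grid(np.random.default_rng(0), (8, 8, 8))
        peak = np.unravel_index(np.argmax(grid.data), grid.shape)
        seeds = sq.SeedSet([tuple(int(i) for i in peak)], [1.0])
        labels = sq.segment_spots(grid, seeds, foreground_threshold=0.0)
        assert (labels.labels == 1).all()

    def test_symmetric_pair_splits_on_midplane(self):
        z, y, x = np.mgrid[0:9, 0:9, 0:17].astype(float)
        blob = lambda cx: np.exp(-(((z - 4) ** 2 + (y - 4) ** 2 + (x - cx) ** 2) / 4.0))
        grid = normalized_grid(blob(4) + blob(12))
        seeds = sq.SeedSet([(4, 4, 4), (4, 4, 12)], [1.0, 1.0])
        labels = sq.segment_spots(grid, seeds, foreground_threshold=0.05)
        fg = grid.data >= 0.05
        assert (labels.labels[fg & (x <= 7)] == 1).all()
        assert (labels.labels[fg & (x >= 9)] == 2).all()

    def test_seed_below_threshold_is_an_error(self):
        grid = normalized_grid(np.linspace(0.1, 1.0, 64).reshape(4, 4, 4))
        with pytest.raises(ValueError, match="seed 0"):
            sq.segment_spots(grid, sq.SeedSet([(0, 0, 0)], [0.1]), 0.9)

    def test_empty_seed_set_with_foreground_is_an_error(self):
        grid = normalized_grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="empty seed"):
            sq.segment_spots(grid, sq.SeedSet([], []), 0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 13, size=3))
        grid = random_foreground_grid(rng, shape)
        threshold = float(np.quantile(grid.data, 0.4))
        fg_idx = np.argwhere(grid.data >= threshold)
        n_seeds = rng.integers(2, 5)
        picks = fg_idx[rng.choice(len(fg_idx), size=n_seeds, replace=False)]
        seeds = sq.SeedSet(
            [tuple(int(i) for i in p) for p in picks],
            [float(grid.data[tuple(p)]) for p in picks],
        )
        got = sq.segment_spots(grid, seeds, threshold)
        want = oracle_labels(grid.data, seeds.seeds, threshold)
        np.testing.assert_array_equal(got.labels, want)

    def test_matches_oracle_on_uniform_costs_with_ties(self):
        # constant intensity: every path cost is pure length, exercising
        # the smaller-seed tie rule on symmetric voxels
        grid = sq.VoxelGrid(np.ones((7, 7, 7)), (0.2,) * 3, normalized=True)
        seeds = sq.SeedSet([(3, 3, 1), (3, 3, 5), (1, 3, 3)], [1.0, 1.0, 1.0])
        got = sq.segment_spots(grid, seeds, foreground_threshold=0.5)
        want = oracle_labels(grid.data, seeds.seeds, 0.5)
        np.testing.assert_array_equal(got.labels, want)

    def test_partition_identity(self):
        grid = random_foreground_grid(np.random.default_rng(9), (10, 10, 10))
        threshold = float(np.quantile(grid.data, 0.5))
        peak = np.unravel_index(np.argmax(grid.data), grid.shape)
        seeds = sq.SeedSet([tuple(int(i) for i in peak)], [1.0])
        labels = sq.segment_spots(grid, seeds, threshold)
        n_fg = int((grid.data >= threshold).sum())
        assert (labels.labels > 0).sum() + labels.n_unreachable == n_fg

    def test_scale_invariance_before_normalization(self):
        spec = small_scene_spec(seed=4, n_spots=3, noise_sd=5.0)
        grid, _ = sq.generate_stack(spec)
        out = {}
        for k in (1.0, 7.3):
            scaled = sq.VoxelGrid(grid.data * k, grid.spacing_um)
            pre = sq.preprocess_stack(scaled)
            seeds = sq.detect_seeds(pre, min_separation_um=0.6)
            labels = sq.segment_spots(pre, seeds, 0.2)
            out[k] = (seeds.seeds, labels.labels)
        assert out[1.0][0] == out[7.3][0]
        np.testing.assert_array_equal(out[1.0][1], out[7.3][1])


class TestConnectivity:
    def _label_map(self, mask):
        return sq.SpotLabelMap(mask.astype(np.int32), 0.5)

    def test_single_voxel_segment_is_connected(self):
        mask = np.zeros((3, 3, 3), dtype=int)
        mask[1, 1, 1] = 1
        assert sq.check_connected(self._label_map(mask), 1)

    def test_diagonal_touch_counts_as_connected(self):
        mask = np.zeros((3, 3, 3), dtype=int)
        mask[0, 0, 0] = mask[1, 1, 1] = 1
        assert sq.check_connected(self._label_map(mask), 1)

    def test_separated_voxels_are_disconnected(self):
        mask = np.zeros((3, 3, 5), dtype=int)
        mask[1, 1, 0] = mask[1, 1, 4] = 1
        assert not sq.check_connected(self._label_map(mask), 1)

    def test_absent_label_errors(self):
        mask = np.zeros((3, 3, 3), dtype=int)
        mask[1, 1, 1] = 1
        with pytest.raises(ValueError, match="absent"):
            sq.check_connected(self._label_map(mask), 4)

    def test_every_emitted_segment_is_connected_over_scene_sweep(self):
        # reduced sweep; the full 100-scene sweep runs in the acceptance suite
        for seed in range(10):
            spec = small_scene_spec(seed=seed, n_spots=3, noise_sd=5.0)
            grid, _ = sq.generate_stack(spec)
            norm = sq.normalize_intensity(grid)
            seeds = sq.detect_seeds(norm, min_separation_um=0.6)
            thr = resolve_foreground_threshold(norm, None)
            seeds = filter_seeds(norm, seeds, thr)
            if len(seeds) == 0:
                continue
            labels = sq.segment_spots(norm, seeds, thr)
            for l in range(1, labels.n_spots + 1):
                if (labels.labels == l).any():
                    assert sq.check_connected(labels, l)


def test_ground_truth_recovery_noiseless():
    out = run_recovery_scene(seed=13)
    assert out["recall"] == 1.0
    assert out["max_error_vox"] <= 1.0
    assert len(out["ious"]) == 4 and min(out["ious"]) >= 0.7
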