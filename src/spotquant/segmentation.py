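"""Spot seeding and seeded Voronoi-style segmentation.

Local intensity maxima of the normalized stack are detected as spot
centers ("seeds"); the thresholded foreground is then partitioned among
the seeds by competitive geodesic front propagation: every seed's front
grows simultaneously through the foreground, and a voxel joins the seed
whose front reaches it at minimal accumulated cost.  The cost of a front
stepping into voxel x is the Euclidean step length multiplied by

    1 + λ · (1 − I(x)),       0 ≤ I ≤ 1,

so fronts race cheaply through bright voxels, slow down in dim ones, and
meet on the intensity ridges between spots.  Because the metric is shared
by all fronts, every voxel on a shortest path from the winning seed is
itself won by that seed — each segment is guaranteed connected, and the
simultaneous propagation is exactly equivalent to computing each seed's
geodesic distance field and taking the per-voxel argmin.  This realizes
an evolving generalized Voronoi partition of the foreground: one
connected segment per seed, segments pairwise disjoint, boundaries on
ridges.

Connectivity is 26-neighborhood throughout, for the front moves, for the
connected-region definition, and for the plateau handling in seed
detection.  Ties in arrival cost resolve to the smaller seed index, making
the partition deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .preprocess import VoxelGrid

logger = logging.getLogger("spotquant")

#: Weight of the intensity term in the front-traversal cost.
DEFAULT_LAMBDA = 5.0
#: Minimum normalized intensity for a local maximum to count as a seed.
DEFAULT_H_MIN = 0.1
#: Seeds closer than this (µm) are merged, keeping the brighter.
DEFAULT_MIN_SEPARATION_UM = 0.4

# Offsets and Euclidean lengths of the 26 neighbor moves.
NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)
NEIGHBOR_LENGTHS = np.sqrt((NEIGHBOR_OFFSETS**2).sum(axis=1)).astype(np.float64)

STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SeedSet:
    """Detected spot centers: voxel indices plus their intensities."""

    seeds: list[tuple[int, int, int]]
    seed_intensities: list[float]

    def __len__(self) -> int:
        return len(self.seeds)


@dataclass
class SpotLabelMap:
    """Integer partition of the foreground into spot segments.

    0 is background; labels 1..L are segments, each generated by one seed
    and connected under 26-connectivity.
    """

    labels: np.ndarray
    foreground_threshold: float
    n_unreachable: int = 0

    @property
    def n_spots(self) -> int:
        return int(self.labels.max())


def _require_normalized(grid: VoxelGrid) -> None:
    if not grid.normalized:
        raise ValueError("grid must be normalized (run normalize_intensity first)")


def detect_seeds(
    grid: VoxelGrid,
    h_min: float = DEFAULT_H_MIN,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
) -> SeedSet:
    """Detect 26-neighborhood local maxima of a normalized stack as seeds.

    A plateau of equal-valued maxima contributes a single seed at its
    intensity-weighted centroid rounded to the nearest voxel (a plateau
    must be bounded by strictly lower voxels; a constant stack has none).
    Maxima closer than ``min_separation_um`` are merged keeping the
    brighter, ties resolving to the smaller lexicographic index.
    """
    _require_normalized(grid)
    data = grid.data
    is_max = (data == ndimage.maximum_filter(data, footprint=STRUCTURE_26, mode="nearest")) & (
        data >= h_min
    )
    comp, n_comp = ndimage.label(is_max, structure=STRUCTURE_26)
    candidates: list[tuple[float, tuple[int, int, int]]] = []
    if n_comp:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n_comp + 1))
        # Intensity-weighted centroid; on a plateau all weights are equal.
        centroids = ndimage.center_of_mass(data, comp, index=range(1, n_comp + 1))
        values = ndimage.maximum(data, comp, index=range(1, n_comp + 1))
        for size, centroid, value in zip(sizes, centroids, values):
            if int(size) == data.size:
                # A maximum plateau must be bounded by strictly lower
                # voxels; a constant stack has no seeds.
                continue
            idx = tuple(
                int(np.clip(round(c), 0, n - 1)) for c, n in zip(centroid, data.shape)
            )
            candidates.append((float(value), idx))
    # Greedy merge: brightest first, ties by lexicographic voxel index.
    candidates.sort(key=lambda t: (-t[0], t[1]))
    spacing = np.asarray(grid.spacing_um)
    kept: list[tuple[int, int, int]] = []
    kept_vals: list[float] = []
    for value, idx in candidates:
        pos = np.asarray(idx) * spacing
        if all(
            np.linalg.norm(pos - np.asarray(k) * spacing) >= min_separation_um for k in kept
        ):
            kept.append(tuple(int(i) for i in idx))
            kept_vals.append(float(data[idx]))
    logger.debug("detect_seeds: %d maxima -> %d seeds", len(candidates), len(kept))
    return SeedSet(kept, kept_vals)


def resolve_foreground_threshold(grid: VoxelGrid, threshold: float | None) -> float:
    """Otsu's threshold of the normalized stack unless given explicitly."""
    _require_normalized(grid)
    if threshold is not None:
        return float(threshold)
    value = float(threshold_otsu(grid.data))
    logger.debug("foreground threshold (Otsu): %.4f", value)
    return value


def processed_spot_attenuation(
    sigma_um: float,
    smooth_sigma_um: float,
    laplacian_weight: float,
    spacing_um: float,
    n_sigma: float = 2.0,
) -> float:
    """Relative intensity of a processed Gaussian spot at radius nσ.

    A punctum of SD σ convolved with a Gaussian of SD s is a Gaussian of
    SD σ' = sqrt(σ² + s²); the Laplacian enhancement g − w∇²g then
    multiplies it by (1 + w_p(3σ'² − r²)/σ'⁴) with w_p = w·h² (h the
    voxel edge).  The returned fraction f(nσ)/f(0) is the level, relative
    to the spot's processed peak, at which its support reaches nσ of the
    ORIGINAL spot — the threshold fraction a recovery experiment needs to
    compare segments against an nσ ground-truth support.
    """
    var = sigma_um**2 + smooth_sigma_um**2
    r2 = (n_sigma * sigma_um) ** 2
    w_p = laplacian_weight * spacing_um**2
    gaussian = np.exp(-r2 / (2 * var))
    shape_factor = max(1.0 + w_p * (3 * var - r2) / var**2, 0.0) / (
        1.0 + 3 * w_p / var
    )
    return float(gaussian * shape_factor)


def matched_foreground_threshold(
    seeds: SeedSet, support_fraction: float = np.exp(-2.0)
) -> float:
    """Foreground threshold matched to a known spot-support convention.

    Thresholds at ``support_fraction`` of the dimmest detected seed so
    every detected spot's foreground support extends to the radius where
    its profile falls to that fraction of its peak.  For unprocessed
    Gaussian spots and a 2σ support the fraction is exp(−2); after
    pre-processing use :func:`processed_spot_attenuation`.
    """
    if len(seeds) == 0:
        raise ValueError("no seeds: cannot derive a matched threshold")
    return float(support_fraction * min(seeds.seed_intensities))


def filter_seeds(grid: VoxelGrid, seeds: SeedSet, threshold: float) -> SeedSet:
    """Drop seeds below the foreground threshold (noise maxima)."""
    kept = [
        (s, v)
        for s, v in zip(seeds.seeds, seeds.seed_intensities)
        if grid.data[s] >= threshold
    ]
    if len(kept) < len(seeds):
        logger.info(
            "filter_seeds: dropped %d/%d seeds below foreground threshold %.4f",
            len(seeds) - len(kept), len(seeds), threshold,
        )
    return SeedSet([s for s, _ in kept], [v for _, v in kept])


def segment_spots(
    grid: VoxelGrid,
    seeds: SeedSet,
    foreground_threshold: float | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> SpotLabelMap:
    """Partition the thresholded foreground among seeds.

    Simultaneous Dijkstra front propagation: each foreground voxel joins
    the seed of minimal geodesic arrival cost, with the traversal cost of
    entering voxel x equal to the Euclidean step length times
    ``1 + lam·(1 − I(x))``.  Equal arrival costs resolve to the smaller
    seed index.  Foreground voxels unreachable from every seed are left
    as background and counted.

    ``foreground_threshold`` defaults to Otsu's threshold of the
    normalized stack.
    """
    _require_normalized(grid)
    data = grid.data
    if foreground_threshold is None:
        foreground_threshold = float(threshold_otsu(data))
        logger.debug("segment_spots: Otsu foreground threshold %.4f", foreground_threshold)
    fg = data >= foreground_threshold
    labels = np.zeros(data.shape, dtype=np.int32)
    if not fg.any():
        return SpotLabelMap(labels, foreground_threshold)
    if len(seeds) == 0:
        raise ValueError("empty seed set with nonempty foreground")
    for i, s in enumerate(seeds.seeds):
        if data[s] < foreground_threshold:
            raise ValueError(
                f"seed {i} at {s} (intensity {data[s]:.4f}) lies below the "
                f"foreground threshold {foreground_threshold:.4f}"
            )

    # One geodesic distance field per seed over the shared metric; a voxel
    # joins the seed of minimal arrival cost (argmin resolves ties to the
    # smaller seed index).  Each field is an exact Dijkstra over the
    # foreground adjacency graph.
    shape = data.shape
    fg_idx = np.flatnonzero(fg.ravel())
    n_fg = fg_idx.size
    rank = np.full(data.size, -1, dtype=np.int64)
    rank[fg_idx] = np.arange(n_fg)
    coords = np.stack(np.unravel_index(fg_idx, shape), axis=1)  # (n_fg, 3)
    intensities = data.ravel()[fg_idx]

    # Directed edges u -> v between 26-adjacent foreground voxels with
    # weight length(u,v) * (1 + lam*(1 - I(v))).
    src_list, dst_list, len_list = [], [], []
    for off, length in zip(NEIGHBOR_OFFSETS, NEIGHBOR_LENGTHS):
        nbr = coords + off
        ok = ((nbr >= 0) & (nbr < np.array(shape))).all(axis=1)
        flat_nbr = np.ravel_multi_index(nbr[ok].T, shape)
        nbr_rank = rank[flat_nbr]
        ok2 = nbr_rank >= 0
        src_list.append(np.flatnonzero(ok)[ok2])
        dst_list.append(nbr_rank[ok2])
        len_list.append(np.full(ok2.sum(), length))
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    lengths = np.concatenate(len_list)

    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra as cs_dijkstra

    seed_ranks = [int(rank[np.ravel_multi_index(s, shape)]) for s in seeds.seeds]
    weights = lengths * (1.0 + lam * (1.0 - intensities[dst]))
    graph = csr_matrix((weights, (src, dst)), shape=(n_fg, n_fg))
    costs = cs_dijkstra(graph, directed=True, indices=seed_ranks)
    costs = np.atleast_2d(costs)

    reachable = np.isfinite(costs).any(axis=0)
    best_seed = np.argmin(costs, axis=0)  # ties -> smaller seed index
    labels_flat = labels.ravel()
    labels_flat[fg_idx[reachable]] = best_seed[reachable] + 1
    n_unreachable = int(np.count_nonzero(~reachable))
    if n_unreachable:
        logger.info("segment_spots: %d foreground voxels unreachable from any seed", n_unreachable)
    return SpotLabelMap(labels, foreground_threshold, n_unreachable)


def trim_segments_to_support(
    grid: VoxelGrid,
    label_map: SpotLabelMap,
    seeds: SeedSet,
    smooth_sigma_um: float,
    laplacian_weight: float,
    n_sigma: float = 2.0,
) -> SpotLabelMap:
    """Restrict each segment to its own spot's predicted nσ support.

    A single global foreground threshold cannot delimit an nσ support for
    every spot at once when spot widths and amplitudes vary: the level at
    which a processed spot's profile reaches nσ is a per-spot fraction of
    its own peak.  For each segment this estimates the processed width σ'
    from the half-maximum radius around the seed, converts it to the
    original spot SD, evaluates :func:`processed_spot_attenuation`, and
    keeps the voxels above that fraction of the seed's peak (the connected
    component containing the seed).  Used when segments must be compared
    against a fixed nσ spot-extent convention.
    """
    _require_normalized(grid)
    h = float(grid.spacing_um[0])
    out = np.zeros_like(label_map.labels)
    for i, seed in enumerate(seeds.seeds):
        l = i + 1
        mask = label_map.labels == l
        if not mask.any():
            continue
        peak = float(grid.data[seed])
        vox = np.argwhere(mask)
        dist = np.linalg.norm((vox - np.asarray(seed)) * h, axis=1)
        vals = grid.data[tuple(vox.T)]
        half = vals >= 0.5 * peak
        if half.sum() < 2:
            out[mask] = l
            continue
        # robust half-maximum radius -> processed width -> support level
        r_half = float(np.quantile(dist[half], 0.95))
        var_processed = max(r_half**2 / (2 * np.log(2)), 1e-6)
        sigma_est = np.sqrt(max(var_processed - smooth_sigma_um**2, 1e-6))
        frac = processed_spot_attenuation(
            sigma_est, smooth_sigma_um, laplacian_weight, h, n_sigma
        )
        keep = mask & (grid.data >= frac * peak)
        comp, _ = ndimage.label(keep, structure=STRUCTURE_26)
        out[comp == comp[seed]] = l
    return SpotLabelMap(out, label_map.foreground_threshold, label_map.n_unreachable)


def check_connected(label_map: SpotLabelMap, l: int) -> bool:
    """True iff segment ``l`` is one 26-connected region (flood-fill test)."""
    if l < 1:
        raise ValueError("label must be a positive integer")
    mask = label_map.labels == l
    if not mask.any():
        raise ValueError(f"label {l} absent from label map")
    _, n_comp = ndimage.label(mask, structure=STRUCTURE_26)
    return n_comp == 1
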