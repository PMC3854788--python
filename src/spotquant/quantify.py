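"""Per-spot brightness and group-level fold-change statistics.

The average brightness of a segmented spot S_l is the sum of normalized
intensities over its voxels divided by the spot's volume in voxels,

    B_l = ( Σ_{x ∈ S_l} I(x) ) / |S_l|,

with the physical volume (|S_l| × voxel volume, µm³) reported alongside so
a per-µm³ variant is a constant rescale.  Group summaries pool spots over
all stacks of a condition and report mean and sample SD (n−1) of the spot
brightnesses; the fold change between two conditions is the ratio of group
means.

Because each stack is normalized to unit maximum, per-stack normalization
erases genuine between-condition intensity differences: two stacks whose
spots differ two-fold produce identical normalized brightnesses.  Group
comparisons must therefore normalize every stack in the cohort by one
shared maximum ("cohort" mode, the pipeline default for comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

import numpy as np
from scipy import ndimage

from .preprocess import VoxelGrid
from .segmentation import SpotLabelMap


@dataclass
class SpotRecord:
    """One segmented spot's size and brightness."""

    spot_id: int
    voxel_count: int
    volume_um3: float
    mean_brightness: float
    sum_brightness: float
    seed_position_um: tuple[float, float, float]
    stack_id: str = ""


@dataclass
class GroupSummary:
    """Pooled spot-brightness statistics for one condition."""

    group_name: str
    n_spots: int
    mean_of_spot_brightness: float
    sd_of_spot_brightness: float | None  # None when fewer than 2 spots
    stacks_included: list[str]


def spot_brightness(
    grid: VoxelGrid,
    label_map: SpotLabelMap,
    stack_id: str = "",
    seed_positions_um: dict[int, tuple[float, float, float]] | None = None,
) -> list[SpotRecord]:
    """Mean brightness of every labeled segment, sorted by spot id."""
    labels = label_map.labels
    if labels.shape != grid.data.shape:
        raise ValueError(
            f"shape mismatch: grid {grid.data.shape} vs labels {labels.shape}"
        )
    voxel_volume = prod(grid.spacing_um)
    n = int(labels.max())
    records: list[SpotRecord] = []
    if n == 0:
        return records
    index = np.arange(1, n + 1)
    sums = ndimage.sum_labels(grid.data, labels, index=index)
    counts = ndimage.sum_labels(np.ones_like(grid.data), labels, index=index)
    for l, s, c in zip(index, sums, counts):
        if c == 0:  # label value unused
            continue
        pos = (seed_positions_um or {}).get(int(l), (np.nan, np.nan, np.nan))
        records.append(
            SpotRecord(
                spot_id=int(l),
                voxel_count=int(c),
                volume_um3=float(c) * voxel_volume,
                mean_brightness=float(s) / float(c),
                sum_brightness=float(s),
                seed_position_um=tuple(float(p) for p in pos),
                stack_id=stack_id,
            )
        )
    return records


def summarize_group(records: list[SpotRecord], group_name: str) -> GroupSummary:
    """Mean and sample SD of spot brightness across a group's spots.

    The SD is taken across spots (not voxels), pooled over all stacks of
    the group; it is undefined (None) for a single spot.
    """
    if not records:
        raise ValueError(f"no spots in group {group_name!r}")
    values = np.array([r.mean_brightness for r in records])
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    stacks = sorted({r.stack_id for r in records})
    return GroupSummary(
        group_name=group_name,
        n_spots=len(values),
        mean_of_spot_brightness=float(values.mean()),
        sd_of_spot_brightness=sd,
        stacks_included=stacks,
    )


def fold_change(reference: GroupSummary, comparison: GroupSummary) -> float:
    """Ratio of reference to comparison group mean spot brightness."""
    if comparison.mean_of_spot_brightness <= 0:
        raise ValueError("comparison group mean brightness must be positive")
    return reference.mean_of_spot_brightness / comparison.mean_of_spot_brightness


def per_stack_means(records: list[SpotRecord]) -> dict[str, float]:
    """Secondary output: mean spot brightness per stack."""
    by_stack: dict[str, list[float]] = {}
    for r in records:
        by_stack.setdefault(r.stack_id, []).append(r.mean_brightness)
    return {k: float(np.mean(v)) for k, v in sorted(by_stack.items())}
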