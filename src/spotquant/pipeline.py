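"""End-to-end workflows with manifests for reproducibility.

Two analyses are wired here:

1. image pipeline — stacks → pre-processing → seed detection → spot
   segmentation → per-spot brightness → group summaries (+ fold change
   when a reference and a comparison group are given);
2. allele pipeline — FASTA of a wild-type target region plus mutant
   amplicons → indel calls and protein consequences as a TSV table.

For group comparisons the stacks are normalized by the cohort-wide
maximum ("cohort" mode) so between-group intensity ratios survive
normalization; per-stack mode is retained for single-stack runs.  Every
run emits a :class:`RunManifest` capturing the exact parameters used;
identical manifests reproduce all outputs byte for byte (timestamps live
only in the manifest itself).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alleles import (
    ComplexAlleleError,
    NoVariantError,
    TargetRegion,
    call_indel,
    protein_consequence,
)
from .preprocess import (
    PreprocessConfig,
    VoxelGrid,
    enhance_laplacian,
    normalize_intensity,
    preprocess_stack,
    resample_isotropic,
    smooth_gaussian,
)
from .quantify import (
    GroupSummary,
    SpotRecord,
    fold_change,
    per_stack_means,
    spot_brightness,
    summarize_group,
)
from .segmentation import (
    DEFAULT_H_MIN,
    DEFAULT_LAMBDA,
    DEFAULT_MIN_SEPARATION_UM,
    SeedSet,
    SpotLabelMap,
    detect_seeds,
    filter_seeds,
    resolve_foreground_threshold,
    segment_spots,
)

logger = logging.getLogger("spotquant")

ALLELE_TSV_COLUMNS = [
    "allele", "kind", "position_nt", "length_nt", "ref_allele",
    "notation", "mutant_peptide",
]


@dataclass
class SegmentationConfig:
    """Seeding and segmentation parameters (lengths in µm)."""

    h_min: float = DEFAULT_H_MIN
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM
    foreground_threshold: float | None = None  # None -> Otsu
    lam: float = DEFAULT_LAMBDA


@dataclass
class RunManifest:
    """Snapshot of everything needed to reproduce a run."""

    command: str
    version: str
    config: dict
    inputs: list[dict]
    rng_seed: int | None = None
    timestamp_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def input_descriptor(path: str | Path) -> dict:
    path = Path(path)
    return {"path": str(path), "sha256": _checksum(path)}


@dataclass
class StackResult:
    """Everything derived from one stack."""

    stack_id: str
    preprocessed: VoxelGrid
    seeds: SeedSet
    label_map: SpotLabelMap
    records: list[SpotRecord]


@dataclass
class ImagePipelineResult:
    stacks: list[StackResult]
    records: list[SpotRecord]
    summaries: list[GroupSummary]
    fold_change: float | None
    per_stack_means: dict[str, float]
    manifest: RunManifest


def _segment_one(
    detection_grid: VoxelGrid,
    quantify_grid: VoxelGrid,
    stack_id: str,
    seg: SegmentationConfig,
) -> StackResult:
    """Seed, segment and measure one stack.

    Geometry (seeds, labels) comes from ``detection_grid`` — each stack's
    own max-normalized copy, so segmentation is invariant to between-stack
    intensity scale — while Eq.-1 brightness is read off
    ``quantify_grid`` (cohort-normalized for group comparisons).
    """
    seeds = detect_seeds(detection_grid, seg.h_min, seg.min_separation_um)
    threshold = resolve_foreground_threshold(detection_grid, seg.foreground_threshold)
    seeds = filter_seeds(detection_grid, seeds, threshold)
    if len(seeds) == 0:
        logger.warning("stack %s: no seeds detected", stack_id)
        label_map = SpotLabelMap(np.zeros(detection_grid.data.shape, dtype=np.int32), threshold)
        return StackResult(stack_id, quantify_grid, seeds, label_map, [])
    label_map = segment_spots(detection_grid, seeds, threshold, seg.lam)
    seed_pos = {
        i + 1: tuple(detection_grid.index_to_um(s)) for i, s in enumerate(seeds.seeds)
    }
    records = spot_brightness(quantify_grid, label_map, stack_id, seed_pos)
    return StackResult(stack_id, quantify_grid, seeds, label_map, records)


def run_image_pipeline(
    stacks: dict[str, list[VoxelGrid]],
    preprocess_config: PreprocessConfig | None = None,
    segmentation_config: SegmentationConfig | None = None,
    normalization: str = "cohort",
    reference_group: str | None = None,
    rng_seed: int | None = None,
    inputs: list[dict] | None = None,
) -> ImagePipelineResult:
    """Run preprocess → seeds → segmentation → brightness → summaries.

    ``stacks`` maps group name → list of raw stacks.  With two or more
    groups, ``normalization='cohort'`` (default) divides every
    pre-processed stack by the single cohort-wide maximum before
    segmentation; ``'per-stack'`` normalizes each stack to its own
    maximum (appropriate only within a stack, never for between-group
    ratios).  Fold change is reported for exactly two groups, as
    reference mean / comparison mean, the reference defaulting to the
    first group.
    """
    if normalization not in ("cohort", "per-stack"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    pre_cfg = preprocess_config or PreprocessConfig()
    seg_cfg = segmentation_config or SegmentationConfig()

    # In cohort mode every stack must pass through one and the same
    # intensity map, otherwise stack-dependent enhancement gains distort
    # between-group brightness ratios.  The histogram stretch therefore
    # uses percentiles pooled over the whole cohort, and the final
    # normalization divides by the single cohort-wide maximum.
    if normalization == "cohort":
        smoothed: dict[str, list[VoxelGrid]] = {}
        for group, grids in stacks.items():
            smoothed[group] = [
                smooth_gaussian(
                    resample_isotropic(g, pre_cfg.target_spacing_um),
                    pre_cfg.gaussian_sigma_um,
                )
                for g in grids
            ]
        pooled = np.concatenate(
            [g.data.ravel() for grids in smoothed.values() for g in grids]
        )
        lo_p, hi_p = pre_cfg.histogram_stretch_percentiles
        vmax = float(pooled.max())
        lo, hi = np.percentile(pooled, [lo_p, hi_p])
        if hi <= lo:
            raise ValueError("cohort histogram is degenerate (constant stacks)")
        logger.info(
            "cohort stretch: pooled low=%.6g high=%.6g max=%.6g", lo, hi, vmax
        )
        preprocessed = {
            group: [
                enhance_laplacian(
                    VoxelGrid(
                        np.clip((g.data - lo) / (hi - lo) * vmax, 0.0, vmax),
                        g.spacing_um,
                        g.origin_um,
                    ),
                    pre_cfg.laplacian_weight,
                )
                for g in grids
            ]
            for group, grids in smoothed.items()
        }
        cohort_max = max(
            float(g.data.max()) for grids in preprocessed.values() for g in grids
        )
        if cohort_max <= 0:
            raise ValueError("empty image: cohort maximum is not positive")
        quantify_grids = {
            group: [
                VoxelGrid(g.data / cohort_max, g.spacing_um, g.origin_um, normalized=True)
                for g in grids
            ]
            for group, grids in preprocessed.items()
        }
    else:
        preprocessed = {
            group: [preprocess_stack(g, pre_cfg, normalize=False) for g in grids]
            for group, grids in stacks.items()
        }
        quantify_grids = None  # set below: per-stack mode quantifies detection grids
    # Detection always runs on each stack's own normalized copy, so the
    # segmentation geometry is invariant to between-stack intensity scale.
    detection: dict[str, list[VoxelGrid]] = {
        group: [normalize_intensity(g) for g in grids]
        for group, grids in preprocessed.items()
    }
    if quantify_grids is None:
        quantify_grids = detection

    stack_results: list[StackResult] = []
    all_records: list[SpotRecord] = []
    summaries: list[GroupSummary] = []
    for group in preprocessed:
        group_records: list[SpotRecord] = []
        for i, (g_det, g_q) in enumerate(zip(detection[group], quantify_grids[group])):
            stack_id = f"{group}/{i}"
            res = _segment_one(g_det, g_q, stack_id, seg_cfg)
            stack_results.append(res)
            group_records.extend(res.records)
        if group_records:
            summaries.append(summarize_group(group_records, group))
        else:
            logger.warning("group %s: zero detected spots", group)
            summaries.append(GroupSummary(group, 0, float("nan"), None, []))
        all_records.extend(group_records)

    fc = None
    if len(stacks) == 2 and all(s.n_spots > 0 for s in summaries):
        names = [s.group_name for s in summaries]
        ref_name = reference_group if reference_group in names else names[0]
        ref = next(s for s in summaries if s.group_name == ref_name)
        cmp_ = next(s for s in summaries if s.group_name != ref_name)
        fc = fold_change(ref, cmp_)
        logger.info(
            "fold change %s/%s = %.4f", ref.group_name, cmp_.group_name, fc
        )

    manifest = RunManifest(
        command="image-pipeline",
        version=__version__,
        config={
            "preprocess": asdict(pre_cfg),
            "segmentation": asdict(seg_cfg),
            "normalization": normalization,
            "reference_group": reference_group,
            "groups": {k: len(v) for k, v in stacks.items()},
        },
        inputs=inputs or [],
        rng_seed=rng_seed,
    )
    return ImagePipelineResult(
        stacks=stack_results,
        records=all_records,
        summaries=summaries,
        fold_change=fc,
        per_stack_means=per_stack_means(all_records),
        manifest=manifest,
    )


def run_allele_pipeline(
    sequences: dict[str, str],
    wild_type_name: str = "wild-type",
    region_params: dict | None = None,
    policy: str = "leftmost",
    inputs: list[dict] | None = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Call indels and protein consequences for every mutant record.

    ``sequences`` maps record name → nucleotide string and must contain
    ``wild_type_name``.  Returns one TSV-ready row per mutant; a record
    that cannot be explained by a single contiguous event is flagged
    ``complex allele`` (and a no-op record ``no variant``).
    """
    if wild_type_name not in sequences:
        raise ValueError(f"wild-type record {wild_type_name!r} missing from input")
    params = {
        "cds_start_nt": 729,
        "frame_offset": 1,
        "first_residue_number": 244,
        "first_residue": "S",
    }
    params.update(region_params or {})
    region = TargetRegion(sequences[wild_type_name], **params)
    rows = []
    for name, seq in sequences.items():
        if name == wild_type_name:
            continue
        try:
            call = call_indel(region, seq, policy)
            cons = protein_consequence(region, call, seq)
            rows.append(
                {
                    "allele": name,
                    "kind": call.kind,
                    "position_nt": call.position_nt,
                    "length_nt": call.length_nt,
                    "ref_allele": call.ref_allele,
                    "notation": cons.notation,
                    "mutant_peptide": cons.mutant_peptide,
                }
            )
        except NoVariantError:
            rows.append(dict.fromkeys(ALLELE_TSV_COLUMNS) | {"allele": name, "kind": "no variant"})
        except ComplexAlleleError as exc:
            rows.append(
                dict.fromkeys(ALLELE_TSV_COLUMNS)
                | {"allele": name, "kind": "complex allele", "notation": str(exc)}
            )
    table = pd.DataFrame(rows, columns=ALLELE_TSV_COLUMNS)
    manifest = RunManifest(
        command="allele-pipeline",
        version=__version__,
        config={"wild_type": wild_type_name, "policy": policy, "region": params},
        inputs=inputs or [],
    )
    return table, manifest
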