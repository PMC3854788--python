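"""File interchange: TIFF stacks with spacing metadata, CSV/FASTA/JSON.

Stacks travel as multi-page TIFF.  Voxel spacing is resolved, in order,
from OME-XML metadata (PhysicalSizeZ/Y/X), from an ImageJ-style TIFF
resolution tag, from a ``<stack>.spacing.txt`` key=value sidecar, or from
an explicit argument; missing spacing is an error.  Label maps are 16-bit
TIFF aligned voxel-for-voxel with their stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import VoxelGrid
from .quantify import GroupSummary, SpotRecord
from .segmentation import SeedSet, SpotLabelMap
from .synthetic import GroundTruth


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(stack_path.suffix + ".spacing.txt")


def write_stack(path: str | Path, grid: VoxelGrid) -> None:
    """Write a multi-page TIFF plus a key=value spacing sidecar (µm)."""
    path = Path(path)
    tifffile.imwrite(path, grid.data.astype(np.float32), photometric="minisblack")
    z, y, x = grid.spacing_um
    _sidecar_path(path).write_text(
        f"spacing_z_um={z}\nspacing_y_um={y}\nspacing_x_um={x}\n"
    )


def _spacing_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tif.ome_metadata:
        return None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tif.ome_metadata)
    for pixels in root.iter():
        if pixels.tag.endswith("Pixels"):
            try:
                return (
                    float(pixels.attrib["PhysicalSizeZ"]),
                    float(pixels.attrib["PhysicalSizeY"]),
                    float(pixels.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    return None


def read_stack(
    path: str | Path, spacing_um: tuple[float, float, float] | None = None
) -> VoxelGrid:
    """Read a stack, resolving voxel spacing from metadata or sidecar."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if spacing_um is None:
            spacing_um = _spacing_from_ome(tif)
    if spacing_um is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            kv = dict(
                line.split("=", 1)
                for line in sidecar.read_text().splitlines()
                if "=" in line
            )
            spacing_um = tuple(
                float(kv[k]) for k in ("spacing_z_um", "spacing_y_um", "spacing_x_um")
            )
    if spacing_um is None:
        raise ValueError(
            f"no voxel spacing for {path}: provide OME metadata, a "
            f"{_sidecar_path(path).name} sidecar, or --spacing Z,Y,X"
        )
    if data.ndim == 2:
        data = data[None]
    return VoxelGrid(data, spacing_um)


def write_label_map(path: str | Path, label_map: SpotLabelMap) -> None:
    labels = label_map.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be written as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")


def write_ground_truth_csv(path: str | Path, truth: GroundTruth) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(1, truth.n_spots + 1),
            "z_um": truth.spot_centers_um[:, 0] if truth.n_spots else [],
            "y_um": truth.spot_centers_um[:, 1] if truth.n_spots else [],
            "x_um": truth.spot_centers_um[:, 2] if truth.n_spots else [],
            "amplitude": truth.spot_amplitudes,
            "sigma_um": truth.spot_sigmas_um,
        }
    )
    df.to_csv(path, index=False)


def write_seeds_csv(path: str | Path, seeds: SeedSet) -> None:
    df = pd.DataFrame(
        [
            {"id": i + 1, "z": s[0], "y": s[1], "x": s[2], "intensity": v}
            for i, (s, v) in enumerate(zip(seeds.seeds, seeds.seed_intensities))
        ],
        columns=["id", "z", "y", "x", "intensity"],
    )
    df.to_csv(path, index=False)


SPOT_CSV_COLUMNS = [
    "stack_id", "spot_id", "z_um", "y_um", "x_um",
    "voxel_count", "volume_um3", "sum", "mean",
]


def spot_records_frame(records: list[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stack_id": r.stack_id,
                "spot_id": r.spot_id,
                "z_um": r.seed_position_um[0],
                "y_um": r.seed_position_um[1],
                "x_um": r.seed_position_um[2],
                "voxel_count": r.voxel_count,
                "volume_um3": r.volume_um3,
                "sum": r.sum_brightness,
                "mean": r.mean_brightness,
            }
            for r in records
        ],
        columns=SPOT_CSV_COLUMNS,
    )


def write_spot_csv(path: str | Path, records: list[SpotRecord]) -> None:
    spot_records_frame(records).to_csv(path, index=False)


def group_summary_dict(summary: GroupSummary) -> dict:
    return {
        "group_name": summary.group_name,
        "n_spots": summary.n_spots,
        "mean_of_spot_brightness": summary.mean_of_spot_brightness,
        "sd_of_spot_brightness": summary.sd_of_spot_brightness,
        "stacks_included": summary.stacks_included,
    }


def write_group_summary_json(path: str | Path, summaries: list[GroupSummary], extra: dict | None = None) -> None:
    payload = {"groups": [group_summary_dict(s) for s in summaries]}
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_allele_fasta(path: str | Path, records: dict[str, str]) -> None:
    """Write named nucleotide sequences (wild-type first if present)."""
    ordered = sorted(records.items(), key=lambda kv: (kv[0] != "wild-type", kv[0]))
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in ordered],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
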