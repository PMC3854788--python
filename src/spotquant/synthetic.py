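"""Ground-truthed synthetic confocal scenes.

Emulates what the quantification pipeline was designed for: anisotropic
confocal stacks of cytoplasmic puncta — bright, roughly Gaussian,
diffraction-limited spots over a diffuse background — imaged in two
conditions that differ in spot amplitude.  Each scene carries its ground
truth (centers, amplitudes, widths and a rendered label map) so seed
detection, segmentation and brightness recovery can be scored without a
microscope.

Spots are isotropic 3D Gaussians in physical units sampled at voxel
centers; there is no further point-spread-function model.  Noise is either
additive Gaussian or Poisson shot noise plus Gaussian read noise.  All
randomness flows through :class:`numpy.random.Generator` seeded from the
scene spec, so a fixed seed gives bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import VoxelGrid

#: Rejection-sampling budget per spot when honoring min separation.
PLACEMENT_ATTEMPTS = 1000

#: Default native spacing in (z, y, x) µm: confocal stacks are coarser
#: axially, which exercises the isotropic resampling stage nontrivially.
#: The axial step is kept at twice the spot SD or finer so puncta remain
#: resolvable (a coarser z-step makes axial localization ill-posed).
DEFAULT_SPACING_UM = (0.4, 0.2, 0.2)


@dataclass
class NoiseModel:
    """Per-voxel noise.

    ``gaussian``: additive N(0, gaussian_sd²).
    ``poisson-gaussian``: signal is converted to expected photon counts at
    ``photons_per_unit``, Poisson-sampled, converted back, then Gaussian
    read noise of SD ``read_sd`` is added — so variance grows with the mean,
    as in a real detector.
    """

    kind: str = "gaussian"
    gaussian_sd: float = 0.0
    photons_per_unit: float = 1.0
    read_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson-gaussian"):
            raise ValueError(f"unknown noise model {self.kind!r}")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "gaussian":
            if self.gaussian_sd == 0:
                return clean.copy()
            return clean + rng.normal(0.0, self.gaussian_sd, clean.shape)
        counts = rng.poisson(np.clip(clean, 0, None) * self.photons_per_unit)
        out = counts / self.photons_per_unit
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, clean.shape)
        return out


@dataclass
class SyntheticSceneSpec:
    """Generative parameters of one synthetic scene.

    Amplitudes are in arbitrary fluorescence units above background; spot
    widths are the isotropic Gaussian SD in µm.  ``min_separation_um``
    must be at least twice the largest spot SD so ground-truth spots stay
    resolvable, and the dimmest spot must exceed the background.
    """

    shape_voxels: tuple[int, int, int] = (20, 64, 64)
    voxel_spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    n_spots: int = 10
    amplitude_range: tuple[float, float] = (80.0, 120.0)
    sigma_um_range: tuple[float, float] = (0.3, 0.5)
    min_separation_um: float = 1.6
    background_level: float = 10.0
    noise_model: NoiseModel = field(default_factory=lambda: NoiseModel("gaussian", gaussian_sd=5.0))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")
        if self.min_separation_um < 2 * self.sigma_um_range[1]:
            raise ValueError(
                f"min_separation_um ({self.min_separation_um}) must be >= 2 × max sigma "
                f"({2 * self.sigma_um_range[1]}) so spots are resolvable"
            )
        if self.amplitude_range[0] <= self.background_level:
            raise ValueError("amplitude_range lower bound must exceed background_level")
        if any(s <= 0 for s in self.voxel_spacing_um) or any(n < 1 for n in self.shape_voxels):
            raise ValueError("invalid grid geometry")


@dataclass
class GroundTruth:
    """Per-spot truth for one scene, plus a rendered reference label map.

    The label map assigns every voxel within 2σ of a spot center to its
    nearest center; 0 is background.
    """

    spot_centers_um: np.ndarray  # (n, 3) physical (z, y, x)
    spot_amplitudes: np.ndarray  # (n,)
    spot_sigmas_um: np.ndarray  # (n,)
    true_label_map: np.ndarray  # int, same shape as the rendered stack

    @property
    def n_spots(self) -> int:
        return len(self.spot_amplitudes)


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot honor min_separation_um."""


def _draw_centers(spec: SyntheticSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample spot centers (µm) honoring the separation constraint.

    Centers are kept 2σ_max away from the stack faces so each spot's mass
    is rendered in full.
    """
    extent = np.array([(n - 1) * s for n, s in zip(spec.shape_voxels, spec.voxel_spacing_um)])
    margin = 2 * spec.sigma_um_range[1]
    lo = np.minimum(margin, extent / 2)
    hi = np.maximum(extent - margin, extent / 2)
    centers: list[np.ndarray] = []
    for i in range(spec.n_spots):
        for _ in range(PLACEMENT_ATTEMPTS):
            c = rng.uniform(lo, hi)
            if all(np.linalg.norm(c - p) >= spec.min_separation_um for p in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place spot {i + 1}/{spec.n_spots} with "
                f"min_separation_um={spec.min_separation_um} in {PLACEMENT_ATTEMPTS} attempts"
            )
    return np.array(centers).reshape(spec.n_spots, 3)


def _voxel_center_coords(spec: SyntheticSceneSpec) -> list[np.ndarray]:
    return [
        np.arange(n) * s
        for n, s in zip(spec.shape_voxels, spec.voxel_spacing_um)
    ]


def render_clean(spec: SyntheticSceneSpec, centers: np.ndarray, amplitudes: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Background plus the sum of isotropic Gaussian spots, noise-free."""
    zc, yc, xc = _voxel_center_coords(spec)
    img = np.full(spec.shape_voxels, float(spec.background_level))
    for c, a, s in zip(centers, amplitudes, sigmas):
        dz2 = (zc - c[0]) ** 2
        dy2 = (yc - c[1]) ** 2
        dx2 = (xc - c[2]) ** 2
        r2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        img += a * np.exp(-r2 / (2 * s**2))
    return img


def render_true_labels(spec: SyntheticSceneSpec, centers: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Reference label map: nearest center within 2σ of it, else 0."""
    labels = np.zeros(spec.shape_voxels, dtype=np.int32)
    if len(centers) == 0:
        return labels
    zc, yc, xc = _voxel_center_coords(spec)
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    pos = np.stack([zz, yy, xx], axis=-1)  # (Z, Y, X, 3)
    d2 = np.stack([np.sum((pos - c) ** 2, axis=-1) for c in centers])  # (n, Z, Y, X)
    nearest = np.argmin(d2, axis=0)
    within = np.take_along_axis(d2, nearest[None], axis=0)[0] <= (2 * sigmas[nearest]) ** 2
    labels[within] = nearest[within] + 1
    return labels


def generate_stack(spec: SyntheticSceneSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Render one ground-truthed synthetic stack.

    Deterministic for a fixed ``spec.rng_seed``; raises
    :class:`PlacementError` if the separation constraint cannot be honored.
    """
    rng = np.random.default_rng(spec.rng_seed)
    centers = _draw_centers(spec, rng)
    amplitudes = rng.uniform(*spec.amplitude_range, size=spec.n_spots)
    sigmas = rng.uniform(*spec.sigma_um_range, size=spec.n_spots)
    clean = render_clean(spec, centers, amplitudes, sigmas)
    noisy = spec.noise_model.apply(clean, rng)
    truth = GroundTruth(centers, amplitudes, sigmas, render_true_labels(spec, centers, sigmas))
    return VoxelGrid(noisy, spec.voxel_spacing_um), truth


def generate_two_condition_experiment(
    spec: SyntheticSceneSpec,
    amplitude_scale: float,
    n_stacks_per_group: int,
) -> tuple[list[tuple[VoxelGrid, GroundTruth]], list[tuple[VoxelGrid, GroundTruth]]]:
    """Paired two-condition experiment (e.g. wild-type vs mutant).

    Group B stacks share group A's geometry (same centers and widths, one
    scene per stack index) but every spot amplitude is multiplied by
    ``amplitude_scale``; noise realizations are independent between groups.
    Per-stack substreams derive deterministically from ``spec.rng_seed``.
    """
    if amplitude_scale <= 0:
        raise ValueError("amplitude_scale must be positive")
    if n_stacks_per_group < 1:
        raise ValueError("n_stacks_per_group must be at least 1")
    group_a: list[tuple[VoxelGrid, GroundTruth]] = []
    group_b: list[tuple[VoxelGrid, GroundTruth]] = []
    root = np.random.SeedSequence(spec.rng_seed)
    for stack_ss in root.spawn(n_stacks_per_group):
        scene_ss, noise_a_ss, noise_b_ss = stack_ss.spawn(3)
        scene_rng = np.random.default_rng(scene_ss)
        centers = _draw_centers(spec, scene_rng)
        amplitudes = scene_rng.uniform(*spec.amplitude_range, size=spec.n_spots)
        sigmas = scene_rng.uniform(*spec.sigma_um_range, size=spec.n_spots)
        labels = render_true_labels(spec, centers, sigmas)
        for group, scale, noise_ss in zip(
            (group_a, group_b), (1.0, amplitude_scale), (noise_a_ss, noise_b_ss)
        ):
            amps = amplitudes * scale
            clean = render_clean(spec, centers, amps, sigmas)
            noisy = spec.noise_model.apply(clean, np.random.default_rng(noise_ss))
            group.append(
                (
                    VoxelGrid(noisy, spec.voxel_spacing_um),
                    GroundTruth(centers, amps, sigmas, labels),
                )
            )
    return group_a, group_b


def true_labels_on_grid(grid: VoxelGrid, truth: GroundTruth) -> np.ndarray:
    """Render the ground-truth label map at another grid's geometry.

    Same rule as :func:`render_true_labels` (nearest center within 2σ),
    evaluated at the given grid's voxel centers — used to score a
    segmentation produced at a different (e.g. resampled) resolution.
    """
    labels = np.zeros(grid.shape, dtype=np.int32)
    if truth.n_spots == 0:
        return labels
    axes = [
        o + np.arange(n) * s
        for o, n, s in zip(grid.origin_um, grid.shape, grid.spacing_um)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pos = np.stack([zz, yy, xx], axis=-1)
    d2 = np.stack([np.sum((pos - c) ** 2, axis=-1) for c in truth.spot_centers_um])
    nearest = np.argmin(d2, axis=0)
    within = (
        np.take_along_axis(d2, nearest[None], axis=0)[0]
        <= (2 * truth.spot_sigmas_um[nearest]) ** 2
    )
    labels[within] = nearest[within] + 1
    return labels


# --------------------------------------------------------------------------
# Packaged sequence fixtures for the allele-consequence module
# --------------------------------------------------------------------------

#: Wild-type ZFN target region of the kif7 coding sequence (cds nt 729–765).
#: The region starts mid-codon: translation skips 1 base, and the first
#: complete codon encodes S at protein position 244.
WILD_TYPE_REGION = "ATCCAAATTCCATTTTGTGGACCTGGCAGGATCAGAG"

#: Mutant allele amplicons.  Each deletion allele reads through the 3' end
#: of the wild-type target region into downstream coding sequence.
ALLELE_SEQUENCES = {
    "i271": "ATCCAAATTCCATTTTGTCAGGATCAGAGCGCATCCTTAA",
    "i272": (
        "ATCCAAATTCCATTCCTGGCAGGATCAGAGCGCATCCTTAAAACCGGCAACACCGGCGAACGGCTCAAG"
        "GAGAGCATTCAGATCAACAGTGGACTTCTTGTTCTTGGAAATGTCATTGGAGCGCTTGGGGACCCCAAA"
        "AGAAAAGGCACCCATATCCCATACAGGGATTCAAAAATCACCAGGATCTTAA"
    ),
    "i273": "ATCCAAATTCCATTTTGTCCTGGCAGGATCAGAG",
}

#: Frame anchor shared by all fixtures: (cds coordinate of the first
#: printed base, bases to skip before the first complete codon, protein
#: position and identity of that codon).
FRAME_ANCHOR = {"cds_start_nt": 729, "frame_offset": 1, "first_residue_number": 244, "first_residue": "S"}


def packaged_allele_fixtures() -> dict[str, tuple[str, str, dict]]:
    """Mapping allele name -> (wild-type sequence, mutant sequence, frame anchor)."""
    return {
        name: (WILD_TYPE_REGION, seq, dict(FRAME_ANCHOR))
        for name, seq in ALLELE_SEQUENCES.items()
    }
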