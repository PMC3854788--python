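# Methods

`spotquant` quantifies the brightness of discrete fluorescent puncta in
3D confocal stacks and compares protein levels between genotypes, and it
annotates the protein consequences of nuclease-induced indel alleles.
This note records the models, the parameters that matter, and the design
choices made where more than one reasonable realization existed.

## Image model and pre-processing

A stack is a scalar intensity field I on a voxel grid with physical
spacing (z, y, x) in µm; positions refer to voxel centers, indices are
0-based in (z, y, x) order. Pre-processing runs in a fixed, logged order:

1. **Isotropic resampling** to a target spacing (default **0.2 µm**) by
   trilinear interpolation, implemented as one linear pass per axis in
   the lerp form `a + t·(b − a)`. That form is exactly
   constant-preserving and exactly the identity at on-grid coordinates,
   which makes the resampling contracts testable to the last bit. The
   output axis length preserves the physical extent to within one voxel.
2. **Gaussian denoising** with SD default **0.3 µm** — the matched-filter
   width for the smallest puncta the pipeline is designed to detect
   (spot SD ≈ 0.3 µm). Convolutions use reflect padding, which preserves
   the local mean at stack faces.
3. **Histogram enhancement** as a global affine percentile stretch: the
   low percentile maps to 0, the high percentile to the previous
   maximum, values outside are clipped. Defaults **(50, 100)**: puncta
   are sparse, so the median estimates the diffuse background, and
   removing that pedestal is what lets per-spot brightness ratios track
   true amplitude ratios. The top percentile is deliberately 100 (no
   saturation): clipping bright cores into plateaus would, after the
   Laplacian step, surround every spot with a ring of spurious maxima
   and destroy seed localization. An affine stretch (rather than, say,
   histogram equalization) is required so that downstream brightness
   ratios are not distorted by a non-linear intensity map.
4. **Laplacian boundary enhancement**: `I − w·∇²I` with the 6-neighbor
   stencil, weight default **1.0**, clipped at 0. Sharpens segment
   boundaries; flat regions are unchanged.
5. **Normalization** by the global maximum, so sup I = 1. Idempotent;
   an all-zero stack is an error.

Every stage is deterministic; re-running a pipeline with an identical
manifest reproduces outputs byte for byte.

## Seeding and segmentation

**Seeds.** Spot centers are the 26-neighborhood local maxima of the
normalized stack with intensity ≥ `h_min` (default **0.1**). An
equal-valued plateau bounded by strictly lower voxels contributes a
single seed at its intensity-weighted centroid rounded to the nearest
voxel (hence a constant stack has no seeds). Maxima closer than
`min_separation_um` (default **0.4 µm**) are merged keeping the
brighter, ties resolving to the smaller lexicographic index. Seed
detection runs on max-normalized data, so it is invariant to overall
intensity scale. In the workflow, seeds below the foreground threshold
(noise maxima) are dropped before segmentation.

**Foreground.** Default: Otsu's threshold on the normalized stack,
overridable. Nothing in the imaging defines "the" foreground; Otsu is a
standard parameter-free choice and is exposed in the config.

**Partition.** The foreground is divided among seeds by competitive
geodesic front propagation — an evolving generalized Voronoi partition.
The cost of a front entering voxel x is

    step_length × (1 + λ·(1 − I(x))),    λ default 5,

with 26-neighborhood moves and Euclidean step lengths in voxels. Fronts
race cheaply through bright voxels and stall in dim ones, so segment
boundaries settle on the intensity ridges between spots. A voxel joins
the seed of minimal geodesic arrival cost; exact ties go to the smaller
seed index, making the output deterministic.

Two properties follow from the metric being *shared* by all fronts, and
both are load-bearing: (i) every voxel on a winning shortest path is
itself won by the same seed, so each segment is a single 26-connected
region containing its seed; (ii) simultaneous propagation is exactly
equivalent to computing one geodesic distance field per seed and taking
the per-voxel argmin — which is how the implementation computes it
(per-seed Dijkstra over the foreground adjacency graph via
`scipy.sparse.csgraph`), and how the independent test oracle re-derives
it. A seed-*dependent* cost (e.g. penalizing descent below each seed's
own intensity) was considered and rejected: under per-seed metrics the
argmin partition can produce disconnected cells, which violates the
connected-region definition the partition is meant to satisfy.

Foreground voxels unreachable from every seed (isolated dim islands)
remain background and are counted, so the partition identity
Σ|S_l| + |unreachable| = |foreground| always holds.

**Per-spot support trimming.** A single global threshold cannot delimit
an "n·σ" support for every spot at once when widths and amplitudes vary:
the intensity level at which a processed spot's profile passes n·σ is a
per-spot fraction of its own peak. For experiments that compare segments
against a fixed 2σ spot-extent convention, `trim_segments_to_support`
restricts each Voronoi cell to its spot's predicted support: the
processed width σ′ is estimated from the half-maximum radius around the
seed, converted to the pre-smoothing SD via σ′² = σ² + s², and the
support level follows the closed form

    f(nσ)/f(0) = exp(−n²σ²/(2σ′²)) · (1 + w_p(3σ′² − n²σ²)/σ′⁴) / (1 + 3w_p/σ′²)

for smoothing SD s and Laplacian weight w (w_p = w·h², h the voxel
edge). The plain partition remains the pipeline output for
quantification; trimming is a measurement-convention adapter, computed
from detected seeds only.

## Brightness and group comparison

Per-spot brightness is the mean of normalized intensity over the
segment's voxels, B_l = (Σ_{x∈S_l} I(x)) / |S_l|, with the physical
volume (|S_l| × h³ µm³) reported separately so a per-µm³ variant is a
constant rescale. Group summaries pool spots across a condition's stacks
and report the mean and the sample SD (n−1) across spots; the SD across
spots, not voxels, is what the error bars of a per-spot quantification
represent. Per-stack means are retained as a secondary output so
alternative poolings can be computed. The fold change between two
conditions is the ratio of group means.

**Cohort normalization.** Dividing each stack by its own maximum erases
genuine between-condition intensity differences — two stacks whose spots
differ two-fold become identical after per-stack normalization. Group
comparisons therefore push every stack of the cohort through *one*
intensity map: the histogram stretch uses percentiles pooled over all
stacks, and the final division uses the single cohort-wide maximum.
(Per-stack enhancement would not suffice: its gain `max/(max − low)`
differs between bright and dim stacks and biases the recovered ratio by
exactly that gain ratio.) Segmentation geometry, by contrast, is always
computed on each stack's own normalized copy, so the partition is
identical across normalization modes and the mode changes only the
intensities entering the brightness sum. Per-stack mode remains the
default for single-stack analyses.

## Synthetic scenes

The generator emulates what the pipeline is built for: anisotropic
confocal stacks of bright, roughly Gaussian, diffraction-limited-to-small
puncta over a diffuse background, imaged under two conditions differing
only in spot amplitude.

Defaults (one scene): grid 20×64×64 voxels at (0.4, 0.2, 0.2) µm (z
coarser than x/y, so resampling is exercised nontrivially, while staying
at or under twice the smallest spot SD — a coarser z-step would make
axial localization ill-posed for sub-µm puncta); 10 spots; amplitudes
uniform in 80–120 AU over a background of 10 AU; isotropic spot SD
uniform in 0.3–0.5 µm; minimum center separation 1.6 µm (≥ 2× the
largest SD, so ground-truth spots stay resolvable); additive Gaussian
noise with SD 5 AU, or Poisson shot noise (1 photon/AU) plus Gaussian
read noise (SD 2 AU) — both give a peak SNR comfortably above 5.
Spot centers are rejection-sampled (1000 attempts per spot, failure is
an error naming the separation constraint) with a 2σ_max margin from
stack faces. All randomness flows through `numpy.random.Generator`
(PCG64) seeded from the scene spec; two-condition experiments derive
per-stack and per-group noise substreams from one root `SeedSequence`,
so a fixed seed is bit-reproducible.

Ground truth stores centers, amplitudes, SDs, and a reference label map
(voxels within 2σ of a center, nearest-center assignment). What the
generator does **not** model: PSF anisotropy and diffraction sidelobes,
cilium axonemes or any elongated structures, spatially varying
background, bleaching, chromatic or drift artifacts, and spot shape
deviations from isotropic Gaussians. Passing the recovery tests
therefore demonstrates correctness of the measurement chain under the
stated model, not robustness to every property of real tissue images.

## Allele consequences

The wild-type nuclease target region (cds nt 729–765) is carried with a
frame anchor: translation skips 1 base and the first complete codon is
S244. Mutant amplicons are compared against the region by flank
alignment: the most parsimonious single contiguous event (deletion,
insertion, or replaced block) whose flanks match; placements ambiguous
within repeats resolve leftmost by default (matching how the deleted
bases are conventionally reported), with the HGVS-style 3' (rightmost)
rule available. Mutant reads extending past the region's 3' end are
recorded as readthrough tail on the call, so applying a call to the
wild type reproduces the mutant string exactly. A same-length replaced
block that agrees with the reference at interior positions is multiple
substitutions, not one event, and is rejected as a complex allele; the
error names both mismatch loci.

Protein consequences are derived at protein level: indels with length
not divisible by 3 are frameshifts, annotated `<ref><pos><alt>fsX<k>`
from the first diverging residue, where k counts residues from the first
altered residue (=1) to the new stop inclusive ("fsX" spelling, not
HGVS "fsTer"); if no stop occurs within the sequenced region the offset
is reported as unknown rather than invented. In-frame events are
resolved by a leftmost protein-level diff, which names
codon-boundary-straddling deletions correctly (e.g. GTG-GAC → GTC
deletes one Asp even though no single codon is excised). Translation
uses the standard code, drops trailing partial codons, and includes the
first stop as `*`.

## Numerical and testing choices

- Tie-breaks are total and documented: seed merge (brighter, then
  lexicographic), front arrival (smaller seed index), protein diff
  (leftmost). The pipeline contains no hidden randomness.
- The segmentation oracle in the test suite is an independent
  pure-Python per-seed Dijkstra; equality is exact (same float
  fixed-point), including constructed uniform-cost tie cases.
- The brightness oracle is an independent per-voxel accumulation loop;
  equality is to machine precision on random label maps.
- Recovery experiments use compact scenes (a few spots, ≤ 20×64×64
  native voxels) and a handful of seeds per condition so the whole
  suite stays fast; the fold-change experiment uses amplitude scales
  {0.25, 0.5, 0.8} with 3 stacks per group and 10 spots per stack.
- Degenerate inputs are first-class: constant stacks (no seeds, warned
  no-op stretch), empty scenes (empty outputs plus a warning), all-zero
  stacks (error), seeds below threshold (error naming the seed).

## Known limitations

- The EGVD realization is a geodesic front-propagation approximation of
  the cited curve-evolution formulation; boundary placement on ridges
  and one-segment-per-seed behavior are preserved, exact numerics of
  the original are not.
- Brightness is reported on normalized scales; absolute fluorescence
  calibration is out of scope.
- The indel caller targets the single-contiguous-event regime of
  short amplicon genotyping; it does not align chromatograms, phase
  heterozygotes, or annotate against transcript models.
- Cohort normalization assumes all stacks were acquired with identical
  settings; it cannot correct for gain differences between sessions.
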