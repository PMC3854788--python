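# spotquant

Quantification of fluorescent puncta in 3D confocal stacks, and protein
consequences of nuclease-induced indel alleles.

Hedgehog-pathway kinesins such as Kif7 accumulate in discrete cytoplasmic
puncta and at cilia tips; comparing their levels between genotypes means
segmenting hundreds of small bright spots in anisotropic confocal stacks
and measuring each spot's brightness on a scale that survives
normalization. `spotquant` implements that measurement chain for
microscopists and developmental biologists:

1. **Pre-processing** — resample to isotropic 0.2 µm voxels (trilinear),
   Gaussian denoising, histogram-based contrast enhancement, Laplacian
   boundary sharpening, max-normalization.
2. **Spot segmentation** — local maxima of the normalized intensity I(x)
   become seeds; the thresholded foreground Ω is partitioned by evolving
   generalized Voronoi fronts: voxel x joins the seed s minimizing the
   geodesic cost ∫(1 + λ(1 − I)) dℓ, so boundaries fall on intensity
   ridges and every segment S_l is a connected region.
3. **Quantification** — per-spot average brightness
   B_l = (Σ_{x∈S_l} I(x)) / |S_l|, group mean ± SD across spots, and the
   between-genotype fold change of group means under a shared ("cohort")
   normalization.
4. **Allele annotation** — deletion/insertion calls from amplicon
   sequences against a wild-type target region, translated into
   frameshift (`D250RfsX7`) or in-frame (`D250del`) protein notation.

A ground-truthed synthetic-scene generator (Gaussian puncta, Gaussian or
Poisson-Gaussian noise, two-condition experiments) makes every stage
testable without a microscope. `docs/methods.md` describes the models
and parameter choices in detail.

## Worked example: two-fold reduction between genotypes

Simulate a wild-type-like and a mutant-like group (mutant spot
amplitudes halved), run the full pipeline, and recover the ratio:

```python
import spotquant as sq

spec = sq.SyntheticSceneSpec(n_spots=10, rng_seed=7)
wt, mut = sq.generate_two_condition_experiment(spec, amplitude_scale=0.5,
                                               n_stacks_per_group=3)
result = sq.run_image_pipeline(
    {"wild-type": [g for g, _ in wt], "mutant": [g for g, _ in mut]},
    normalization="cohort", reference_group="wild-type",
)
for s in result.summaries:
    print(f"{s.group_name}: n_spots={s.n_spots}  "
          f"mean={s.mean_of_spot_brightness:.4f}  sd={s.sd_of_spot_brightness:.4f}")
print(f"fold change (wild-type / mutant): {result.fold_change:.3f}")
```

prints

```
wild-type: n_spots=30  mean=0.3607  sd=0.0316
mutant: n_spots=30  mean=0.1820  sd=0.0160
fold change (wild-type / mutant): 1.981
```

Thirty spots per group were segmented; mean spot brightness (normalized
units) dropped from 0.361 ± 0.032 to 0.182 ± 0.016, a recovered fold
change of 1.98 against the simulated ground truth of 2.0. The same
comparison under `normalization="per-stack"` returns ≈ 1.0 — per-stack
max-normalization erases between-group differences, which is why group
comparisons use the cohort mode.

## Worked example: allele consequences

```sh
spotquant alleles kif7_alleles.fasta --out out/
```

on a FASTA containing the packaged wild-type target region
(`sq.packaged_allele_fixtures()`) and the three mutant amplicons prints

```
allele     kind  position_nt  length_nt ref_allele   notation                                              mutant_peptide
  i271 deletion          747          8   GGACCTGG  D250RfsX7                                                     RIRAHP*
  i272 deletion          743          7    TTGTGGA F248SfsX59 SWQDQSASLKPATPANGSRRAFRSTVDFLFLEMSLERLGTPKEKAPISHTGIQKSPGS*
  i273 deletion          747          3        GGA    D250del
```

i271 and i272 are frameshifts truncating the protein after 7 and 59
novel codons respectively; i273 removes a single aspartate in-frame,
across a codon boundary.

The CLI also provides `simulate`, `preprocess`, `segment`, `quantify`
and `compare` subcommands (`spotquant --help`); every subcommand is a
thin wrapper over a library function and writes a JSON run manifest.

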