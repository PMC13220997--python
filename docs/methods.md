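# Methods

## Problem and approach

`leaftex` quantifies the texture complexity of leaf abaxial surfaces from
stomata-annotated grayscale electron micrographs and turns it into a
species-level score. The pipeline treats complexity not as a single
hand-picked statistic but as the outcome of a pairwise game: patches from
different species are repeatedly compared on three interpretable texture
features, the wins are accumulated per species, and a Bradley–Terry model
condenses them into one ability per species. Around that core sit a patch
sampler, a full texture feature bank with a kNN species classifier (a
sanity check that the features actually carry species identity), a
significance-based grouping of species into complexity classes, and
rank-robustness diagnostics.

## Patch sampling

Stomata centers are inputs (produced upstream by any detector). For each
micrograph, 120 sub-images of 80 µm × 80 µm are drawn around uniformly
chosen non-excluded stomata and resized to 512×512 px by bilinear
interpolation (anti-aliasing when downscaling). In `whole_leaf` mode the
window center jitters uniformly within ±half a patch of the stoma per
axis; this guarantees each patch contains its anchor while covering
surrounding texture. `roi` mode centers the window on the stoma. Windows
are clipped to lie fully inside the image; overlapping patches are allowed
— with 120 windows from one micrograph, disjointness is not achievable.
Balancing then downsamples to a fixed per-species quota (default 480,
benchmark scale 240), stratified round-robin over source images so
per-image counts differ by at most one.

## Features

Per 512×512 patch:

* **GLCM block** — intensities linearly quantized to 64 levels; symmetric
  normalized co-occurrence matrices at offsets {1, 2, 4} px ×
  {0°, 45°, 90°, 135°} (Euclidean offsets, i.e. diagonal distance d
  displaces round(d/√2) per axis, as in `skimage`); ASM, contrast,
  entropy (log₂), homogeneity and correlation are averaged over the 12
  offsets (isotropic). A constant patch yields ASM = 1, entropy = 0, and
  correlation defined as 0.
* **Spectral block** — per patch, mean-subtracted 2-D FFT, log₁₀(1+power),
  radially averaged into 64 equal-width frequency bins up to Nyquist (DC
  excluded; rotation-invariant by construction); PCA fitted on training
  patches reduces the 64-vector to 25 scores. The PCA uses the population
  covariance with a deterministic sign convention (largest-magnitude
  loading positive), so refits are reproducible and duplication of the
  training set leaves the model unchanged. The model is frozen after
  fitting; later data is only projected.
* **Gradient block** — 3×3 Sobel with reflect borders; mean and population
  standard deviation of the gradient magnitude.
* **Information density** — DEFLATE (zlib level 9) of the raw row-major
  bytes, expressed as bits per pixel. Compressing the raw byte stream
  rather than a container file removes encoder-metadata nondeterminism
  while preserving the ordinal content of a file-size measurement.

The **complexity triplet** driving the ranking game is
(info_density = compression bpp, heterogeneity = 1 − ASM,
variability = gradient std). 1 − ASM is preferred over 1/ASM because it is
bounded on near-constant patches; any strictly monotone transform yields
identical duel outcomes.

## Classification

Species identity is checked by 3-NN with Euclidean distance on the full
feature block. Validation is grouped: all patches of one source image (or
leaf, or tree) share a fold, with species-stratified round-robin
assignment, so accuracy measures generalization to unseen imaging areas.
The spectral PCA is refit inside each training fold — never on test data.

Standardization is deliberately not a flat per-column z-score. Scalar
features with heterogeneous units (GLCM statistics, gradient stats, bpp)
are z-scored individually. The 25 spectral scores share one unit and are
variance-ordered by construction; z-scoring each would inflate the minor
components — which carry almost no variance and mostly patch noise — to
the same weight as the leading ones and swamp the distance metric (on the
benchmark this costs ~35 accuracy points). They are therefore centered
per column and scaled by a single pooled standard deviation, which keeps
the block's total weight equal to that of z-scored columns while
preserving the components' natural relative scale.

Vote ties are resolved by summed inverse neighbor distance, then by
lexicographically smallest species label, making predictions fully
deterministic.

## Tournament and Bradley–Terry scoring

For every unordered species pair, 1000 patch pairs are drawn uniformly
with replacement (exhaustive all-against-all available for small data).
Each match compares the three triplet features independently: the strictly
greater value takes that feature's point; exact equality splits it. Win
credit accumulates into a species×species matrix; a per-patch win fraction
(points won / points contested) is retained as the per-sample complexity
scalar for the grouping stage. Per-feature points are the default because
each feature is meant to contribute its own evidence; a majority-of-three
mode exists for sensitivity analysis.

Bradley–Terry abilities (P(i beats j) = π_i/(π_i+π_j)) are fitted by
minorization–maximization on the win credits, with a 0.5 pseudocount per
ordered pair so the MLE exists even under total domination. Convergence is
max |Δ log π| < 1e-10; the iteration cap is 10⁶ because the MM map
converges linearly and near-dominant win matrices routinely need ~10⁵
cheap O(n²) iterations at this tolerance. Abilities are normalized to
Σ log π = 0; the score is the min–max rescaled log-ability in [0, 1]
(0.5 for all species in the fully degenerate equal-ability case), and
rank 1 is the least complex species, ties broken lexicographically.

## Complexity groups

All species pairs are tested with the two-sample Kruskal–Wallis rank test
(tie-corrected, χ² approximation, df = 1) on per-patch win fractions;
p-values are Benjamini–Hochberg adjusted across the pair family (raw-p and
parametric one-way ANOVA modes available). Species are merged by
average-linkage hierarchical clustering on d = −log₁₀(max(p_adj, 1e−16)),
cutting at −log₁₀(alpha) with alpha = 0.05, so pairs indistinguishable at
level alpha tend to co-group. The number of groups is emergent, never
forced. Group labels are ordered by ascending median species score.

## Stability diagnostics

* **Bootstrap**: 20 replicates, each keeping 80% of patches per species
  (without replacement, preserving class balance), tournament pairings
  redrawn with replicate-derived seeds (master seed + replicate index),
  full refit, Spearman ρ against the full-data ranking, plus per-species
  rank variance.
* **Feature leave-one-out**: the tournament is rerun on each 2-feature
  subset of the triplet; Spearman ρ against the 3-feature ranking measures
  how much any single feature drives the result.

## Synthetic data generator

The generator emulates per-species leaf-surface textures with a single
ground-truth complexity parameter c ∈ [0, 1] mapped monotonically to:
spectral slope β = 3 − 2c of a 1/f^β Gaussian random field; papilla
density 30c per 100 µm² (Gaussian bumps, nominal radius 1.5 µm, rendered
with σ = radius/2 so the visible extent matches the radius, amplitude 35
gray levels); wrinkle amplitude 20c gray levels (two sinusoidal gratings
with random orientation and 30–60 µm wavelength); i.i.d. sensor noise
(σ = 4). Stomata are rendered as dark ellipses (8×4 µm, intensity ×0.35,
6 per 10⁴ µm² Poisson) and their centers returned as annotations, so both
sampling modes see realistic anchors.

The composed structure field is renormalized to mean 128 / sd 30 *before*
stomata and noise are added. This keeps complexity expressed through
texture structure rather than dynamic range: without it, dense papilla
fields clip at 255 and become more compressible than simple textures,
breaking the ground-truth monotonicity the generator exists to provide.

What the generator does *not* emulate: multilayered wax plates, trichomes,
stomatal dimorphism, charging/contrast artifacts of real electron
micrographs, or between-tree biological variation. Passing tests on
synthetic data therefore demonstrate correctness and internal consistency
of the method, not field-readiness on real micrographs.

## Benchmark scale and defaults

The default benchmark is 10 species with c evenly spaced in [0.05, 0.95],
4 micrographs per species (2048 px at 0.2 µm/px), 120 patches per image,
balanced to 240 patches per species (2400 total) — large enough that the
classification, stability and leave-one-out regimes are meaningful, small
enough to run on a single CPU in a few minutes. Grouped cross-validation
uses 4 folds (leave-one-image-out per species). All randomness flows from
one master seed; stage seeds are derived deterministically, and reruns are
byte-identical.

## Known limitations

* The per-sample complexity scalar entering the Kruskal–Wallis tests is
  the tournament win fraction; with very unequal patch counts per species
  its variance differs between species.
* Bradley–Terry assumes transitive abilities; strongly non-transitive
  feature structure would be summarized, not detected. The per-feature
  leave-one-out report is the provided diagnostic.
* The pseudocount (0.5 per ordered pair) slightly shrinks extreme ability
  ratios; with 1000 matches per pair the effect on ranks is negligible.
* kNN accuracy depends on the standardization choice discussed above;
  with many informative feature blocks of similar quality the block
  scaling and plain z-scoring converge.
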