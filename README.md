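# leaftex

Quantifying leaf-surface texture complexity from electron micrographs.

Tree leaf surfaces — cuticular wax films, papillae, wrinkles, wax plates —
differ strikingly between species, and that microtopography matters for
everything that lands on a leaf, from fungal spores to aerosols. `leaftex`
turns stomata-annotated grayscale micrographs of the leaf underside into a
single, comparable **texture complexity score per species**, plus the
diagnostics needed to trust it.

## Method

From each micrograph, 80 µm × 80 µm patches are sampled around annotated
stomata and resized to 512×512 px. Each patch yields a texture feature
bank — isotropic gray-level co-occurrence (GLCM) statistics, 25 PCA
components of the radially averaged Fourier log-power spectrum, Sobel
gradient statistics, and lossless-compression information density (bits
per pixel) — validated by a grouped-CV 3-nearest-neighbor species
classifier.

The complexity score itself comes from a pairwise game on the triplet

> info density = compression bpp, heterogeneity = 1 − ASM,
> variability = gradient σ,

each monotone in perceived complexity. Patches of different species are
repeatedly pitted against each other; the greater value takes each
feature's point. Species-level win counts w_ij are condensed by a
Bradley–Terry model, P(i beats j) = π_i / (π_i + π_j), fitted by
minorization–maximization; the min–max normalized log π is the complexity
score in [0, 1] and rank 1 is the least complex species. Species whose
per-patch complexity distributions are indistinguishable (pairwise
Kruskal–Wallis, BH-adjusted, hierarchical clustering on −log₁₀ p) share a
complexity group, and bootstrap resampling plus feature leave-one-out
quantify rank robustness.

A synthetic micrograph generator with a ground-truth complexity parameter
c (spectral slope, papilla density, wrinkle amplitude all monotone in c,
with rendered stomata) makes the entire pipeline runnable and testable
with no imaging data. See `docs/methods.md` for details and assumptions.

## Worked example

```sh
leaftex simulate bench --n-species 10 --seed 42   # 40 synthetic micrographs
leaftex run --manifest bench/manifest.csv --annotations bench/annotations.csv \
            --out-dir results --seed 42
```

or through the library (smaller numbers for brevity):

```python
from leaftex.benchmark import run_benchmark

result = run_benchmark(seed=42)          # default 10-species benchmark
print(result.scores[["species", "score", "rank"]].to_string(index=False))
```

```
  species    score  rank
species01 0.000000     1
species02 0.117966     2
species03 0.195417     3
species04 0.339517     4
species05 0.541032     5
species06 0.794916     6
species07 0.893048     7
species08 0.980041     8
species09 0.995957     9
species10 1.000000    10
```

The ten synthetic species were generated with complexity parameter c
evenly spaced from 0.05 (species01) to 0.95 (species10); the fitted
ranking recovers that ordering exactly, and the score spacing reflects how
decisively each species wins its pairwise comparisons.
`result.classification.accuracy` reports the grouped-CV species
classification accuracy (0.964 on this benchmark),
`result.bootstrap.rho_mean` the bootstrap rank stability (0.996), and
`result.leave_one_out.rho` the per-feature leave-one-out rank agreement.

On real data, point `leaftex run` at a manifest CSV (image paths, species,
tree/leaf/batch labels, µm-per-pixel) and a stomata-annotation CSV; all
artifacts — feature tables, win matrix, score table with groups, stability
reports, resolved config — are written as CSV/JSON to the output
directory, byte-reproducible given the seed.

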