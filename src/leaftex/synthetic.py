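"""Synthetic leaf-surface micrographs with ground-truth complexity ordering.

Each species is driven by a single complexity parameter c ∈ [0, 1] mapped
monotonically to several texture ingredients:

* a 1/f^β Gaussian random field base texture with spectral slope
  β = 3 − 2c (steep and smooth at low c, flat and rough at high c);
* papillae — Gaussian bumps at Poisson locations with density 30c per
  100 µm² and radius 1.5 µm;
* low-frequency sinusoidal wrinkles of amplitude 20c gray levels;
* i.i.d. Gaussian sensor noise (σ = 4 gray levels).

Stomata are rendered as dark ellipses (8 × 4 µm) at Poisson locations
(6 per 10⁴ µm²) and their centers are returned as annotations, so
stomata-anchored sampling works exactly as on real data. Higher c yields
higher information density, heterogeneity and gradient variability, giving
an unambiguous ground-truth complexity ordering for rank-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .io_annot import Manifest, Micrograph, StomaAnnotation, write_annotations, \
    write_manifest

PAPILLA_AMPLITUDE = 35.0  # gray levels at bump center
STOMA_DARKENING = 0.35  # multiplicative intensity inside the stoma ellipse
WRINKLE_WAVELENGTH_UM = (30.0, 60.0)


@dataclass
class SpeciesSpec:
    """Texture parameters of one synthetic species, all monotone in complexity_c."""

    name: str
    complexity_c: float
    papilla_radius_um: float = 1.5
    stomata_density: float = 6.0  # per 10^4 µm²
    noise_sd: float = 4.0
    spectral_slope_beta: float = field(init=False)
    papilla_density: float = field(init=False)  # per 100 µm²
    wrinkle_amplitude: float = field(init=False)  # gray levels

    def __post_init__(self) -> None:
        if not 0.0 <= self.complexity_c <= 1.0:
            raise ValueError(f"complexity_c must be in [0, 1], got {self.complexity_c}")
        self.spectral_slope_beta = 3.0 - 2.0 * self.complexity_c
        self.papilla_density = 30.0 * self.complexity_c
        self.wrinkle_amplitude = 20.0 * self.complexity_c


def _power_law_field(size_px: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with power spectrum ∝ 1/f^β, zero mean, unit sd."""
    white = rng.standard_normal((size_px, size_px))
    f = np.fft.fft2(white)
    fr = np.fft.fftfreq(size_px)[:, None]
    fc = np.fft.fftfreq(size_px)[None, :]
    radius = np.sqrt(fr * fr + fc * fc)
    radius[0, 0] = np.inf  # kill DC
    amplitude = radius ** (-beta / 2.0)
    field = np.real(np.fft.ifft2(f * amplitude))
    sd = field.std()
    return field / sd if sd > 0 else field


def _gaussian_bump(sigma_px: float) -> np.ndarray:
    half = max(1, int(np.ceil(3 * sigma_px)))
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax * ax) / (2 * sigma_px * sigma_px))
    return np.outer(g1, g1)


def generate_micrograph(
    spec: SpeciesSpec,
    size_px: int = 2048,
    pixel_size_um: float = 0.2,
    seed: int = 0,
    image_id: str | None = None,
    tree_id: str = "t1",
    leaf_id: str = "l1",
    batch_id: str = "b1",
) -> tuple[Micrograph, list[StomaAnnotation]]:
    """Render one synthetic micrograph and its stomata annotations."""
    rng = np.random.default_rng(seed)
    side_um = size_px * pixel_size_um
    area_um2 = side_um * side_um

    structure = 30.0 * _power_law_field(size_px, spec.spectral_slope_beta, rng)

    # papillae: fixed-kernel Gaussian bumps at Poisson locations
    n_pap = rng.poisson(spec.papilla_density * area_um2 / 100.0)
    if n_pap > 0:
        # sigma = half the nominal radius, so the bump's visible extent
        # (≈2 sigma) matches papilla_radius_um
        bump = PAPILLA_AMPLITUDE * _gaussian_bump(
            0.5 * spec.papilla_radius_um / pixel_size_um
        )
        half = bump.shape[0] // 2
        rows = rng.integers(size_px, size=n_pap)
        cols = rng.integers(size_px, size=n_pap)
        papillae = np.zeros_like(structure)
        for r, c in zip(rows, cols):
            r0, r1 = max(0, r - half), min(size_px, r + half + 1)
            c0, c1 = max(0, c - half), min(size_px, c + half + 1)
            papillae[r0:r1, c0:c1] += bump[
                r0 - (r - half) : bump.shape[0] - ((r + half + 1) - r1),
                c0 - (c - half) : bump.shape[1] - ((c + half + 1) - c1),
            ]
        structure += papillae - papillae.mean()

    # two low-frequency sinusoidal wrinkle gratings
    if spec.wrinkle_amplitude > 0:
        yy, xx = np.mgrid[0:size_px, 0:size_px].astype(float) * pixel_size_um
        for _ in range(2):
            theta = rng.uniform(0, np.pi)
            wavelength = rng.uniform(*WRINKLE_WAVELENGTH_UM)
            phase = rng.uniform(0, 2 * np.pi)
            proj = xx * np.cos(theta) + yy * np.sin(theta)
            structure += (spec.wrinkle_amplitude / 2.0) * np.sin(
                2 * np.pi * proj / wavelength + phase
            )

    # fix the overall contrast so complexity is carried by texture structure,
    # not dynamic range: without this, dense papilla fields clip at 255 and
    # become *more* compressible than simple textures
    structure *= 30.0 / structure.std()
    img = 128.0 + structure

    # stomata: dark ellipses 8 × 4 µm at Poisson locations
    n_stomata = rng.poisson(spec.stomata_density * area_um2 / 1e4)
    semi_major_px = 4.0 / pixel_size_um
    semi_minor_px = 2.0 / pixel_size_um
    margin = int(np.ceil(semi_major_px)) + 1
    annots: list[StomaAnnotation] = []
    iid = image_id or f"{spec.name}_s{seed}"
    for s in range(n_stomata):
        r = int(rng.integers(margin, size_px - margin))
        c = int(rng.integers(margin, size_px - margin))
        rot = rng.uniform(-np.pi, np.pi)
        rr, cc = ellipse(r, c, semi_minor_px, semi_major_px,
                         shape=(size_px, size_px), rotation=rot)
        img[rr, cc] *= STOMA_DARKENING
        annots.append(
            StomaAnnotation(
                image_id=iid, stoma_index=s, center_row=r, center_col=c,
                major_axis_um=8.0,
            )
        )

    img += rng.normal(0.0, spec.noise_sd, size=(size_px, size_px))
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    micro = Micrograph(
        image_id=iid, pixels=pixels, pixel_size_um=pixel_size_um,
        species=spec.name, tree_id=tree_id, leaf_id=leaf_id,
        batch_id=batch_id, magnification_tag="synthetic",
    )
    return micro, annots


def species_specs(
    n_species: int = 10, c_range: tuple[float, float] = (0.05, 0.95)
) -> list[SpeciesSpec]:
    """Evenly spaced complexity parameters; species index order is the ground truth."""
    cs = np.linspace(c_range[0], c_range[1], n_species)
    return [
        SpeciesSpec(name=f"species{i + 1:02d}", complexity_c=float(c))
        for i, c in enumerate(cs)
    ]


def generate_benchmark(
    out_dir: str | Path,
    n_species: int = 10,
    images_per_species: int = 4,
    c_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 42,
    size_px: int = 2048,
    pixel_size_um: float = 0.2,
) -> tuple[Manifest, list[StomaAnnotation]]:
    """Write a complete synthetic dataset consumable by the I/O layer.

    Layout: ``out_dir/images/*.png``, ``out_dir/manifest.csv``,
    ``out_dir/annotations.csv``. Fully deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValueError("need ≥ 2 species")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    meta_rows = []
    annotations: list[StomaAnnotation] = []
    for si, spec in enumerate(species_specs(n_species, c_range)):
        for j in range(images_per_species):
            image_id = f"{spec.name}_img{j + 1}"
            img_seed = (seed * 1000003 + si * 101 + j) % (2**31)
            micro, annots = generate_micrograph(
                spec, size_px=size_px, pixel_size_um=pixel_size_um,
                seed=img_seed, image_id=image_id,
                tree_id=f"{spec.name}_t{j // 2 + 1}",
                leaf_id=f"{spec.name}_l{j + 1}",
                batch_id="b1",
            )
            fname = f"{image_id}.png"
            iio.imwrite(img_dir / fname, micro.pixels)
            meta_rows.append(
                {
                    "image_id": image_id,
                    "path": f"images/{fname}",
                    "species": spec.name,
                    "tree_id": micro.tree_id,
                    "leaf_id": micro.leaf_id,
                    "batch_id": micro.batch_id,
                    "pixel_size_um": pixel_size_um,
                    "magnification_tag": "synthetic",
                }
            )
            annotations.extend(annots)

    # manifest paths are kept relative to the manifest file location
    manifest = Manifest(pd.DataFrame(meta_rows))
    write_manifest(manifest, out_dir / "manifest.csv")
    write_annotations(annotations, out_dir / "annotations.csv")
    return manifest, annotations
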