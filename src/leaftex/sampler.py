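"""Stomata-anchored sub-image sampling and per-species dataset balancing.

Patches are 80 µm × 80 µm windows (by default) drawn around annotated
stomata, then resized to the canonical 512×512 pixel raster. In
``whole_leaf`` mode the window center jitters uniformly within ±half a
patch of the anchoring stoma; in ``roi`` mode it sits on the stoma itself.
Windows are always clipped to lie fully inside the source image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .io_annot import Manifest, Micrograph, StomaAnnotation, ValidationError

PATCH_PIXELS = 512

PATCH_MANIFEST_COLUMNS = [
    "patch_id",
    "image_id",
    "species",
    "tree_id",
    "leaf_id",
    "batch_id",
    "stoma_index",
    "offset_row_um",
    "offset_col_um",
    "mode",
]


class SamplingError(RuntimeError):
    pass


@dataclass
class SubImagePatch:
    patch_id: str
    pixels: np.ndarray  # 512×512 uint8
    image_id: str
    species: str
    tree_id: str
    leaf_id: str
    batch_id: str
    stoma_index: int
    offset_um: tuple[float, float]
    mode: str  # "whole_leaf" | "roi"


def _resize_window(window: np.ndarray) -> np.ndarray:
    """Bilinear resize to 512×512; anti-aliasing only when downscaling."""
    if window.shape == (PATCH_PIXELS, PATCH_PIXELS):
        return window.astype(np.uint8)
    anti_alias = min(window.shape) > PATCH_PIXELS
    out = resize(
        window.astype(float),
        (PATCH_PIXELS, PATCH_PIXELS),
        order=1,
        anti_aliasing=anti_alias,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def sample_subimages(
    m: Micrograph,
    annots: list[StomaAnnotation],
    n: int = 120,
    patch_size_um: float = 80.0,
    mode: str = "whole_leaf",
    seed: int = 0,
) -> list[SubImagePatch]:
    """Draw ``n`` stomata-anchored patches from one micrograph.

    Each patch picks a non-excluded stoma uniformly at random (with
    replacement), offsets the window center by up to ±half a patch per axis
    (whole_leaf mode) or not at all (roi mode), clips the window inside the
    image, and resizes it to 512×512.
    """
    if mode not in ("whole_leaf", "roi"):
        raise ValidationError(f"unknown sampling mode {mode!r}")
    usable = [a for a in annots if a.image_id == m.image_id and not a.exclusion]
    if not usable:
        raise SamplingError(f"{m.image_id}: no usable (non-excluded) stoma annotation")

    window_px = int(round(patch_size_um / m.pixel_size_um))
    h, w = m.shape
    if window_px > min(h, w):
        raise ValidationError(
            f"{m.image_id}: patch window {window_px} px exceeds image {m.shape}"
        )
    half = window_px / 2.0
    rng = np.random.default_rng(seed)

    patches: list[SubImagePatch] = []
    for i in range(n):
        stoma = usable[rng.integers(len(usable))]
        if mode == "whole_leaf":
            jitter_r = rng.uniform(-half, half)
            jitter_c = rng.uniform(-half, half)
        else:
            jitter_r = jitter_c = 0.0
        center_r = stoma.center_row + jitter_r
        center_c = stoma.center_col + jitter_c
        # clip so the window lies fully inside the image
        r0 = int(round(np.clip(center_r - half, 0, h - window_px)))
        c0 = int(round(np.clip(center_c - half, 0, w - window_px)))
        window = m.pixels[r0 : r0 + window_px, c0 : c0 + window_px]
        offset_um = (
            ((r0 + half) - stoma.center_row) * m.pixel_size_um,
            ((c0 + half) - stoma.center_col) * m.pixel_size_um,
        )
        patches.append(
            SubImagePatch(
                patch_id=f"{m.image_id}_p{i:04d}",
                pixels=_resize_window(window),
                image_id=m.image_id,
                species=m.species,
                tree_id=m.tree_id,
                leaf_id=m.leaf_id,
                batch_id=m.batch_id,
                stoma_index=stoma.stoma_index,
                offset_um=offset_um,
                mode=mode,
            )
        )
    return patches


def balance_dataset(
    patches: list[SubImagePatch], per_species: int, seed: int = 0
) -> list[SubImagePatch]:
    """Downsample to exactly ``per_species`` patches per species.

    Selection is stratified by source image: within a species, patches are
    drawn round-robin across its images (each image's pool pre-shuffled), so
    per-image counts differ by at most one when availability allows.
    """
    by_species: dict[str, dict[str, list[SubImagePatch]]] = {}
    for p in patches:
        by_species.setdefault(p.species, {}).setdefault(p.image_id, []).append(p)

    deficits = {
        sp: sum(len(v) for v in imgs.values())
        for sp, imgs in by_species.items()
        if sum(len(v) for v in imgs.values()) < per_species
    }
    if deficits:
        raise ValidationError(
            f"species below per_species={per_species} quota: {deficits}"
        )

    rng = np.random.default_rng(seed)
    selected: list[SubImagePatch] = []
    for sp in sorted(by_species):
        imgs = by_species[sp]
        pools = []
        for image_id in sorted(imgs):
            pool = sorted(imgs[image_id], key=lambda p: p.patch_id)
            rng.shuffle(pool)
            pools.append(pool)
        taken = 0
        depth = 0
        while taken < per_species:
            for pool in pools:
                if taken >= per_species:
                    break
                if depth < len(pool):
                    selected.append(pool[depth])
                    taken += 1
            depth += 1
    return selected


def patch_manifest(patches: list[SubImagePatch]) -> pd.DataFrame:
    """Tabulate patch provenance (one row per patch, keyed by patch_id)."""
    return pd.DataFrame(
        [
            {
                "patch_id": p.patch_id,
                "image_id": p.image_id,
                "species": p.species,
                "tree_id": p.tree_id,
                "leaf_id": p.leaf_id,
                "batch_id": p.batch_id,
                "stoma_index": p.stoma_index,
                "offset_row_um": p.offset_um[0],
                "offset_col_um": p.offset_um[1],
                "mode": p.mode,
            }
            for p in patches
        ],
        columns=PATCH_MANIFEST_COLUMNS,
    )


def write_patches(patches: list[SubImagePatch], out_dir: str | Path) -> Path:
    """Store patches as PNGs plus a patch-manifest CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in patches:
        iio.imwrite(out_dir / f"{p.patch_id}.png", p.pixels)
    csv_path = out_dir / "patches.csv"
    patch_manifest(patches).to_csv(csv_path, index=False)
    return csv_path


def read_patches(out_dir: str | Path) -> list[SubImagePatch]:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "patches.csv")
    patches = []
    for _, row in df.iterrows():
        patches.append(
            SubImagePatch(
                patch_id=str(row["patch_id"]),
                pixels=iio.imread(out_dir / f"{row['patch_id']}.png"),
                image_id=str(row["image_id"]),
                species=str(row["species"]),
                tree_id=str(row["tree_id"]),
                leaf_id=str(row["leaf_id"]),
                batch_id=str(row["batch_id"]),
                stoma_index=int(row["stoma_index"]),
                offset_um=(float(row["offset_row_um"]), float(row["offset_col_um"])),
                mode=str(row["mode"]),
            )
        )
    return patches
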