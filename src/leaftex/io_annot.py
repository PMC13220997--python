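"""Micrograph, annotation and manifest I/O.

The dataset contract: one manifest row per grayscale micrograph (with its
physical pixel size in µm and provenance labels), plus a CSV of stomata
center annotations addressed by 0-based (row, col) pixel coordinates.
Stomata inside fungal-colonization regions carry ``exclusion=True`` and are
retained but skipped by the patch sampler.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "image_id",
    "path",
    "species",
    "tree_id",
    "leaf_id",
    "batch_id",
    "pixel_size_um",
    "magnification_tag",
]

ANNOTATION_COLUMNS = ["image_id", "stoma_index", "center_row", "center_col"]


class ValidationError(ValueError):
    """A dataset-contract violation (bad metadata, out-of-bounds annotation...)."""


@dataclass
class Micrograph:
    """A single grayscale electron micrograph with physical scale and provenance."""

    image_id: str
    pixels: np.ndarray  # 2-D uint8
    pixel_size_um: float
    species: str
    tree_id: str = ""
    leaf_id: str = ""
    batch_id: str = ""
    magnification_tag: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"{self.image_id}: micrograph pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValidationError(
                f"{self.image_id}: pixel_size_um must be positive, got {self.pixel_size_um}"
            )
        if not self.species:
            raise ValidationError(f"{self.image_id}: species must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class StomaAnnotation:
    """One stoma center on a micrograph, 0-based (row, col) pixel coordinates."""

    image_id: str
    stoma_index: int
    center_row: int
    center_col: int
    major_axis_um: float | None = None
    exclusion: bool = False


@dataclass
class Manifest:
    """Table of micrograph records; ``image_id`` is the unique key."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        dup = self.records["image_id"][self.records["image_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate image_id in manifest: {sorted(set(dup))}")
        self.records = (
            self.records[MANIFEST_COLUMNS]
            .sort_values("image_id", kind="stable")
            .reset_index(drop=True)
        )

    def row(self, image_id: str) -> pd.Series:
        match = self.records[self.records["image_id"] == image_id]
        if match.empty:
            raise KeyError(f"image_id {image_id!r} not in manifest")
        return match.iloc[0]

    def __len__(self) -> int:
        return len(self.records)


def load_micrograph(path: str | Path, manifest_row: pd.Series) -> Micrograph:
    """Read one micrograph file and attach metadata from its manifest row.

    Multi-channel images are collapsed to grayscale by channel average;
    multi-page TIFFs are truncated to page 0. Both conversions are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"micrograph file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
        # multi-page stack: keep first frame
        logger.warning("%s: multi-page image, reading page 0 only", path)
        arr = arr[0]
    if arr.ndim == 3:
        logger.warning("%s: multi-channel image, converting by luminance average", path)
        arr = arr[..., :3].mean(axis=-1)
    arr = np.clip(np.round(np.asarray(arr, dtype=float)), 0, 255).astype(np.uint8)

    pixel_size_um = float(manifest_row["pixel_size_um"])
    m = Micrograph(
        image_id=str(manifest_row["image_id"]),
        pixels=arr,
        pixel_size_um=pixel_size_um,
        species=str(manifest_row["species"]),
        tree_id=str(manifest_row["tree_id"]),
        leaf_id=str(manifest_row["leaf_id"]),
        batch_id=str(manifest_row["batch_id"]),
        magnification_tag=str(manifest_row["magnification_tag"]),
    )
    return m


def check_patch_fits(m: Micrograph, patch_size_um: float = 80.0) -> None:
    """Raise if the micrograph cannot hold a single patch window."""
    window_px = int(round(patch_size_um / m.pixel_size_um))
    if min(m.shape) < window_px:
        raise ValidationError(
            f"{m.image_id}: image {m.shape} smaller than one "
            f"{patch_size_um} µm patch ({window_px} px) at {m.pixel_size_um} µm/px"
        )


def load_annotations(path: str | Path, manifest: Manifest,
                     image_shapes: dict[str, tuple[int, int]] | None = None,
                     base_dir: str | Path | None = None
                     ) -> list[StomaAnnotation]:
    """Read stomata annotations from CSV and validate against the manifest.

    ``image_shapes`` maps image_id -> (rows, cols) for bounds checking; when
    omitted, shapes are read lazily from the image files in the manifest
    (relative manifest paths resolved against ``base_dir``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation CSV missing columns: {missing}")
    if df.empty:
        warnings.warn(f"annotation file {path} contains no rows", stacklevel=2)
        return []

    known = set(manifest.records["image_id"])
    unknown = sorted(set(df["image_id"].astype(str)) - known)
    if unknown:
        raise ValidationError(f"annotations reference unknown image_id(s): {unknown}")

    if image_shapes is None:
        root = Path(base_dir) if base_dir is not None else Path(".")
        image_shapes = {}
        for _, row in manifest.records.iterrows():
            if str(row["image_id"]) in set(df["image_id"].astype(str)):
                p = Path(row["path"])
                props = iio.improps(p if p.is_absolute() else root / p)
                shape = props.shape
                image_shapes[str(row["image_id"])] = (int(shape[0]), int(shape[1]))

    bad_rows = []
    annots: list[StomaAnnotation] = []
    for idx, row in df.iterrows():
        image_id = str(row["image_id"])
        r, c = int(row["center_row"]), int(row["center_col"])
        h, w = image_shapes[image_id]
        if not (0 <= r < h and 0 <= c < w):
            bad_rows.append(int(idx))
            continue
        major = row.get("major_axis_um", np.nan)
        annots.append(
            StomaAnnotation(
                image_id=image_id,
                stoma_index=int(row["stoma_index"]),
                center_row=r,
                center_col=c,
                major_axis_um=None if pd.isna(major) else float(major),
                exclusion=bool(row.get("exclusion", False)),
            )
        )
    if bad_rows:
        raise ValidationError(
            f"annotation centers out of image bounds at CSV rows: {bad_rows}"
        )
    return annots


def write_annotations(annots: list[StomaAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "image_id": a.image_id,
                "stoma_index": a.stoma_index,
                "center_row": a.center_row,
                "center_col": a.center_col,
                "major_axis_um": a.major_axis_um,
                "exclusion": a.exclusion,
            }
            for a in annots
        ],
        columns=ANNOTATION_COLUMNS + ["major_axis_um", "exclusion"],
    )
    df.to_csv(path, index=False)


def build_manifest(root_dir: str | Path, metadata: pd.DataFrame) -> Manifest:
    """Assemble a manifest from a metadata table whose paths live under root_dir."""
    root_dir = Path(root_dir)
    if metadata.empty:
        warnings.warn(f"no metadata rows for {root_dir}; manifest is empty", stacklevel=2)
        return Manifest()
    records = metadata.copy()
    records["path"] = [str(root_dir / p) for p in records["path"]]
    for p, image_id in zip(records["path"], records["image_id"]):
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest references missing file {p} ({image_id})")
    return Manifest(records)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.records.to_csv(path, index=False)


def read_manifest(path: str | Path) -> Manifest:
    if not Path(path).exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    return Manifest(pd.read_csv(path))
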