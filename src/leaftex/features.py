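"""Per-patch texture features and the complexity triplet.

Four feature families are computed on each 512×512 grayscale patch:

* isotropic gray-level co-occurrence (GLCM) statistics — ASM, contrast,
  entropy (bits), homogeneity, correlation — averaged over offsets
  {1, 2, 4} px × {0°, 45°, 90°, 135°} on 64 quantization levels;
* 25 spectral components: the radially averaged log power spectrum
  (64 bins, DC excluded) reduced by PCA fitted on training patches;
* Sobel gradient-magnitude mean and standard deviation;
* lossless-compression information density in bits per pixel
  (zlib level 9 on the raw byte stream).

The complexity triplet driving the pairwise ranking game is
(info_density = compression bpp, heterogeneity = 1 − ASM,
variability = gradient std); each is monotone in perceived texture
complexity.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import graycomatrix

from .sampler import SubImagePatch

GLCM_LEVELS = 64
GLCM_DISTANCES = (1, 2, 4)
GLCM_ANGLES_DEG = (0, 45, 90, 135)
SPECTRAL_BINS = 64
SPECTRAL_COMPONENTS = 25

GLCM_COLUMNS = [
    "glcm_asm",
    "glcm_contrast",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_correlation",
]
TRIPLET_COLUMNS = ["info_density", "heterogeneity", "variability"]


def _glcm_stats(P: np.ndarray) -> tuple[float, float, float, float, float]:
    """The five statistics of one normalized symmetric co-occurrence matrix."""
    levels = P.shape[0]
    i = np.arange(levels, dtype=float)[:, None]
    j = np.arange(levels, dtype=float)[None, :]
    asm = float(np.sum(P * P))
    contrast = float(np.sum(P * (i - j) ** 2))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    homogeneity = float(np.sum(P / (1.0 + (i - j) ** 2)))
    mu_i = float(np.sum(i * P))
    mu_j = float(np.sum(j * P))
    var_i = float(np.sum((i - mu_i) ** 2 * P))
    var_j = float(np.sum((j - mu_j) ** 2 * P))
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        correlation = 0.0  # constant patch convention
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * P) / denom)
    return asm, contrast, entropy, homogeneity, correlation


def quantize(patch: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Linear quantization of 8-bit intensities into ``levels`` bins."""
    return (np.asarray(patch, dtype=np.uint16) * levels // 256).astype(np.uint8)


def glcm_features(
    patch: np.ndarray,
    levels: int = GLCM_LEVELS,
    distances: Sequence[int] = GLCM_DISTANCES,
    angles_deg: Sequence[float] = GLCM_ANGLES_DEG,
) -> tuple[float, float, float, float, float]:
    """Isotropic GLCM features: per-offset statistics averaged over all offsets."""
    if levels < 2:
        raise ValueError("levels must be ≥ 2")
    q = quantize(patch, levels)
    angles_rad = [np.deg2rad(a) for a in angles_deg]
    # P has shape (levels, levels, n_dist, n_angle); symmetric and normalized
    P = graycomatrix(
        q, distances=list(distances), angles=angles_rad, levels=levels,
        symmetric=True, normed=True,
    )
    stats = [
        _glcm_stats(P[:, :, d, a])
        for d in range(len(distances))
        for a in range(len(angles_rad))
    ]
    return tuple(float(np.mean(col)) for col in zip(*stats))  # type: ignore[return-value]


def gradient_features(patch: np.ndarray) -> tuple[float, float]:
    """Mean and population std of the 3×3 Sobel gradient magnitude (reflect border)."""
    x = np.asarray(patch, dtype=float)
    gr = ndimage.sobel(x, axis=0, mode="reflect")
    gc = ndimage.sobel(x, axis=1, mode="reflect")
    mag = np.hypot(gr, gc)
    return float(mag.mean()), float(mag.std())


def compression_feature(patch: np.ndarray) -> float:
    """Bits per pixel after DEFLATE (zlib level 9) of the raw row-major bytes."""
    raw = np.ascontiguousarray(patch, dtype=np.uint8).tobytes()
    compressed = zlib.compress(raw, 9)
    return 8.0 * len(compressed) / np.asarray(patch).size


def radial_spectrum(patch: np.ndarray, bins: int = SPECTRAL_BINS) -> np.ndarray:
    """Radially averaged log₁₀(1 + power spectrum) in equal-width frequency bins.

    Frequencies run from 0 to the Nyquist radius 0.5 cycles/px; the DC term
    and corner frequencies above Nyquist are excluded. Rotation of the patch
    by 90° leaves the result unchanged.
    """
    x = np.asarray(patch, dtype=float)
    x = x - x.mean()
    power = np.abs(np.fft.fft2(x)) ** 2
    logp = np.log10(1.0 + power)
    fr = np.fft.fftfreq(x.shape[0])[:, None]
    fc = np.fft.fftfreq(x.shape[1])[None, :]
    r = np.sqrt(fr * fr + fc * fc)
    mask = (r > 0) & (r <= 0.5)
    idx = np.minimum((r[mask] / 0.5 * bins).astype(int), bins - 1)
    sums = np.bincount(idx, weights=logp[mask], minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    out = np.zeros(bins)
    nonzero = counts > 0
    out[nonzero] = sums[nonzero] / counts[nonzero]
    return out


@dataclass
class SpectralModel:
    """PCA of radially averaged log power spectra, fitted on training patches.

    Components are orthonormal rows ordered by decreasing explained variance
    (population covariance). The model is frozen after fitting: applying it
    to later patches is a projection, never a refit.
    """

    radial_bins: int
    mean_spectrum: np.ndarray  # (bins,)
    components: np.ndarray  # (n_components, bins)
    explained_variance: np.ndarray  # (n_components,)

    def transform_spectra(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if spectra.shape[1] != self.radial_bins:
            raise ValueError(
                f"expected {self.radial_bins}-bin spectra, got {spectra.shape[1]}"
            )
        return (spectra - self.mean_spectrum) @ self.components.T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "radial_bins": self.radial_bins,
            "mean_spectrum": self.mean_spectrum.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpectralModel":
        d = json.loads(Path(path).read_text())
        return cls(
            radial_bins=int(d["radial_bins"]),
            mean_spectrum=np.asarray(d["mean_spectrum"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
        )


def fit_spectral_model_from_spectra(
    spectra: np.ndarray, n_components: int = SPECTRAL_COMPONENTS
) -> SpectralModel:
    """PCA on precomputed radial spectra (population covariance, eigh).

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making the fit deterministic and invariant to duplicating the
    training set.
    """
    X = np.asarray(spectra, dtype=float)
    n, bins = X.shape
    if n < n_components + 1:
        raise ValueError(
            f"need ≥ {n_components + 1} training patches for {n_components} "
            f"components, got {n}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    components = evecs[:, order].T.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return SpectralModel(
        radial_bins=bins,
        mean_spectrum=mean,
        components=components,
        explained_variance=np.maximum(evals[order], 0.0),
    )


def fit_spectral_model(
    training_patches: Iterable[np.ndarray | SubImagePatch],
    bins: int = SPECTRAL_BINS,
    n_components: int = SPECTRAL_COMPONENTS,
) -> SpectralModel:
    spectra = np.array(
        [radial_spectrum(_pixels(p), bins) for p in training_patches]
    )
    return fit_spectral_model_from_spectra(spectra, n_components)


def spectral_transform(model: SpectralModel, patch: np.ndarray) -> np.ndarray:
    """Project one patch's centered radial log-spectrum onto the components."""
    if model is None or model.components is None:
        raise RuntimeError("spectral model is not fitted")
    return model.transform_spectra(radial_spectrum(_pixels(patch), model.radial_bins))[0]


def _pixels(p: np.ndarray | SubImagePatch) -> np.ndarray:
    return p.pixels if isinstance(p, SubImagePatch) else np.asarray(p)


def _provenance(p: np.ndarray | SubImagePatch, i: int) -> dict:
    if isinstance(p, SubImagePatch):
        return {
            "patch_id": p.patch_id,
            "image_id": p.image_id,
            "species": p.species,
            "tree_id": p.tree_id,
            "leaf_id": p.leaf_id,
            "batch_id": p.batch_id,
        }
    return {"patch_id": f"patch{i:05d}"}


def compute_base_features(
    patches: Iterable[np.ndarray | SubImagePatch],
    levels: int = GLCM_LEVELS,
    distances: Sequence[int] = GLCM_DISTANCES,
    angles_deg: Sequence[float] = GLCM_ANGLES_DEG,
) -> pd.DataFrame:
    """GLCM + gradient + compression features (everything except spectral PCA)."""
    rows = []
    for i, p in enumerate(patches):
        px = _pixels(p)
        try:
            asm, contrast, entropy, homogeneity, correlation = glcm_features(
                px, levels, distances, angles_deg
            )
            grad_mean, grad_std = gradient_features(px)
            bpp = compression_feature(px)
        except Exception as exc:  # add patch context, re-raise
            raise RuntimeError(
                f"feature computation failed for {_provenance(p, i)['patch_id']}"
            ) from exc
        row = _provenance(p, i)
        row.update(
            glcm_asm=asm,
            glcm_contrast=contrast,
            glcm_entropy=entropy,
            glcm_homogeneity=homogeneity,
            glcm_correlation=correlation,
            grad_mean=grad_mean,
            grad_std=grad_std,
            compression_bpp=bpp,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("patch_id")


def compute_spectra(
    patches: Iterable[np.ndarray | SubImagePatch], bins: int = SPECTRAL_BINS
) -> pd.DataFrame:
    """Radial spectra table (patch_id × bins) for later per-fold PCA fits."""
    rows, ids = [], []
    for i, p in enumerate(patches):
        rows.append(radial_spectrum(_pixels(p), bins))
        ids.append(_provenance(p, i)["patch_id"])
    return pd.DataFrame(
        np.array(rows), index=pd.Index(ids, name="patch_id"),
        columns=[f"bin{b:02d}" for b in range(bins)],
    )


def assemble_features(
    patches: list[np.ndarray | SubImagePatch],
    model: SpectralModel,
    **glcm_kwargs,
) -> pd.DataFrame:
    """Full per-patch feature table plus the complexity triplet columns.

    One row per patch: GLCM block, 25 spectral scores s01…s25, gradient
    stats, compression density, and the derived triplet
    (info_density, heterogeneity = 1 − ASM, variability = grad_std).
    """
    base = compute_base_features(patches, **glcm_kwargs)
    spectra = compute_spectra(patches, model.radial_bins)
    scores = model.transform_spectra(spectra.values)
    spec_df = pd.DataFrame(
        scores, index=spectra.index,
        columns=[f"s{i + 1:02d}" for i in range(scores.shape[1])],
    )
    out = base.join(spec_df)
    out["info_density"] = out["compression_bpp"]
    out["heterogeneity"] = 1.0 - out["glcm_asm"]
    out["variability"] = out["grad_std"]
    return out


_PROVENANCE_COLUMNS = {"species", "image_id", "tree_id", "leaf_id", "batch_id"}


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Columns usable as classifier inputs (excludes provenance and triplet aliases).

    Prefers the standard feature names when present; otherwise falls back to
    every numeric column that is not provenance or a triplet alias.
    """
    spectral = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    known = [
        c
        for c in GLCM_COLUMNS + ["grad_mean", "grad_std", "compression_bpp"]
        if c in df.columns
    ]
    if known or spectral:
        return known + spectral
    skip = _PROVENANCE_COLUMNS | set(TRIPLET_COLUMNS)
    return [
        c
        for c in df.columns
        if c not in skip and pd.api.types.is_numeric_dtype(df[c])
    ]


def complexity_triplet(df: pd.DataFrame) -> pd.DataFrame:
    """Extract (species, info_density, heterogeneity, variability) per patch."""
    cols = [c for c in ("species",) if c in df.columns] + TRIPLET_COLUMNS
    missing = [c for c in TRIPLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks triplet columns: {missing}")
    return df[cols].copy()
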