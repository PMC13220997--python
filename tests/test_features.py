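"""Texture feature tests: GLCM against a brute-force oracle, gradient and
compression behavior on analytically understood inputs, spectral model
properties, and triplet monotonicity on the synthetic generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr

from leaftex import features, synthetic
from leaftex.features import (
    SpectralModel,
    assemble_features,
    compression_feature,
    fit_spectral_model,
    fit_spectral_model_from_spectra,
    glcm_features,
    gradient_features,
    quantize,
    radial_spectrum,
    spectral_transform,
)

def glcm_oracle(patch, levels, distances, angles_deg):
    """Brute-force pair enumeration: symmetric, normalized, feature-averaged.

    Offsets are Euclidean: (round(d·sin θ), round(d·cos θ)), so diagonal
    angles at distance d displace by round(d/√2) per axis.
    """
    q = quantize(patch, levels).astype(int)
    h, w = q.shape
    stats = []
    for d in distances:
        for ang in angles_deg:
            theta = np.deg2rad(ang)
            dr = int(round(np.sin(theta) * d))
            dc = int(round(np.cos(theta) * d))
            P = np.zeros((levels, levels))
            for r in range(h):
                for c in range(w):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w:
                        P[q[r, c], q[r2, c2]] += 1
                        P[q[r2, c2], q[r, c]] += 1
            P /= P.sum()
            i = np.arange(levels)[:, None].astype(float)
            j = np.arange(levels)[None, :].astype(float)
            asm = (P**2).sum()
            contrast = (P * (i - j) ** 2).sum()
            nz = P[P > 0]
            entropy = -(nz * np.log2(nz)).sum()
            homog = (P / (1 + (i - j) ** 2)).sum()
            mi, mj = (i * P).sum(), (j * P).sum()
            vi = ((i - mi) ** 2 * P).sum()
            vj = ((j - mj) ** 2 * P).sum()
            corr = 0.0 if vi * vj == 0 else ((i - mi) * (j - mj) * P).sum() / np.sqrt(vi * vj)
            stats.append((asm, contrast, entropy, homog, corr))
    return tuple(np.mean(col) for col in zip(*stats))


class TestGLCM:
    def test_constant_patch(self, constant_patch):
        asm, contrast, entropy, homog, corr = glcm_features(constant_patch)
        assert asm == 1.0
        assert contrast == 0.0
        assert entropy == 0.0
        assert homog == 1.0
        assert corr == 0.0  # degenerate-variance convention

    def test_checkerboard_horizontal(self):
        # 2×2 board of two quantization levels, distance 1, angle 0: the two
        # symmetric horizontal pairs give P = [[0,.5],[.5,0]]
        board = np.array([[0, 128], [128, 0]], dtype=np.uint8)
        asm, contrast, *_ = glcm_features(
            board, levels=2, distances=(1,), angles_deg=(0,)
        )
        assert asm == pytest.approx(0.5)
        assert contrast == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 256, size=(4, 4), dtype=np.uint8)
        got = glcm_features(patch, levels=4, distances=(1, 2), angles_deg=(0, 45, 90, 135))
        expected = glcm_oracle(patch, 4, (1, 2), (0, 45, 90, 135))
        assert np.allclose(got, expected, atol=1e-12)

    def test_isotropic_is_mean_of_per_offset_features(self, rng):
        patch = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        combined = glcm_features(patch, distances=(1, 2), angles_deg=(0, 90))
        singles = [
            glcm_features(patch, distances=(d,), angles_deg=(a,))
            for d in (1, 2)
            for a in (0, 90)
        ]
        assert np.allclose(combined, np.mean(singles, axis=0), atol=1e-12)

    def test_invariant_to_constant_shift_within_range(self, rng):
        # +32 gray levels shifts every 64-level quantization bin by exactly 8
        patch = rng.integers(0, 193, size=(64, 64), dtype=np.uint8)
        assert np.allclose(
            glcm_features(patch), glcm_features(patch + 32), atol=1e-12
        )


class TestGradient:
    def test_constant_patch_is_zero(self, constant_patch):
        assert gradient_features(constant_patch) == (0.0, 0.0)

    def test_linear_ramp_has_uniform_interior_gradient(self):
        ramp = np.tile(np.arange(512, dtype=float), (512, 1))
        grad_mean, grad_std = gradient_features(ramp)
        # Sobel of a ramp is constant away from borders under reflect padding
        assert grad_std < 0.05 * grad_mean

    def test_noise_rougher_than_blurred_noise(self, noise_patch):
        blurred = gaussian_filter(noise_patch.astype(float), 4)
        assert gradient_features(noise_patch)[1] > gradient_features(blurred)[1]


class TestCompression:
    def test_constant_patch_compresses_away(self):
        patch = np.full((512, 512), 7, dtype=np.uint8)
        assert compression_feature(patch) < 0.05

    def test_random_patch_incompressible(self, noise_patch):
        assert compression_feature(noise_patch) > 7.9

    def test_blur_reduces_information_density(self, noise_patch):
        blurred = np.clip(gaussian_filter(noise_patch.astype(float), 4), 0, 255)
        assert compression_feature(noise_patch) > compression_feature(
            blurred.astype(np.uint8)
        )


class TestSpectralModel:
    def test_rotation_invariance_of_radial_spectrum(self, rng):
        patch = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        s0 = radial_spectrum(patch)
        s90 = radial_spectrum(np.rot90(patch))
        assert np.max(np.abs(s0 - s90)) < 1e-6

    def _train_spectra(self, rng, n=40):
        patches = rng.integers(0, 256, size=(n, 32, 32), dtype=np.uint8)
        return np.array([radial_spectrum(p) for p in patches])

    def test_explained_variance_nonincreasing(self, rng):
        model = fit_spectral_model_from_spectra(self._train_spectra(rng), 25)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_components_orthonormal(self, rng):
        model = fit_spectral_model_from_spectra(self._train_spectra(rng), 10)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(10), atol=1e-10)

    def test_duplicating_training_set_gives_identical_model(self, rng):
        spectra = self._train_spectra(rng)
        m1 = fit_spectral_model_from_spectra(spectra, 10)
        m2 = fit_spectral_model_from_spectra(np.vstack([spectra, spectra]), 10)
        assert np.allclose(m1.mean_spectrum, m2.mean_spectrum)
        assert np.allclose(m1.components, m2.components, atol=1e-8)
        assert np.allclose(m1.explained_variance, m2.explained_variance, atol=1e-8)

    def test_training_scores_have_zero_mean(self, rng):
        spectra = self._train_spectra(rng)
        model = fit_spectral_model_from_spectra(spectra, 10)
        scores = model.transform_spectra(spectra)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_transform_is_affine_in_the_spectrum(self, rng):
        spectra = self._train_spectra(rng)
        model = fit_spectral_model_from_spectra(spectra, 10)
        s1, s2, a = spectra[0], spectra[1], 0.3
        mixed = model.transform_spectra(a * s1 + (1 - a) * s2)[0]
        expected = a * model.transform_spectra(s1)[0] + (1 - a) * model.transform_spectra(s2)[0]
        assert np.allclose(mixed, expected, atol=1e-10)

    def test_too_few_training_patches_rejected(self, rng):
        patches = rng.integers(0, 256, size=(10, 16, 16), dtype=np.uint8)
        with pytest.raises(ValueError, match="training patches"):
            fit_spectral_model(list(patches), n_components=25)

    def test_unfitted_model_rejected(self, rng):
        with pytest.raises(RuntimeError, match="not fitted"):
            spectral_transform(SpectralModel(64, None, None, None), rng.integers(0, 256, (16, 16)))

    def test_json_round_trip(self, rng, tmp_path):
        model = fit_spectral_model_from_spectra(self._train_spectra(rng), 5)
        model.to_json(tmp_path / "m.json")
        back = SpectralModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.components, model.components)
        assert np.allclose(back.mean_spectrum, model.mean_spectrum)


class TestAssembly:
    def test_table_shape_and_triplet_definition(self, rng):
        patches = list(rng.integers(0, 256, size=(30, 32, 32), dtype=np.uint8))
        model = fit_spectral_model(patches, n_components=4)
        table = assemble_features(patches, model)
        assert len(table) == 30
        assert np.allclose(table["heterogeneity"], 1 - table["glcm_asm"])
        assert np.allclose(table["info_density"], table["compression_bpp"])
        assert np.allclose(table["variability"], table["grad_std"])

    def test_noise_beats_constant_on_every_triplet_feature(self, rng):
        patches = [np.full((64, 64), 100, dtype=np.uint8)] + [
            rng.integers(0, 256, size=(64, 64), dtype=np.uint8) for _ in range(29)
        ]
        model = fit_spectral_model(patches, n_components=4)
        table = assemble_features(patches, model)
        const, noise = table.iloc[0], table.iloc[1]
        for col in ("info_density", "heterogeneity", "variability"):
            assert noise[col] > const[col]


def test_triplet_features_monotone_in_generator_complexity():
    """Expected info density, heterogeneity and variability all rise with c."""
    cs = [0.05, 0.275, 0.5, 0.725, 0.95]
    means = []
    for c in cs:
        spec = synthetic.SpeciesSpec(f"c{c}", c)
        vals = []
        for seed in (11, 12):
            m, _ = synthetic.generate_micrograph(spec, size_px=640, seed=seed)
            p = m.pixels[64:576, 64:576]
            asm = glcm_features(p)[0]
            vals.append(
                [compression_feature(p), 1 - asm, gradient_features(p)[1]]
            )
        means.append(np.mean(vals, axis=0))
    means = np.array(means)
    for k, name in enumerate(("info_density", "heterogeneity", "variability")):
        rho = spearmanr(cs, means[:, k]).statistic
        assert rho >= 0.8, f"{name} not monotone in c (rho={rho})"
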