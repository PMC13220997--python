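"""Shared fixtures: deterministic patches and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from leaftex import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_patch():
    return np.full((64, 64), 100, dtype=np.uint8)


@pytest.fixture
def noise_patch(rng):
    return rng.integers(0, 256, size=(512, 512), dtype=np.uint8)


@pytest.fixture(scope="session")
def mini_bench(tmp_path_factory):
    """Tiny synthetic dataset: 3 species × 2 images of 512 px (0.2 µm/px)."""
    out = tmp_path_factory.mktemp("mini_bench")
    manifest, annots = synthetic.generate_benchmark(
        out, n_species=3, images_per_species=2, size_px=512, seed=7
    )
    return out, manifest, annots


def make_triplets(
    species_means: dict[str, tuple[float, float, float]],
    n_per_species: int = 8,
    noise: float = 0.0,
    seed: int = 0,
):
    """Per-patch triplet table with species-level feature means (optionally noisy)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for sp, (a, b, c) in species_means.items():
        for i in range(n_per_species):
            jitter = rng.normal(0, noise, size=3) if noise else np.zeros(3)
            rows.append(
                {
                    "patch_id": f"{sp}_{i}",
                    "species": sp,
                    "info_density": a + jitter[0],
                    "heterogeneity": b + jitter[1],
                    "variability": c + jitter[2],
                }
            )
    return pd.DataFrame(rows).set_index("patch_id")
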