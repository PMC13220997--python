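"""Run configuration: defaults, YAML round-trip, flag overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline knobs with their default study conditions."""

    # paths
    manifest: str = "manifest.csv"
    annotations: str = "annotations.csv"
    out_dir: str = "leaftex_out"
    # sampling
    n_per_image: int = 120
    patch_size_um: float = 80.0
    mode: str = "whole_leaf"  # or "roi"
    per_species: int = 480
    # features
    glcm_levels: int = 64
    glcm_distances: tuple[int, ...] = (1, 2, 4)
    glcm_angles_deg: tuple[float, ...] = (0, 45, 90, 135)
    spectral_bins: int = 64
    spectral_components: int = 25
    # classifier
    k: int = 3
    n_folds: int = 4
    grouping: str = "source_image"
    # tournament
    pairs_per_species_pair: int = 1000
    duel_mode: str = "per_feature"  # or "majority"
    exhaustive: bool = False
    # grouping
    alpha: float = 0.05
    adjust: str = "bh"  # or "none"
    kw_test: str = "kruskal"  # or "anova"
    # stability
    n_boot: int = 20
    frac: float = 0.8
    # master seed
    seed: int = 42

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["glcm_distances"] = list(self.glcm_distances)
        d["glcm_angles_deg"] = list(self.glcm_angles_deg)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.glcm_distances = tuple(cfg.glcm_distances)
        cfg.glcm_angles_deg = tuple(cfg.glcm_angles_deg)
        return cfg
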