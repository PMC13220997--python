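"""End-to-end pipeline: sample → features → classify → rank → group → stability.

Every stage writes its artifacts under the configured output directory and
the resolved configuration plus a run log are always persisted, so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import cross_validated_accuracy, make_split
from .config import RunConfig
from .features import (
    assemble_features,
    complexity_triplet,
    compute_spectra,
    fit_spectral_model,
)
from .grouping import cluster_groups, pairwise_kw
from .io_annot import load_annotations, load_micrograph, read_manifest
from .sampler import balance_dataset, patch_manifest, sample_subimages
from .stability import bootstrap_ranks, feature_loo
from .tournament import fit_bradley_terry, rank_species, run_tournament

logger = logging.getLogger(__name__)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("sample")
def sample_stage(config: RunConfig):
    manifest = read_manifest(config.manifest)
    base = Path(config.manifest).parent
    annots = load_annotations(config.annotations, manifest, base_dir=base)
    patches = []
    for i, (_, row) in enumerate(manifest.records.iterrows()):
        p = Path(row["path"])
        micro = load_micrograph(p if p.is_absolute() else base / p, row)
        patches.extend(
            sample_subimages(
                micro,
                annots,
                n=config.n_per_image,
                patch_size_um=config.patch_size_um,
                mode=config.mode,
                seed=(config.seed * 7919 + i) % (2**31),
            )
        )
    return balance_dataset(patches, config.per_species, seed=config.seed)


@_stage("features")
def feature_stage(patches, config: RunConfig, out: Path):
    model = fit_spectral_model(
        patches, bins=config.spectral_bins, n_components=config.spectral_components
    )
    model.to_json(out / "spectral_model.json")
    table = assemble_features(
        patches,
        model,
        levels=config.glcm_levels,
        distances=config.glcm_distances,
        angles_deg=config.glcm_angles_deg,
    )
    table.to_csv(out / "features.csv")
    spectra = compute_spectra(patches, config.spectral_bins)
    return table, spectra


@_stage("classify")
def classify_stage(table, spectra, config: RunConfig, out: Path):
    plan = make_split(
        patch_manifest_from_features(table),
        grouping=config.grouping,
        n_folds=config.n_folds,
        seed=config.seed,
    )
    report = cross_validated_accuracy(
        table, plan, k=config.k, spectra=spectra,
        n_components=config.spectral_components,
    )
    (out / "classification.json").write_text(
        json.dumps(
            {"accuracy": report.accuracy, "per_fold_accuracy": report.per_fold_accuracy}
        )
    )
    report.confusion.to_csv(out / "confusion.csv")
    return report


def patch_manifest_from_features(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("image_id", "species", "tree_id", "leaf_id", "batch_id")
            if c in table.columns]
    return table[cols].reset_index()


@_stage("rank")
def rank_stage(table, config: RunConfig, out: Path):
    triplets = complexity_triplet(table)
    wm = run_tournament(
        triplets,
        pairs_per_species_pair=config.pairs_per_species_pair,
        seed=config.seed,
        mode=config.duel_mode,
        exhaustive=config.exhaustive,
    )
    wm.w.to_csv(out / "win_matrix.csv")
    wm.patch_stats.to_csv(out / "patch_win_fractions.csv")
    scores = rank_species(fit_bradley_terry(wm))
    return triplets, wm, scores


@_stage("group")
def group_stage(wm, scores, config: RunConfig, out: Path):
    tests = pairwise_kw(
        wm.patch_stats, value_col="win_fraction",
        test=config.kw_test, adjust=config.adjust,
    )
    tests.p_adj.to_csv(out / "pairwise_p_adj.csv")
    groups = cluster_groups(
        tests, alpha=config.alpha,
        species_scores=scores.set_index("species")["score"],
    )
    scores = scores.copy()
    scores["group"] = scores["species"].map(groups.labels).to_numpy()
    scores.to_csv(out / "complexity_scores.csv", index=False)
    pd.DataFrame(groups.linkage, columns=["left", "right", "height", "size"]).to_csv(
        out / "linkage.csv", index=False
    )
    return groups, scores


@_stage("stability")
def stability_stage(triplets, scores, config: RunConfig, out: Path):
    full_ranks = scores.set_index("species")["rank"]
    boot = bootstrap_ranks(
        triplets,
        n_boot=config.n_boot,
        frac=config.frac,
        seed=config.seed,
        full_ranks=full_ranks,
        pairs_per_species_pair=config.pairs_per_species_pair,
        mode=config.duel_mode,
    )
    loo = feature_loo(
        triplets,
        seed=config.seed,
        full_ranks=full_ranks,
        pairs_per_species_pair=config.pairs_per_species_pair,
        mode=config.duel_mode,
    )
    boot.replicate_ranks.to_csv(out / "bootstrap_ranks.csv")
    summary = {
        "bootstrap": {
            "n_boot": boot.n_boot,
            "frac": boot.frac,
            "rho_mean": boot.rho_mean,
            "rho_sd": boot.rho_sd,
            "per_replicate_rho": boot.per_replicate_rho,
            "zero_variance_count": boot.zero_variance_count,
        },
        "leave_one_out": {"rho": loo.rho, "rho_min": loo.rho_min},
    }
    (out / "stability.json").write_text(json.dumps(summary, indent=2))
    return boot, loo


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the artifact directory."""
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")

    patches = sample_stage(config)
    patch_manifest(patches).to_csv(out / "patches.csv", index=False)
    table, spectra = feature_stage(patches, config, out)
    report = classify_stage(table, spectra, config, out)
    triplets, wm, scores = rank_stage(table, config, out)
    groups, scores = group_stage(wm, scores, config, out)
    stability_stage(triplets, scores, config, out)

    log = {
        "leaftex_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_patches": len(patches),
        "classification_accuracy": report.accuracy,
        "wall_time_s": round(time.perf_counter() - t0, 2),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return out
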