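"""Rank-robustness diagnostics: bootstrap resampling and feature leave-one-out.

Bootstrap stability reruns the whole tournament + Bradley–Terry fit on
per-species subsamples (default 20 replicates of 80% of patches, drawn
without replacement to preserve class balance) and reports the Spearman
correlation of each replicate ranking against the full-data ranking.
Feature leave-one-out reruns the tournament with each triplet feature
removed in turn, measuring how much any single feature drives the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .features import TRIPLET_COLUMNS
from .io_annot import ValidationError
from .tournament import fit_bradley_terry, run_tournament


@dataclass
class StabilityReport:
    n_boot: int
    frac: float
    per_replicate_rho: list[float]
    rho_mean: float
    rho_sd: float
    per_species_rank_variance: pd.Series
    zero_variance_count: int
    replicate_ranks: pd.DataFrame = field(repr=False, default=None)  # species × replicate


@dataclass
class LooReport:
    configurations: dict[str, pd.DataFrame]  # left-out feature -> score table
    rho: dict[str, float]  # left-out feature -> Spearman vs full ranking

    @property
    def rho_min(self) -> float:
        return min(self.rho.values())


def _rank_series(table: pd.DataFrame) -> pd.Series:
    return table.set_index("species")["rank"]


def _fit_ranks(triplets: pd.DataFrame, seed: int, **tournament_kwargs) -> pd.Series:
    wm = run_tournament(triplets, seed=seed, **tournament_kwargs)
    return _rank_series(fit_bradley_terry(wm))


def bootstrap_ranks(
    triplets: pd.DataFrame,
    n_boot: int = 20,
    frac: float = 0.8,
    seed: int = 0,
    full_ranks: pd.Series | None = None,
    **tournament_kwargs,
) -> StabilityReport:
    """Bootstrap rank stability of the complexity ranking.

    Each replicate keeps ⌊frac·n⌋ patches per species (without replacement),
    reruns the tournament (pairings redrawn with a replicate-derived seed)
    and the Bradley–Terry fit, and is compared to the full-data ranking by
    Spearman correlation.
    """
    if not (0.0 < frac <= 1.0):
        raise ValidationError(f"frac must be in (0, 1], got {frac}")
    if full_ranks is None:
        full_ranks = _fit_ranks(triplets, seed=seed, **tournament_kwargs)
    species = list(full_ranks.index)

    rng = np.random.default_rng(seed)
    rhos: list[float] = []
    rank_cols = {}
    for b in range(n_boot):
        keep_parts = []
        for sp, sub in triplets.groupby("species"):
            m = int(np.floor(frac * len(sub)))
            pick = rng.choice(len(sub), size=m, replace=False)
            keep_parts.append(sub.iloc[np.sort(pick)])
        replicate = pd.concat(keep_parts)
        rep_ranks = _fit_ranks(replicate, seed=seed + b + 1, **tournament_kwargs)
        rep_ranks = rep_ranks.reindex(species)
        rho = float(spearmanr(full_ranks.to_numpy(), rep_ranks.to_numpy()).statistic)
        rhos.append(rho)
        rank_cols[f"rep{b:02d}"] = rep_ranks

    replicate_ranks = pd.DataFrame(rank_cols)
    rank_var = replicate_ranks.var(axis=1, ddof=0)
    return StabilityReport(
        n_boot=n_boot,
        frac=frac,
        per_replicate_rho=rhos,
        rho_mean=float(np.mean(rhos)),
        rho_sd=float(np.std(rhos)),
        per_species_rank_variance=rank_var,
        zero_variance_count=int((rank_var == 0).sum()),
        replicate_ranks=replicate_ranks,
    )


def feature_loo(
    triplets: pd.DataFrame,
    seed: int = 0,
    full_ranks: pd.Series | None = None,
    feature_cols: list[str] | None = None,
    **tournament_kwargs,
) -> LooReport:
    """Leave each triplet feature out, re-rank, and compare to the full ranking."""
    if feature_cols is None:
        feature_cols = list(TRIPLET_COLUMNS)
    if full_ranks is None:
        full_ranks = _fit_ranks(
            triplets, seed=seed, feature_cols=feature_cols, **tournament_kwargs
        )
    species = list(full_ranks.index)

    configurations: dict[str, pd.DataFrame] = {}
    rho: dict[str, float] = {}
    for left_out in feature_cols:
        reduced = [c for c in feature_cols if c != left_out]
        wm = run_tournament(
            triplets, seed=seed, feature_cols=reduced, **tournament_kwargs
        )
        table = fit_bradley_terry(wm)
        configurations[left_out] = table
        loo_ranks = _rank_series(table).reindex(species)
        rho[left_out] = float(
            spearmanr(full_ranks.to_numpy(), loo_ranks.to_numpy()).statistic
        )
    return LooReport(configurations=configurations, rho=rho)
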