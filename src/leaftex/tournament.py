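"""Pairwise complexity game and Bradley–Terry species scoring.

Patches from different species are pitted against each other: for each of
the three complexity-triplet features the patch with the strictly greater
value takes that feature's point (exact equality splits it). Win credit is
accumulated into a species×species win matrix and a Bradley–Terry model
P(i beats j) = π_i / (π_i + π_j) is fitted by minorization–maximization,
yielding one ability per species, a min–max normalized score in [0, 1],
and a rank (1 = least complex).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import TRIPLET_COLUMNS
from .io_annot import ValidationError


@dataclass(frozen=True)
class DuelOutcome:
    patch_a: str
    patch_b: str
    wins_a: int
    wins_b: int
    ties: int


@dataclass
class WinMatrix:
    """Species×species win credit and match counts, plus per-patch win fractions."""

    species: list[str]
    w: pd.DataFrame  # w.loc[i, j] = win credit of i over j (ties count ½)
    n_matches: pd.DataFrame  # feature points contested between i and j
    patch_stats: pd.DataFrame  # patch_id × (species, points_won, points_contested, win_fraction)


def _triplet_values(t) -> tuple[str, np.ndarray]:
    if isinstance(t, pd.Series):
        name = str(t.name) if t.name is not None else ""
        vals = np.array([t[c] for c in TRIPLET_COLUMNS], dtype=float)
    else:
        name = getattr(t, "patch_id", "")
        vals = np.array(
            [t.info_density, t.heterogeneity, t.variability], dtype=float
        )
    return name, vals


def duel(a, b) -> DuelOutcome:
    """One match: three independent feature comparisons, greater value wins."""
    name_a, va = _triplet_values(a)
    name_b, vb = _triplet_values(b)
    if not (np.isfinite(va).all() and np.isfinite(vb).all()):
        raise ValidationError(f"non-finite triplet in duel {name_a!r} vs {name_b!r}")
    wins_a = int(np.sum(va > vb))
    wins_b = int(np.sum(vb > va))
    return DuelOutcome(name_a, name_b, wins_a, wins_b, len(va) - wins_a - wins_b)


def run_tournament(
    triplets: pd.DataFrame,
    pairs_per_species_pair: int = 1000,
    seed: int = 0,
    feature_cols: list[str] | None = None,
    mode: str = "per_feature",
    exhaustive: bool = False,
) -> WinMatrix:
    """Play the complexity game over all species pairs.

    ``triplets`` is a per-patch table with a ``species`` column and the
    feature columns (default: the complexity triplet). For each unordered
    species pair, ``pairs_per_species_pair`` patch pairs are drawn uniformly
    with replacement (or all cross pairs when ``exhaustive``). In
    ``per_feature`` mode every feature contributes its own point; in
    ``majority`` mode each match yields a single point to the patch winning
    the majority of feature comparisons.
    """
    if feature_cols is None:
        feature_cols = list(TRIPLET_COLUMNS)
    if mode not in ("per_feature", "majority"):
        raise ValidationError(f"unknown duel mode {mode!r}")
    if "species" not in triplets.columns:
        raise ValidationError("triplet table needs a 'species' column")
    vals_all = triplets[feature_cols].to_numpy(float)
    if not np.isfinite(vals_all).all():
        raise ValidationError("non-finite feature values in triplet table")

    species = sorted(triplets["species"].unique())
    if len(species) < 2:
        raise ValidationError("tournament needs ≥ 2 species")
    sp_index: dict[str, np.ndarray] = {
        sp: np.flatnonzero((triplets["species"] == sp).to_numpy()) for sp in species
    }
    small = {sp: len(ix) for sp, ix in sp_index.items() if len(ix) < 2}
    if small:
        raise ValidationError(f"species with < 2 patches: {small}")

    n_feat = len(feature_cols)
    w = pd.DataFrame(0.0, index=species, columns=species)
    n_matches = pd.DataFrame(0, index=species, columns=species)
    points_won = np.zeros(len(triplets))
    points_contested = np.zeros(len(triplets))
    rng = np.random.default_rng(seed)

    for sp_a, sp_b in itertools.combinations(species, 2):
        ia_pool, ib_pool = sp_index[sp_a], sp_index[sp_b]
        if exhaustive:
            ia = np.repeat(ia_pool, len(ib_pool))
            ib = np.tile(ib_pool, len(ia_pool))
        else:
            ia = ia_pool[rng.integers(len(ia_pool), size=pairs_per_species_pair)]
            ib = ib_pool[rng.integers(len(ib_pool), size=pairs_per_species_pair)]
        va, vb = vals_all[ia], vals_all[ib]
        gt = va > vb
        lt = va < vb
        eq = ~(gt | lt)
        if mode == "per_feature":
            pa = gt.sum(axis=1) + 0.5 * eq.sum(axis=1)
            per_match = n_feat
        else:
            net = gt.sum(axis=1) - lt.sum(axis=1)
            pa = (net > 0) + 0.5 * (net == 0)
            per_match = 1
        total = per_match * len(ia)
        w.loc[sp_a, sp_b] += float(pa.sum())
        w.loc[sp_b, sp_a] += float(total - pa.sum())
        n_matches.loc[sp_a, sp_b] += total
        n_matches.loc[sp_b, sp_a] += total
        np.add.at(points_won, ia, pa)
        np.add.at(points_won, ib, per_match - pa)
        np.add.at(points_contested, ia, per_match)
        np.add.at(points_contested, ib, per_match)

    with np.errstate(invalid="ignore"):
        winfrac = np.where(points_contested > 0, points_won / points_contested, np.nan)
    patch_stats = pd.DataFrame(
        {
            "species": triplets["species"].to_numpy(),
            "points_won": points_won,
            "points_contested": points_contested,
            "win_fraction": winfrac,
        },
        index=triplets.index.rename("patch_id"),
    )
    return WinMatrix(species=species, w=w, n_matches=n_matches, patch_stats=patch_stats)


def fit_bradley_terry(
    W: WinMatrix | pd.DataFrame,
    max_iter: int = 1_000_000,
    tol: float = 1e-10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Maximum-likelihood Bradley–Terry abilities by MM iteration.

    A pseudocount (default 0.5 win credit per ordered pair) guarantees a
    finite MLE even under total domination. Abilities are normalized to
    Σ log π = 0; the score column is the min–max rescaled log-ability and
    rank 1 goes to the least complex species.
    """
    wdf = W.w if isinstance(W, WinMatrix) else W
    species = list(wdf.index)
    n = len(species)
    w = wdf.to_numpy(float) + pseudocount
    np.fill_diagonal(w, 0.0)
    n_ij = w + w.T
    if np.any((w.sum(axis=1) == 0) | (w.sum(axis=0) == 0)):
        raise ValidationError(
            "comparison graph not connected: some species has no wins or no losses"
        )

    pi = np.ones(n)
    for iteration in range(max_iter):
        # diagonal of n_ij is zero, so the j=i term contributes nothing
        denom = (n_ij / (pi[:, None] + pi[None, :])).sum(axis=1)
        new_pi = w.sum(axis=1) / denom
        new_pi /= np.exp(np.mean(np.log(new_pi)))
        delta = np.max(np.abs(np.log(new_pi) - np.log(pi)))
        pi = new_pi
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"Bradley–Terry MM did not converge in {max_iter} iterations "
            f"(last max |Δ log π| = {delta:.3e})"
        )

    log_pi = np.log(pi)
    spread = log_pi.max() - log_pi.min()
    if spread < 1e-12:
        score = np.full(n, 0.5)
    else:
        score = (log_pi - log_pi.min()) / spread
    table = pd.DataFrame(
        {
            "species": species,
            "bt_ability": pi,
            "log_ability": log_pi,
            "score": score,
            "group": [None] * n,
        }
    )
    order = table.sort_values(["score", "species"], kind="stable").index
    ranks = pd.Series(np.arange(1, n + 1), index=order)
    table["rank"] = ranks.reindex(table.index).to_numpy()
    return table[["species", "bt_ability", "log_ability", "score", "rank", "group"]]


def rank_species(table: pd.DataFrame) -> pd.DataFrame:
    """Order the score table by ascending score, ties by species name."""
    out = table.sort_values(["score", "species"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
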