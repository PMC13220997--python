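"""Complexity groups from pairwise Kruskal–Wallis tests.

Two species belong to the same complexity group when their per-patch
tournament win fractions are statistically indistinguishable. All species
pairs are tested with the two-sample Kruskal–Wallis rank test, p-values are
Benjamini–Hochberg adjusted across the pair family, and species are merged
by average-linkage hierarchical clustering on d = −log₁₀(p_adj), cutting
the tree at −log₁₀(alpha).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, kruskal
from statsmodels.stats.multitest import multipletests

from .io_annot import ValidationError

P_FLOOR = 1e-16


@dataclass
class PairwiseTestMatrix:
    species: list[str]
    H: pd.DataFrame  # test statistics (NaN on the diagonal)
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame  # BH-adjusted across the pair family


@dataclass
class ComplexityGroups:
    labels: pd.Series  # species -> group label (1 = lowest-complexity group)
    linkage: np.ndarray  # scipy linkage matrix
    alpha: float

    @property
    def n_groups(self) -> int:
        return int(self.labels.nunique())


def pairwise_kw(
    per_patch_values: pd.DataFrame,
    value_col: str = "win_fraction",
    test: str = "kruskal",
    adjust: str = "bh",
) -> PairwiseTestMatrix:
    """All-pairs two-sample Kruskal–Wallis tests on per-patch complexity values.

    ``per_patch_values`` has one row per patch with ``species`` and the value
    column (by default the tournament win fraction). ``test='anova'`` swaps
    in a parametric one-way F-test; ``adjust='none'`` skips BH correction.
    """
    if test not in ("kruskal", "anova"):
        raise ValidationError(f"unknown test {test!r}")
    groups = {
        sp: sub[value_col].to_numpy(float)
        for sp, sub in per_patch_values.groupby("species")
    }
    too_small = {sp: len(v) for sp, v in groups.items() if len(v) < 3}
    if too_small:
        raise ValidationError(f"species with < 3 values: {too_small}")

    species = sorted(groups)
    H = pd.DataFrame(np.nan, index=species, columns=species)
    p_raw = pd.DataFrame(1.0, index=species, columns=species)
    pairs = list(itertools.combinations(species, 2))
    pvals = []
    for a, b in pairs:
        if test == "kruskal":
            stat, p = kruskal(groups[a], groups[b])
        else:
            stat, p = f_oneway(groups[a], groups[b])
        H.loc[a, b] = H.loc[b, a] = stat
        p_raw.loc[a, b] = p_raw.loc[b, a] = p
        pvals.append(p)

    p_adj = p_raw.copy()
    if adjust == "bh" and pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for (a, b), q in zip(pairs, adj):
            p_adj.loc[a, b] = p_adj.loc[b, a] = q
    return PairwiseTestMatrix(species=species, H=H, p_raw=p_raw, p_adj=p_adj)


def cluster_groups(
    tests: PairwiseTestMatrix,
    alpha: float = 0.05,
    species_scores: pd.Series | None = None,
) -> ComplexityGroups:
    """Average-linkage clustering on −log₁₀(p_adj), cut at −log₁₀(alpha).

    Species pairs that cannot be distinguished at level ``alpha`` tend to
    co-group. Group labels are renumbered so group 1 has the lowest median
    complexity score (``species_scores``, e.g. the Bradley–Terry score);
    without scores, groups are numbered by species-name order of their
    lowest member.
    """
    species = tests.species
    dist = -np.log10(np.maximum(tests.p_adj.loc[species, species].to_numpy(float), P_FLOOR))
    np.fill_diagonal(dist, 0.0)
    if len(species) == 1:
        Z = np.empty((0, 4))
        raw = np.array([1])
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(Z, t=-np.log10(alpha), criterion="distance")

    labels = pd.Series(raw, index=pd.Index(species, name="species"))
    if species_scores is not None:
        key = labels.groupby(labels).apply(
            lambda members: float(np.median(species_scores.reindex(members.index)))
        )
    else:
        key = labels.groupby(labels).apply(lambda members: min(members.index))
    order = {old: new for new, old in enumerate(key.sort_values().index, start=1)}
    labels = labels.map(order)
    return ComplexityGroups(labels=labels, linkage=Z, alpha=alpha)
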