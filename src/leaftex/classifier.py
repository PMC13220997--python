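"""Species classification of texture patches by k-nearest neighbors (k=3).

Validation is group-aware: patches from the same source image (or leaf, or
tree) never straddle a train/test boundary, so reported accuracy measures
generalization to unseen imaging areas rather than patch-overlap recall.
The spectral PCA is refit inside each training fold to keep the feature
pipeline free of test-set leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import feature_columns, fit_spectral_model_from_spectra
from .io_annot import ValidationError

GROUPING_KEYS = {"source_image": "image_id", "leaf": "leaf_id", "tree": "tree_id"}


@dataclass
class SplitPlan:
    """Fold assignment per patch; all patches of one group share a fold."""

    assignments: pd.Series  # patch_id -> fold index
    grouping: str
    n_folds: int

    def fold_ids(self, fold: int) -> pd.Index:
        return self.assignments.index[self.assignments == fold]


@dataclass
class ClassificationReport:
    accuracy: float
    confusion: pd.DataFrame  # true species × predicted species counts
    per_fold_accuracy: list[float] = field(default_factory=list)


def make_split(
    patch_manifest: pd.DataFrame,
    grouping: str = "source_image",
    n_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Grouped, species-stratified fold assignment.

    Within each species its grouping-key values are shuffled (seeded) and
    dealt round-robin to folds, so every fold sees every species and no
    group is split.
    """
    if grouping not in GROUPING_KEYS:
        raise ValidationError(f"unknown grouping {grouping!r}; options {list(GROUPING_KEYS)}")
    key = GROUPING_KEYS[grouping]
    df = patch_manifest.reset_index() if "patch_id" not in patch_manifest.columns else patch_manifest
    rng = np.random.default_rng(seed)

    group_fold: dict[tuple[str, str], int] = {}
    for sp in sorted(df["species"].unique()):
        groups = sorted(df.loc[df["species"] == sp, key].astype(str).unique())
        if len(groups) < n_folds:
            raise ValidationError(
                f"species {sp!r} has {len(groups)} distinct {grouping} groups "
                f"but n_folds={n_folds}"
            )
        rng.shuffle(groups)
        for i, g in enumerate(groups):
            group_fold[(sp, g)] = i % n_folds

    folds = [
        group_fold[(sp, g)]
        for sp, g in zip(df["species"], df[key].astype(str))
    ]
    assignments = pd.Series(folds, index=pd.Index(df["patch_id"], name="patch_id"))
    return SplitPlan(assignments=assignments, grouping=grouping, n_folds=n_folds)


def _is_spectral(name: str) -> bool:
    return name.startswith("s") and name[1:].isdigit()


def _standardize(train_X: np.ndarray, test_X: np.ndarray, names: list[str]):
    """Training-set standardization with block treatment of spectral scores.

    Scalar features with heterogeneous units are z-scored per column.
    The spectral PCA scores (columns s01, s02, …) all share one unit
    (log-power), so they are centered per column but scaled by a single
    pooled std: per-column z-scoring would inflate minor components —
    which by PCA construction carry little variance and mostly patch
    noise — to the same weight as the leading ones and swamp the
    Euclidean metric. Block scaling keeps the block's total variance
    equal to that of z-scored columns while preserving the components'
    natural relative scale. Zero-variance columns are dropped with a
    warning.
    """
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    spectral = np.array([_is_spectral(n) for n in names])
    scale = sd.copy()
    if spectral.any():
        pooled = np.sqrt((sd[spectral] ** 2).mean())
        scale[spectral] = pooled
    keep = scale > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance feature columns: {dropped}", stacklevel=3)
    return (
        (train_X[:, keep] - mu[keep]) / scale[keep],
        (test_X[:, keep] - mu[keep]) / scale[keep],
    )


def _vote(labels: np.ndarray, dists: np.ndarray) -> str:
    """Majority vote; ties by summed inverse distance, then lexicographic label."""
    counts: dict[str, int] = {}
    invd: dict[str, float] = {}
    for lab, d in zip(labels, dists):
        counts[lab] = counts.get(lab, 0) + 1
        invd[lab] = invd.get(lab, 0.0) + (np.inf if d == 0 else 1.0 / d)
    return min(counts, key=lambda lab: (-counts[lab], -invd[lab], lab))


def knn_classify(
    train_features: pd.DataFrame,
    test_features: pd.DataFrame,
    k: int = 3,
    label_col: str = "species",
    columns: list[str] | None = None,
) -> ClassificationReport:
    """kNN with z-score standardization (train statistics) and Euclidean distance."""
    if columns is None:
        columns = feature_columns(train_features)
    missing = [c for c in columns if c not in test_features.columns]
    if missing:
        raise ValidationError(f"test features missing columns: {missing}")
    if k > len(train_features):
        raise ValidationError(f"k={k} exceeds training size {len(train_features)}")

    train_X, test_X = _standardize(
        train_features[columns].to_numpy(float),
        test_features[columns].to_numpy(float),
        columns,
    )
    train_y = train_features[label_col].to_numpy(str)
    true_y = test_features[label_col].to_numpy(str)

    nn = NearestNeighbors(n_neighbors=k).fit(train_X)
    dists, idx = nn.kneighbors(test_X)
    pred_y = np.array([_vote(train_y[ix], d) for ix, d in zip(idx, dists)])

    species = sorted(set(train_y) | set(true_y))
    confusion = pd.DataFrame(0, index=species, columns=species)
    for t, p in zip(true_y, pred_y):
        confusion.loc[t, p] += 1
    accuracy = float((pred_y == true_y).mean()) if len(true_y) else float("nan")
    return ClassificationReport(accuracy=accuracy, confusion=confusion,
                                per_fold_accuracy=[accuracy])


def cross_validated_accuracy(
    features: pd.DataFrame,
    plan: SplitPlan,
    k: int = 3,
    spectra: pd.DataFrame | None = None,
    n_components: int = 25,
) -> ClassificationReport:
    """Grouped cross-validation with per-fold spectral-PCA refit.

    ``features`` holds the non-spectral feature block (plus species labels);
    when ``spectra`` (patch_id × radial bins) is provided, a spectral model
    is fitted on each training fold and its 25 scores appended to both
    partitions before classification.
    """
    not_covered = features.index.difference(plan.assignments.index)
    if len(not_covered):
        raise ValidationError(f"split plan does not cover patches: {list(not_covered)[:5]}")

    confusions: list[pd.DataFrame] = []
    per_fold = []
    for fold in range(plan.n_folds):
        test_ids = plan.fold_ids(fold).intersection(features.index)
        train_ids = features.index.difference(test_ids)
        train = features.loc[train_ids].copy()
        test = features.loc[test_ids].copy()

        missing_species = set(test["species"]) - set(train["species"])
        if missing_species:
            warnings.warn(
                f"fold {fold}: species absent from training, excluded from test: "
                f"{sorted(missing_species)}", stacklevel=2,
            )
            test = test[~test["species"].isin(missing_species)]
        if test.empty:
            continue

        if spectra is not None:
            model = fit_spectral_model_from_spectra(
                spectra.loc[train.index].to_numpy(float), n_components
            )
            for part in (train, test):
                scores = model.transform_spectra(spectra.loc[part.index].to_numpy(float))
                for i in range(scores.shape[1]):
                    part[f"s{i + 1:02d}"] = scores[:, i]

        report = knn_classify(train, test, k=k)
        confusions.append(report.confusion)
        per_fold.append(report.accuracy)

    species = sorted(set().union(*(c.index for c in confusions)))
    pooled = pd.DataFrame(0, index=species, columns=species)
    for c in confusions:
        pooled = pooled.add(c, fill_value=0).astype(int)
    accuracy = float(np.trace(pooled.values) / pooled.values.sum())
    return ClassificationReport(accuracy=accuracy, confusion=pooled,
                                per_fold_accuracy=per_fold)
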