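"""Random-forest pathogenicity classifier.

The score of a variant is the ensemble average f(X) = (1/T) * sum_t h_t(X)
over T trees, each tree contributing the constant value of the terminal node
(region) the feature vector falls into -- for a classification forest, the
pathogenic-class fraction of that leaf.  Hyperparameters follow the
randomForest-style vocabulary: ``mtry`` (features considered per split),
``ntree`` (number of trees) and ``max_node`` (cap on terminal nodes per
tree).  Training uses stratified five-fold cross-validation with a grid
search maximizing out-of-fold AUROC; missing feature values are median
imputed with medians fitted on the training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import apply_medians, impute_median

_ARCHIVE_VERSION = 1


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameter grid and CV settings.

    Defaults are the optimum of the full grid search: mtry=20, ntree=200,
    max_node=30, selected by mean out-of-fold AUROC over 5 folds.
    """

    mtry_grid: tuple[int, ...] = (2, 5, 10, 15, 20)
    ntree_grid: tuple[int, ...] = (20, 50, 100, 200, 300, 400)
    max_node_grid: tuple[int, ...] = (5, 10, 20, 30)
    folds: int = 5
    seed: int = 0
    mtry: int = 20
    ntree: int = 200
    max_node: int = 30

    def __post_init__(self) -> None:
        if not (self.mtry_grid and self.ntree_grid and self.max_node_grid):
            raise ModelError("hyperparameter grids must be non-empty")
        if self.folds < 2:
            raise ModelError("folds must be >= 2")

    @property
    def grid(self) -> list[tuple[int, int, int]]:
        """All (mtry, ntree, max_node) combinations (5 x 6 x 4 = 120 by default)."""
        return list(product(self.mtry_grid, self.ntree_grid, self.max_node_grid))


@dataclass
class TrainedForest:
    """A fitted forest plus everything needed to reproduce its predictions."""

    forest: RandomForestClassifier
    medians: pd.Series
    feature_names: tuple[str, ...]
    hyperparams: dict
    seed: int
    cv_auroc: float | None = None
    metadata: dict = field(default_factory=dict)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ModelError("labels must contain both classes")


def _make_forest(mtry: int, ntree: int, max_node: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        max_leaf_nodes=max_node,
        random_state=seed,
        n_jobs=1,
    )


def _as_matrix(features: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(features, pd.DataFrame):
        raise ModelError("features must be a pandas DataFrame with named columns")
    return features


def cross_val_auroc(
    features: pd.DataFrame,
    labels,
    mtry: int,
    ntree: int,
    max_node: int,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean out-of-fold AUROC for one hyperparameter combination.

    Folds are stratified to preserve the class ratio; per-fold imputation
    medians are fitted on the fold's training rows only.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    _check_two_classes(y)
    if len(y) < folds:
        raise ModelError(f"need at least {folds} rows for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aurocs = []
    for k, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, med = impute_median(X.iloc[tr])
        Xva = apply_medians(X.iloc[va], med)
        clf = _make_forest(mtry, ntree, max_node, seed + k)
        clf.fit(Xtr, y[tr])
        p = clf.predict_proba(Xva)[:, 1]
        aurocs.append(roc_auc_score(y[va], p))
    return float(np.mean(aurocs))


def grid_search_cv(
    features: pd.DataFrame, labels, config: ModelConfig
) -> tuple[dict, pd.DataFrame]:
    """Evaluate every grid point by mean out-of-fold AUROC.

    Deterministic given ``config.seed``.  Ties are broken by smaller ntree,
    then smaller max_node.  Returns the best hyperparameters and the full CV
    table (one row per combination).
    """
    rows = []
    for mtry, ntree, max_node in config.grid:
        auroc = cross_val_auroc(
            features, labels, mtry, ntree, max_node, config.folds, config.seed
        )
        rows.append({"mtry": mtry, "ntree": ntree, "max_node": max_node, "cv_auroc": auroc})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["cv_auroc", "ntree", "max_node"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    params = {"mtry": int(best.mtry), "ntree": int(best.ntree), "max_node": int(best.max_node)}
    return params, table


def train(
    features: pd.DataFrame,
    labels,
    hyperparams: dict | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> TrainedForest:
    """Fit the final forest on all training rows with the given hyperparameters.

    Imputation medians are fitted on the training rows and stored for reuse
    at prediction time.  ``cv_auroc`` records the cross-validated AUROC of
    the chosen hyperparameters on the same data.
    """
    config = config or ModelConfig(seed=seed)
    hp = hyperparams or {"mtry": config.mtry, "ntree": config.ntree, "max_node": config.max_node}
    X = _as_matrix(features)
    y = np.asarray(labels)
    _check_two_classes(y)
    Ximp, medians = impute_median(X)
    clf = _make_forest(hp["mtry"], hp["ntree"], hp["max_node"], seed)
    clf.fit(Ximp, y)
    cv = cross_val_auroc(
        X, y, hp["mtry"], hp["ntree"], hp["max_node"], config.folds, seed
    )
    return TrainedForest(
        forest=clf,
        medians=medians,
        feature_names=tuple(X.columns),
        hyperparams=dict(hp),
        seed=seed,
        cv_auroc=cv,
    )


def predict(model: TrainedForest, features: pd.DataFrame) -> np.ndarray:
    """Score variants with a trained forest; scores lie in [0, 1].

    Missing values are imputed with the medians stored at training time.
    The feature registry must match the model's exactly (names and order).
    """
    X = _as_matrix(features)
    if tuple(X.columns) != model.feature_names:
        raise ModelError(
            "feature registry mismatch: model was trained on "
            f"{model.feature_names}, got {tuple(X.columns)}"
        )
    Ximp = apply_medians(X, model.medians)
    return model.forest.predict_proba(Ximp)[:, 1]


def importance(model: TrainedForest) -> pd.DataFrame:
    """Per-feature total Gini-impurity decrease, normalized to max = 100.

    Returns one row per feature, descending by importance.
    """
    imp = model.forest.feature_importances_
    top = imp.max()
    norm = imp / top * 100.0 if top > 0 else imp
    return (
        pd.DataFrame({"feature": model.feature_names, "importance": norm})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def evaluate(scores, labels) -> dict[str, float]:
    """AUROC (rank statistic, ties averaged) and AUPRC (step-interpolated)."""
    y = np.asarray(labels)
    _check_two_classes(y)
    s = np.asarray(scores, dtype=float)
    return {
        "auroc": float(roc_auc_score(y, s)),
        "auprc": float(average_precision_score(y, s)),
    }


def save_model(model: TrainedForest, path: str | Path) -> None:
    """Serialize a trained forest as a versioned single-file archive."""
    joblib.dump(
        {
            "version": _ARCHIVE_VERSION,
            "forest": model.forest,
            "medians": model.medians,
            "feature_names": model.feature_names,
            "hyperparams": model.hyperparams,
            "seed": model.seed,
            "cv_auroc": model.cv_auroc,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path: str | Path, expected_features: tuple[str, ...] | None = None) -> TrainedForest:
    """Load a model archive; refuse on version or feature-registry mismatch."""
    d = joblib.load(path)
    if d.get("version") != _ARCHIVE_VERSION:
        raise ModelError(f"unsupported model archive version {d.get('version')}")
    names = tuple(d["feature_names"])
    if expected_features is not None and names != tuple(expected_features):
        raise ModelError("feature registry mismatch in model archive")
    return TrainedForest(
        forest=d["forest"],
        medians=d["medians"],
        feature_names=names,
        hyperparams=d["hyperparams"],
        seed=d["seed"],
        cv_auroc=d["cv_auroc"],
        metadata=d.get("metadata", {}),
    )
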