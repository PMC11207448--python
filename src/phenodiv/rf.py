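"""Random-forest discriminant validation of cluster groups.

The cluster partition is treated as a known class label and a
Breiman-style random forest (bootstrap per tree, ``mtry`` candidate
features per split, majority vote) is trained on the key traits using a
stratified 70/30 train/test split.  ``mtry`` is tuned by out-of-bag
misclassification over a grid (k-fold cross-validation available), and
variable importance is mean decrease in accuracy: the drop in accuracy
when one feature's values are permuted, averaged over seeded repeats.

Accuracy is reported per class plus two conventions of "average":
macro (mean of per-class accuracies) and micro (pooled correct / total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .catalog import PUBLISHED_KEY_TRAITS
from .simulate import TraitMatrix

__all__ = ["RFConfig", "RFReport", "split", "fit_forest", "tune_mtry",
           "importance", "validate_groups"]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest validation settings."""

    n_trees: int = 500
    mtry_grid: tuple[int, ...] = ()     # empty -> 1..n_features
    train_fraction: float = 0.7
    seed: int = 0
    n_cv_folds: int = 5
    stratify: bool = True
    tune_by: str = "oob"                # "oob" or "cv"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split(
    X: np.ndarray,
    labels: np.ndarray,
    config: RFConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded train/test split at ``train_fraction`` (stratified by default).

    The training set holds ``floor(train_fraction * n)`` samples.  Under a
    non-stratified split a class can end up absent from the training set;
    that degenerate outcome triggers a warning rather than an error.
    """
    labels = np.asarray(labels)
    strat = labels if config.stratify else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        np.asarray(X, dtype=float),
        labels,
        train_size=config.train_fraction,
        random_state=config.seed,
        stratify=strat,
    )
    missing = set(np.unique(labels)) - set(np.unique(y_tr))
    if missing:
        warnings.warn(f"class(es) absent from training set: {sorted(missing)}",
                      stacklevel=2)
    return X_tr, X_te, y_tr, y_te


def fit_forest(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RFConfig,
    mtry: int,
    *,
    oob: bool = True,
) -> RandomForestClassifier:
    """Train a seeded random forest with ``mtry`` split candidates."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data holds a single class")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=mtry,
        oob_score=oob,
        bootstrap=True,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        # tiny classes can leave some trees without OOB samples
        warnings.simplefilter("ignore", UserWarning)
        clf.fit(X_train, y_train)
    return clf


def tune_mtry(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: RFConfig,
) -> tuple[int, pd.Series]:
    """Misclassification per ``mtry``; returns the argmin (smallest mtry wins ties).

    Evaluation is out-of-bag error by default, or ``config.n_cv_folds``-fold
    stratified cross-validation when ``config.tune_by == "cv"``.
    """
    n_features = X_train.shape[1]
    grid = config.mtry_grid or tuple(range(1, n_features + 1))
    if any(m > n_features for m in grid):
        raise ValueError("mtry exceeds the number of features")
    errors = {}
    for m in grid:
        if config.tune_by == "cv":
            cv = StratifiedKFold(
                n_splits=config.n_cv_folds, shuffle=True, random_state=config.seed
            )
            clf = RandomForestClassifier(
                n_estimators=config.n_trees, max_features=m,
                random_state=config.seed,
            )
            acc = cross_val_score(clf, X_train, y_train, cv=cv).mean()
            errors[m] = 100.0 * (1.0 - acc)
        else:
            clf = fit_forest(X_train, y_train, config, m, oob=True)
            errors[m] = 100.0 * (1.0 - clf.oob_score_)
    curve = pd.Series(errors, name="misclassification_percent")
    best = min(grid, key=lambda m: (errors[m], m))
    return int(best), curve


def importance(
    clf: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    *,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Mean-decrease-accuracy importance, descending; catalog order breaks ties."""
    res = permutation_importance(
        clf, X, y, n_repeats=n_repeats, random_state=seed, scoring="accuracy"
    )
    s = pd.Series(res.importances_mean, index=feature_names, name="mean_decrease_accuracy")
    order = sorted(
        range(len(feature_names)), key=lambda j: (-round(s.iloc[j], 12), j)
    )
    return s.iloc[order]


@dataclass
class RFReport:
    """Per-class and average accuracies plus the tuning curve and importances."""

    best_mtry: int
    misclassification_curve: pd.Series
    per_class: pd.DataFrame   # index class; columns n_train, correct_train, ...
    macro_accuracy: dict      # {"train": %, "test": %}
    micro_accuracy: dict      # {"train": %, "test": %}
    importances: pd.Series
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_mtry": self.best_mtry,
            "misclassification_percent_by_mtry": {
                int(k): float(v) for k, v in self.misclassification_curve.items()
            },
            "per_class": self.per_class.to_dict(orient="index"),
            "macro_accuracy_percent": self.macro_accuracy,
            "micro_accuracy_percent": self.micro_accuracy,
            "importance_mean_decrease_accuracy": {
                k: float(v) for k, v in self.importances.items()
            },
            "features": list(self.feature_names),
        }


def _class_accuracy(y_true, y_pred, classes) -> pd.DataFrame:
    rows = {}
    for c in classes:
        mask = y_true == c
        n = int(mask.sum())
        correct = int((y_pred[mask] == c).sum())
        rows[c] = {
            "n": n,
            "correct": correct,
            "accuracy_percent": 100.0 * correct / n if n else np.nan,
        }
    return pd.DataFrame(rows).T


def validate_groups(
    matrix: TraitMatrix,
    labels: np.ndarray,
    config: RFConfig | None = None,
    features: tuple[str, ...] = PUBLISHED_KEY_TRAITS,
) -> RFReport:
    """Full discriminant validation on the key-trait subset.

    Splits 70/30, tunes ``mtry``, refits at the best value, and reports
    per-class and average accuracies on both partitions together with
    permutation importances computed on the whole panel.
    """
    config = config or RFConfig()
    labels = np.asarray(labels)
    X = np.column_stack([matrix.column(f) for f in features])
    X_tr, X_te, y_tr, y_te = split(X, labels, config)
    best, curve = tune_mtry(X_tr, y_tr, config)
    clf = fit_forest(X_tr, y_tr, config, best)
    classes = sorted(np.unique(labels))

    pred_tr = clf.predict(X_tr)
    pred_te = clf.predict(X_te)
    tab_tr = _class_accuracy(y_tr, pred_tr, classes)
    tab_te = _class_accuracy(y_te, pred_te, classes)
    per_class = tab_tr.join(tab_te, lsuffix="_train", rsuffix="_test")

    macro = {
        "train": float(np.nanmean(tab_tr["accuracy_percent"])),
        "test": float(np.nanmean(tab_te["accuracy_percent"])),
    }
    micro = {
        "train": 100.0 * float((pred_tr == y_tr).mean()),
        "test": 100.0 * float((pred_te == y_te).mean()),
    }
    imp = importance(clf, X, labels, list(features), seed=config.seed)
    return RFReport(
        best_mtry=best,
        misclassification_curve=curve,
        per_class=per_class,
        macro_accuracy=macro,
        micro_accuracy=micro,
        importances=imp,
        feature_names=list(features),
    )
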