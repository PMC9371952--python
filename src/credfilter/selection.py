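"""Cross-validated feature selection and seeded model search.

Feature selection is backward recursive feature elimination (RFE) driven
by the absolute coefficients of a regularized logistic model, with the
retained feature count capped at 30% of the topic's sample size.  Model
search is an exhaustive seeded grid over three families — regularized
linear, gradient-boosted trees and a multilayer perceptron — scored by the
mean cross-validated F1 of the positive (credible) class.  The winner's
out-of-fold probabilities feed the downstream cutoff selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .corpus import NEGATIVE, POSITIVE
from .features import FeatureMatrix, FeatureSpec

__all__ = [
    "MODEL_FAMILIES",
    "FoldAssignment",
    "ModelConfig",
    "OOFPredictions",
    "make_folds",
    "default_fold_count",
    "rfe_select",
    "default_grids",
    "model_search",
    "evaluate_roc",
    "encode_labels",
]

#: simpler-first order used for tie-breaking in the model search
MODEL_FAMILIES = ("regularized-linear", "gradient-boosted-trees", "multilayer-perceptron")


def encode_labels(binary_labels: Sequence[str]) -> np.ndarray:
    """Map positive/negative triplet labels to 1/0."""
    out = np.empty(len(binary_labels), dtype=int)
    for i, lab in enumerate(binary_labels):
        if lab == POSITIVE:
            out[i] = 1
        elif lab == NEGATIVE:
            out[i] = 0
        else:
            raise ValueError(f"unknown binary label {lab!r}")
    return out


@dataclass
class FoldAssignment:
    """Stratified fold indices, one per sample."""

    ids: list[str]
    fold_of: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        if len(self.ids) != len(self.fold_of):
            raise ValueError("ids and fold_of must align")

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_of == fold
        return ~test, test


def default_fold_count(n: int) -> int:
    """Fold count grows with topic size: clamp(floor(n/50), 3, 10)."""
    return int(np.clip(n // 50, 3, 10))


def make_folds(
    labels: Sequence[str] | np.ndarray,
    k: int | None = None,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> FoldAssignment:
    """Assign samples to stratified folds, seeded and deterministic.

    ``labels`` may be positive/negative strings or a 0/1 array.  Within
    each class, fold sizes differ by at most one.  Raises on single-class
    input or k < 2.
    """
    y = encode_labels(labels) if not isinstance(labels, np.ndarray) else np.asarray(labels)
    if y.dtype.kind not in "iub":
        y = encode_labels(list(labels))
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to build stratified folds")
    if k is None:
        k = default_fold_count(n)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    minority = int(np.bincount(y).min())
    if k > minority:
        raise ValueError(
            f"k={k} exceeds the minority class count ({minority}); reduce k"
        )
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
        fold_of[test_idx] = f
    return FoldAssignment(ids=ids, fold_of=fold_of, k=k)


def rfe_select(
    matrix: FeatureMatrix,
    labels: Sequence[str] | np.ndarray,
    n_target: int | None = None,
    step: int = 1,
    C: float = 1.0,
    seed: int = 0,
) -> list[FeatureSpec]:
    """Backward feature elimination capped at 30% of the sample count.

    A regularized logistic model is fitted, features are scored by
    absolute coefficient, the ``step`` lowest-scoring features are
    removed, and the model is refitted until ``n_target`` features remain
    (default: floor(0.3 * n_samples)).  The matrix is expected to be
    standardized so coefficient magnitudes are comparable.
    """
    y = labels if isinstance(labels, np.ndarray) else encode_labels(labels)
    if n_target is None:
        n_target = int(0.3 * matrix.n_rows)
    if n_target <= 0:
        raise ValueError(f"n_target must be positive, got {n_target}")
    if n_target > matrix.n_cols:
        raise ValueError(
            f"n_target={n_target} exceeds the number of columns ({matrix.n_cols})"
        )
    if n_target == matrix.n_cols:
        return list(matrix.specs)
    estimator = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    rfe = RFE(estimator=estimator, n_features_to_select=n_target, step=step)
    rfe.fit(matrix.values, y)
    return [s for s, keep in zip(matrix.specs, rfe.support_) if keep]


@dataclass(frozen=True)
class ModelConfig:
    """One candidate model: family, hyperparameters, seed."""

    family: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)

    def make_estimator(self):
        hp = self.hp
        if self.family == "regularized-linear":
            return LogisticRegression(
                C=float(hp.get("C", 1.0)), max_iter=2000, random_state=self.seed
            )
        if self.family == "gradient-boosted-trees":
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=int(hp.get("n_estimators", 100)),
                max_depth=int(hp.get("max_depth", 3)),
                learning_rate=float(hp.get("learning_rate", 0.3)),
                random_state=self.seed,
                n_jobs=1,
                verbosity=0,
                eval_metric="logloss",
            )
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (32,))),
            alpha=float(hp.get("alpha", 1e-4)),
            max_iter=int(hp.get("max_iter", 400)),
            random_state=self.seed,
        )


def default_grids() -> dict[str, list[dict]]:
    """Small per-family grids (kept tiny so full runs stay fast)."""
    return {
        "regularized-linear": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
        "gradient-boosted-trees": [
            {"n_estimators": 100, "max_depth": 3},
            {"n_estimators": 200, "max_depth": 2},
        ],
        "multilayer-perceptron": [{"hidden_layer_sizes": (32,)}],
    }


@dataclass
class OOFPredictions:
    """Out-of-fold positive-class probabilities, one per sample.

    Every sample is scored exactly once, by the per-fold model that was
    not trained on its fold.
    """

    ids: list[str]
    fold_of: np.ndarray
    p_positive: np.ndarray
    models: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        self.p_positive = np.asarray(self.p_positive, dtype=float)
        if not (len(self.ids) == len(self.fold_of) == len(self.p_positive)):
            raise ValueError("ids, fold_of and p_positive must align")
        if np.any((self.p_positive < 0) | (self.p_positive > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"triplet_id": self.ids, "fold": self.fold_of, "p_positive": self.p_positive}
        )
        if labels is not None:
            df["label"] = list(labels)
        return df


def _cv_oof(X: np.ndarray, y: np.ndarray, folds: FoldAssignment, config: ModelConfig):
    """Fit per fold; return (oof probabilities, per-fold F1 list, models)."""
    p = np.full(len(y), np.nan)
    f1s: list[float] = []
    models: dict[int, object] = {}
    for f in range(folds.k):
        train, test = folds.train_test(f)
        est = config.make_estimator()
        est.fit(X[train], y[train])
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        p[test] = est.predict_proba(X[test])[:, pos_col]
        f1s.append(f1_score(y[test], (p[test] >= 0.5).astype(int), pos_label=1, zero_division=0))
        models[f] = est
    assert not np.any(np.isnan(p))
    return p, f1s, models


def model_search(
    matrix: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    folds: FoldAssignment,
    grids: Mapping[str, list[dict]] | None = None,
    seed: int = 0,
) -> tuple[ModelConfig, OOFPredictions, pd.DataFrame]:
    """Exhaustive seeded grid search scored by positive-class F1.

    Every candidate is evaluated by cross-validation on the given folds;
    the score is the mean per-fold F1 of the positive class.  Exact score
    ties break toward the simpler family (linear < trees < perceptron),
    then toward the earlier grid point.  Returns the winning config, its
    out-of-fold probabilities (with the per-fold fitted models) and a
    leaderboard of all candidates.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    ids = matrix.row_ids if isinstance(matrix, FeatureMatrix) else list(folds.ids)
    y = labels if isinstance(labels, np.ndarray) else encode_labels(labels)
    grids = dict(grids) if grids is not None else default_grids()
    candidates = [
        ModelConfig(family=family, hyperparameters=tuple(sorted(hp.items())), seed=seed)
        for family in MODEL_FAMILIES
        if family in grids
        for hp in grids[family]
    ]
    if not candidates:
        raise ValueError("the search grid is empty")

    best: tuple[float, ModelConfig, OOFPredictions] | None = None
    rows = []
    for config in candidates:
        p, f1s, models = _cv_oof(X, y, folds, config)
        score = float(np.mean(f1s))
        rows.append(
            {"family": config.family, "hyperparameters": dict(config.hyperparameters),
             "mean_f1": score}
        )
        if best is None or score > best[0]:
            oof = OOFPredictions(ids=list(ids), fold_of=folds.fold_of, p_positive=p, models=models)
            best = (score, config, oof)
    leaderboard = pd.DataFrame(rows).sort_values("mean_f1", ascending=False, kind="stable")
    return best[1], best[2], leaderboard.reset_index(drop=True)


def evaluate_roc(
    scores: OOFPredictions | np.ndarray, labels: Sequence[str] | np.ndarray
) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC of out-of-fold scores against binary labels.

    AUC equals the probability that a random positive outranks a random
    negative, ties counting one half.
    """
    p = scores.p_positive if isinstance(scores, OOFPredictions) else np.asarray(scores, float)
    y = labels if isinstance(labels, np.ndarray) else encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(y, p)
    auc = float(roc_auc_score(y, p))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc
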