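"""Global and local model explanations, and feature-set reports.

Two complementary explanation routes:

* *coefficients* — for the regularized linear family trained on
  unit-variance features, coefficient magnitudes are directly comparable,
  so the top absolute weights (signs preserved: positive leans credible)
  are a global explanation;
* *local surrogate* — for any model exposing probabilities, a
  ridge-regularized weighted linear surrogate is fitted to the model's
  log-odds on perturbed neighbours of one instance (lexical columns are
  randomly masked to zero, stylometric columns resampled from the
  training marginal, neighbours weighted by a cosine-distance kernel).

Two report shapes summarize which feature families models rely on: the
per-topic percentage share of each family among the important features,
and the cross-topic recurrence counts of stylometric features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge

from .features import FeatureSpec, LEXICAL_FAMILIES

__all__ = [
    "Explanation",
    "coefficient_importance",
    "local_surrogate",
    "feature_family_share",
    "family_share_table",
    "cross_topic_overlap",
    "plot_feature_weights",
]

#: report families: every lexical column collapses onto 'lexical'
_REPORT_FAMILY = {
    "TFIDF": "lexical",
    "EMB": "lexical",
    "LEXICON": "lexicon",
    "NER": "ner",
    "POS": "pos",
    "DEP": "dep",
    "SENT": "sent",
}
REPORT_FAMILIES = ("lexicon", "ner", "pos", "dep", "sent", "lexical")


@dataclass
class Explanation:
    """Ranked signed feature weights for one model or one instance."""

    target_id: str
    method: str  # 'coefficients' | 'local-surrogate'
    items: list[tuple[FeatureSpec, float]]  # ranked by |ranking score|, descending
    contributions: np.ndarray | None = None  # local: weight * (x - train mean)

    def top_specs(self) -> list[FeatureSpec]:
        return [spec for spec, _ in self.items]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [s.family for s, _ in self.items],
                "name": [s.name for s, _ in self.items],
                "weight": [w for _, w in self.items],
            }
        )


def coefficient_importance(
    model, specs: Sequence[FeatureSpec], top_k: int = 16, model_id: str = "model"
) -> Explanation:
    """Top absolute coefficients of a linear model as a global explanation.

    Valid only for the linear family fitted on standardized features
    (otherwise magnitudes are incomparable).  Zero-weight features are
    dropped, so an all-zero model yields an empty ranking.
    """
    if not isinstance(model, LogisticRegression):
        raise TypeError(
            "coefficient_importance requires the regularized-linear family; "
            "use local_surrogate for black-box models"
        )
    coefs = np.asarray(model.coef_).ravel()
    if len(coefs) != len(specs):
        raise ValueError("coefficient count does not match feature specs")
    order = np.argsort(-np.abs(coefs), kind="stable")
    items = [
        (specs[i], float(coefs[i])) for i in order[:top_k] if coefs[i] != 0.0
    ]
    return Explanation(target_id=model_id, method="coefficients", items=items)


def _logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


def local_surrogate(
    model,
    instance: np.ndarray,
    X_train: np.ndarray,
    specs: Sequence[FeatureSpec],
    n_samples: int = 1000,
    top_k: int = 16,
    seed: int = 0,
    mask_prob: float = 0.5,
    ridge_alpha: float = 1.0,
    instance_id: str = "instance",
) -> Explanation:
    """Local surrogate explanation of one prediction.

    ``n_samples`` perturbed neighbours of the instance are generated:
    with probability ``mask_prob`` per column, lexical (TFIDF/EMB) values
    are masked to zero and stylometric values are resampled from the
    training marginal of that column.  Neighbours are weighted by
    exp(-d^2 / sigma^2) on cosine distance to the instance with
    sigma = 0.25 * sqrt(n_features), and a ridge surrogate is fitted to
    the model's log-odds.  The reported weight of a feature is its
    surrogate coefficient; its contribution is weight * (x_j - train mean
    of column j), and the ranking is by absolute contribution.
    Deterministic for a fixed seed.
    """
    if n_samples < 10:
        raise ValueError(f"n_samples must be >= 10, got {n_samples}")
    x = np.asarray(instance, dtype=float).ravel()
    X_train = np.asarray(X_train, dtype=float)
    d = len(x)
    if X_train.shape[1] != d or len(specs) != d:
        raise ValueError("instance, X_train and specs disagree on dimension")
    rng = np.random.default_rng(seed)
    is_lexical = np.array([s.family in LEXICAL_FAMILIES for s in specs])

    perturb = rng.random((n_samples, d)) < mask_prob
    Z = np.tile(x, (n_samples, 1))
    Z[perturb & is_lexical] = 0.0
    styl_cols = np.where(~is_lexical)[0]
    if len(styl_cols):
        donor_rows = rng.integers(0, X_train.shape[0], size=(n_samples, len(styl_cols)))
        resampled = X_train[donor_rows, styl_cols]
        mask_styl = perturb[:, styl_cols]
        Z[:, styl_cols] = np.where(mask_styl, resampled, Z[:, styl_cols])

    # cosine-distance proximity kernel
    x_norm = np.linalg.norm(x)
    z_norms = np.linalg.norm(Z, axis=1)
    denom = np.where(z_norms * x_norm > 0, z_norms * x_norm, 1.0)
    cos = np.where(z_norms * x_norm > 0, Z @ x / denom, 0.0)
    dist = 1.0 - cos
    sigma = 0.25 * np.sqrt(d)
    weights = np.exp(-(dist**2) / sigma**2)

    proba = np.asarray(model.predict_proba(Z))
    col = _pos_col(model)
    target = _logit(proba[:, -1 if col is None else col])
    surrogate = Ridge(alpha=ridge_alpha)
    surrogate.fit(Z, target, sample_weight=weights)
    coef = np.asarray(surrogate.coef_, dtype=float)

    train_mean = X_train.mean(axis=0)
    contributions = coef * (x - train_mean)
    order = np.argsort(-np.abs(contributions), kind="stable")[:top_k]
    items = [(specs[i], float(coef[i])) for i in order]
    return Explanation(
        target_id=instance_id,
        method="local-surrogate",
        items=items,
        contributions=contributions,
    )


def _pos_col(model) -> int | None:
    classes = getattr(model, "classes_", None)
    if classes is None:
        return None
    hits = np.where(np.asarray(classes) == 1)[0]
    return int(hits[0]) if len(hits) else None


def feature_family_share(important_specs: Sequence[FeatureSpec]) -> dict[str, float]:
    """Percentage of each report family among the important features.

    Lexical columns (TF-IDF or embedding dimensions) collapse onto one
    'lexical' family; the stylometric families are reported separately.
    Percentages sum to 100 within rounding.
    """
    if not important_specs:
        raise ValueError("important feature list is empty")
    counts = {fam: 0 for fam in REPORT_FAMILIES}
    for s in important_specs:
        counts[_REPORT_FAMILY[s.family]] += 1
    n = len(important_specs)
    return {fam: 100.0 * c / n for fam, c in counts.items()}


def family_share_table(per_topic_specs: Mapping[str, Sequence[FeatureSpec]]) -> pd.DataFrame:
    """One row per topic, one column per report family (percentages)."""
    return pd.DataFrame(
        {topic: feature_family_share(specs) for topic, specs in per_topic_specs.items()}
    ).T[list(REPORT_FAMILIES)]


def cross_topic_overlap(
    per_topic_specs: Mapping[str, Sequence[FeatureSpec]]
) -> pd.DataFrame:
    """How many topics share each recurring stylometric feature.

    Counts, over topics, the presence of each non-lexical feature in the
    topic's important-feature list; features appearing in only one topic
    are dropped.  Requires at least two topics.
    """
    if len(per_topic_specs) < 2:
        raise ValueError("cross-topic overlap needs at least 2 topics")
    counts: dict[FeatureSpec, int] = {}
    for specs in per_topic_specs.values():
        for spec in {s for s in specs if s.family not in LEXICAL_FAMILIES}:
            counts[spec] = counts.get(spec, 0) + 1
    rows = [
        {"family": s.family, "name": s.name, "n_topics": c}
        for s, c in counts.items()
        if c > 1
    ]
    df = pd.DataFrame(rows, columns=["family", "name", "n_topics"])
    return df.sort_values(
        ["n_topics", "family", "name"], ascending=[False, True, True]
    ).reset_index(drop=True)


def plot_feature_weights(explanation: Explanation, path: str) -> None:
    """Horizontal bar chart of the ranked signed weights."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{s.family}:{s.name}" for s, _ in explanation.items][::-1]
    weights = [w for _, w in explanation.items][::-1]
    fig, ax = plt.subplots(figsize=(7, max(2, 0.3 * len(labels))))
    colors = ["tab:blue" if w >= 0 else "tab:red" for w in weights]
    ax.barh(labels, weights, color=colors)
    ax.set_xlabel("signed weight (positive leans credible)")
    ax.set_title(f"{explanation.method}: {explanation.target_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
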