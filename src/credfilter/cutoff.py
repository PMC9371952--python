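"""Precision-constrained cutoff selection and expert-time utilization.

Triplets whose out-of-fold positive-class probability is at or above the
cutoff are treated as credible and removed from the expert annotation
queue; everything below the cutoff is kept for manual review.  The cutoff
is chosen per topic by three criteria: the negative proportion below the
cutoff should exceed the topic baseline as much as possible with minimum
fold-to-fold variance, the positive precision above the cutoff must stay
high (a hard floor, default 0.9), and more samples above the cutoff are
preferred.

*Baseline utilization* is the negative (non-credible) proportion of the
whole topic — the chance an expert annotating unfiltered data sees a
non-credible statement.  *Optimized utilization* is the same proportion
below the cutoff.  Both are reported on the 0-100 scale along with their
difference in percentage points and their ratio (the improvement factor).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .selection import OOFPredictions, encode_labels

__all__ = [
    "CutoffCandidate",
    "CutoffReport",
    "round_half_up",
    "candidate_statistics",
    "select_cutoff",
    "utilization_report",
    "partition_summary",
    "utilization_table",
]

#: probe thresholds always added to the candidate grid
EXTRA_GRID = (0.5, 0.9, 0.95, 0.97, 0.99)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (1.45 -> 1.5), as used in printed reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CutoffCandidate:
    """Statistics of one threshold t over the out-of-fold predictions."""

    t: float
    mean_below_neg: float  # mean over folds of the negative proportion below t
    sd_below_neg: float  # its standard deviation over folds
    above_pos_precision: float  # pooled positive proportion at/above t
    above_count: int
    below_count: int
    pooled_below_neg: float  # pooled negative proportion below t

    def __post_init__(self) -> None:
        for v in (self.mean_below_neg, self.above_pos_precision, self.pooled_below_neg):
            if not 0.0 <= v <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


def _as_arrays(
    oof: OOFPredictions | np.ndarray, labels: Sequence[str] | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    if isinstance(oof, OOFPredictions):
        p, fold_of = oof.p_positive, oof.fold_of
    else:
        p, fold_of = np.asarray(oof, dtype=float), None
    y = labels if isinstance(labels, np.ndarray) else encode_labels(labels)
    if len(p) != len(y):
        raise ValueError("probabilities and labels must align")
    return p, np.asarray(y), fold_of


def candidate_statistics(
    oof: OOFPredictions | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    grid: Sequence[float] | None = None,
) -> list[CutoffCandidate]:
    """Evaluate cutoff candidates over a threshold grid.

    The default grid is the sorted unique out-of-fold probabilities plus
    the probe thresholds {0.5, 0.9, 0.95, 0.97, 0.99}.  Candidates that
    leave either side empty (no samples below or none at/above the
    threshold) are excluded.  Fold-wise statistics use the folds with at
    least one sample below the threshold; without fold information the
    pooled value is used and the variance is reported as 0.
    """
    p, y, fold_of = _as_arrays(oof, labels)
    if grid is None:
        grid = np.unique(np.concatenate([np.unique(p), np.array(EXTRA_GRID)]))
    candidates: list[CutoffCandidate] = []
    for t in sorted(float(g) for g in set(grid)):
        below = p < t
        above = ~below
        n_below, n_above = int(below.sum()), int(above.sum())
        if n_below == 0 or n_above == 0:
            continue
        pooled_below_neg = float(np.mean(y[below] == 0))
        if fold_of is not None:
            fold_vals = [
                float(np.mean(y[below & (fold_of == f)] == 0))
                for f in np.unique(fold_of)
                if np.any(below & (fold_of == f))
            ]
            mean_bn = float(np.mean(fold_vals))
            sd_bn = float(np.std(fold_vals))
        else:
            mean_bn, sd_bn = pooled_below_neg, 0.0
        candidates.append(
            CutoffCandidate(
                t=t,
                mean_below_neg=mean_bn,
                sd_below_neg=sd_bn,
                above_pos_precision=float(np.mean(y[above] == 1)),
                above_count=n_above,
                below_count=n_below,
                pooled_below_neg=pooled_below_neg,
            )
        )
    return candidates


def select_cutoff(
    candidates: Sequence[CutoffCandidate],
    baseline_neg_rate: float,
    pos_precision_floor: float = 0.9,
    lam: float = 1.0,
) -> tuple[CutoffCandidate, bool]:
    """Pick the cutoff by floor-constrained, variance-penalized gain.

    Feasible candidates keep positive precision at/above the floor; among
    them the objective (mean_below_neg - baseline) - lam * sd_below_neg is
    maximized.  Ties break toward the larger above-count, then the smaller
    threshold.  If nothing is feasible the candidate with the highest
    positive precision is returned with the feasibility flag False.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    feasible = [c for c in candidates if c.above_pos_precision >= pos_precision_floor]
    if not feasible:
        fallback = max(candidates, key=lambda c: (c.above_pos_precision, c.above_count, -c.t))
        return fallback, False

    def key(c: CutoffCandidate) -> tuple[float, int, float]:
        objective = (c.mean_below_neg - baseline_neg_rate) - lam * c.sd_below_neg
        return (objective, c.above_count, -c.t)

    return max(feasible, key=key), True


@dataclass(frozen=True)
class CutoffReport:
    """Baseline vs. optimized expert-time utilization at a chosen cutoff."""

    chosen_t: float
    baseline_utilization: float  # % negative in the whole topic
    optimized_utilization: float  # % negative below the cutoff
    pp_improvement: float  # optimized - baseline, percentage points
    factor: float  # optimized / baseline, half-up to 1 decimal
    above_pos_precision: float
    fraction_above: float

    def to_row(self, topic: str | None = None) -> dict:
        row = {
            "cutoff": self.chosen_t,
            "baseline_utilization_pct": round_half_up(self.baseline_utilization, 1),
            "optimized_utilization_pct": round_half_up(self.optimized_utilization, 1),
            "pp_improvement": round_half_up(self.pp_improvement, 1),
            "factor": self.factor,
            "above_pos_precision": self.above_pos_precision,
            "fraction_above": self.fraction_above,
        }
        if topic is not None:
            row = {"topic": topic, **row}
        return row


def utilization_report(
    labels: Sequence[str] | np.ndarray,
    oof: OOFPredictions | np.ndarray,
    t: float,
) -> CutoffReport:
    """Report baseline vs. optimized utilization for cutoff ``t``.

    Percentages are on the 0-100 scale; the improvement factor is
    optimized/baseline rounded half-up to one decimal.  The conservation
    identity baseline = w * below_neg + (1 - w) * above_neg (w the below
    fraction) holds by construction.
    """
    p, y, _ = _as_arrays(oof, labels)
    below = p < t
    if not below.any():
        raise ValueError(f"cutoff t={t} leaves no samples below it")
    baseline = 100.0 * float(np.mean(y == 0))
    optimized = 100.0 * float(np.mean(y[below] == 0))
    above = ~below
    above_prec = float(np.mean(y[above] == 1)) if above.any() else float("nan")
    return CutoffReport(
        chosen_t=float(t),
        baseline_utilization=baseline,
        optimized_utilization=optimized,
        pp_improvement=optimized - baseline,
        factor=round_half_up(optimized / baseline, 1) if baseline > 0 else float("inf"),
        above_pos_precision=above_prec,
        fraction_above=float(np.mean(above)),
    )


def partition_summary(
    labels: Sequence[str] | np.ndarray, oof: OOFPredictions | np.ndarray, t: float
) -> pd.DataFrame:
    """Class proportions below / above the cutoff and in the whole set.

    Mirrors the three-bar partition view: the below column is the negative
    precision, the above column the positive precision, the total column
    the raw label proportions.
    """
    p, y, _ = _as_arrays(oof, labels)
    below = p < t
    rows = {}
    for name, mask in (("below", below), ("above", ~below), ("total", np.ones_like(below, bool))):
        n = int(mask.sum())
        rows[name] = {
            "n": n,
            "negative_pct": 100.0 * float(np.mean(y[mask] == 0)) if n else float("nan"),
            "positive_pct": 100.0 * float(np.mean(y[mask] == 1)) if n else float("nan"),
        }
    return pd.DataFrame(rows).T


def utilization_table(reports: dict[str, CutoffReport]) -> pd.DataFrame:
    """Delimited-table view of per-topic cutoff reports."""
    return pd.DataFrame([rep.to_row(topic) for topic, rep in reports.items()])
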