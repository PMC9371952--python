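"""Reported reference values from the annotation study this package models.

These printed values are inputs, not outputs: the per-topic utilization
table and the worked filtering example are used to verify the package's
report arithmetic (column means, percentage-point differences, improvement
factors), and the corpus-scale constants feed the throughput defaults.
The underlying expert-annotated corpus itself is not redistributable here,
so none of these numbers are recomputed from raw data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cutoff import round_half_up

__all__ = [
    "reported_utilization_table",
    "reported_column_means",
    "WORKED_EXAMPLE",
    "STUDY_SCALE",
    "reconstruct_worked_example",
]

#: per-topic baseline utilization and improvements, for runs using TF-IDF
#: and embedding-vector lexical features respectively (topics anonymized
#: A-J as reported)
_UTILIZATION_ROWS = [
    # topic, baseline %, pp improvement (tfidf), factor (tfidf), pp (emb), factor (emb)
    ("A", 44.7, 20.2, 1.5, 27.6, 1.6),
    ("B", 18.7, 17.2, 1.9, 30.7, 2.6),
    ("C", 20.2, 33.9, 2.7, 21.9, 2.1),
    ("D", 41.3, 22.2, 1.5, 28.1, 1.7),
    ("E", 18.4, 40.8, 3.2, 17.0, 1.9),
    ("F", 19.5, 47.4, 3.4, 35.7, 2.8),
    ("G", 46.7, 22.4, 1.5, 12.2, 1.3),
    ("H", 12.4, 22.4, 2.8, 26.8, 3.2),
    ("I", 16.4, 21.2, 2.3, 25.0, 2.5),
    ("J", 37.7, 11.4, 1.3, 12.9, 1.3),
]

#: the worked heart-supplements filtering example: overall negative share,
#: negative share below / above the chosen cutoff of 0.97
WORKED_EXAMPLE = {
    "cutoff": 0.97,
    "overall_neg_pct": 44.7,
    "below_neg_pct": 64.9,
    "above_neg_pct": 13.6,
}

#: corpus scale and observed evaluation-time range (seconds)
STUDY_SCALE = {
    "n_statements": 10000,
    "n_articles": 247,
    "mean_eval_seconds_fastest_topic": 18.0,
    "mean_eval_seconds_slowest_topic": 35.0,
}


def reported_utilization_table() -> pd.DataFrame:
    """The reported per-topic utilization table (one row per topic)."""
    return pd.DataFrame(
        _UTILIZATION_ROWS,
        columns=["topic", "baseline_pct", "pp_tfidf", "factor_tfidf", "pp_emb", "factor_emb"],
    ).set_index("topic")


def reported_column_means() -> dict[str, float]:
    """Column means of the utilization table, half-up to one decimal."""
    df = reported_utilization_table()
    return {
        col: round_half_up(float(df[col].mean()), 1)
        for col in ("pp_tfidf", "factor_tfidf", "pp_emb", "factor_emb")
    }


def reconstruct_worked_example(
    n_below: int = 1000, n_above: int = 1000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Construct (labels, probabilities, cutoff) matching the worked example.

    Builds a synthetic prediction set whose overall negative share is
    exactly 44.7% and whose below-cutoff negative share is exactly 64.9%,
    so the utilization arithmetic (20.2 pp improvement, factor 1.5) can be
    recomputed rather than asserted.  Labels are 1=positive, 0=negative.
    """
    t = 0.5
    neg_below = int(round(WORKED_EXAMPLE["below_neg_pct"] / 100 * n_below))
    total_neg = WORKED_EXAMPLE["overall_neg_pct"] / 100 * (n_below + n_above)
    if abs(total_neg - round(total_neg)) > 1e-9:
        raise ValueError("n_below + n_above must make the overall share exact")
    neg_above = int(round(total_neg)) - neg_below
    if not 0 <= neg_above <= n_above:
        raise ValueError("infeasible (n_below, n_above) for the worked example")
    y = np.concatenate(
        [
            np.zeros(neg_below), np.ones(n_below - neg_below),  # below cutoff
            np.zeros(neg_above), np.ones(n_above - neg_above),  # above cutoff
        ]
    ).astype(int)
    p = np.concatenate([np.full(n_below, 0.25), np.full(n_above, 0.75)])
    return y, p, t
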