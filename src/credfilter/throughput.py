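"""Expert-time economics: evaluation-time summaries and daily throughput.

An expert annotating sentence credibility works a bounded day with
periodic breaks; dividing the effective working seconds by the mean
per-statement evaluation time gives the statements evaluated per day, and
dividing by the statements per article gives articles per day.  Observed
per-topic mean evaluation times around 18-35 s and an 8-hour day with
15-minute hourly breaks put an expert in the range of roughly 617-1200
statements (15-30 articles of ~40 statements) per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .corpus import Corpus

__all__ = [
    "WorkdayModel",
    "effective_seconds",
    "statements_per_day",
    "articles_per_day",
    "time_summary",
]


@dataclass(frozen=True)
class WorkdayModel:
    """Workday assumptions: hours, hourly break minutes, statements/article."""

    hours_per_day: float = 8.0
    break_minutes_per_hour: float = 15.0
    statements_per_article: float = 40.0

    def __post_init__(self) -> None:
        if self.hours_per_day <= 0:
            raise ValueError("hours_per_day must be positive")
        if not 0 <= self.break_minutes_per_hour < 60:
            raise ValueError("break_minutes_per_hour must be in [0, 60)")
        if self.statements_per_article <= 0:
            raise ValueError("statements_per_article must be positive")


def effective_seconds(model: WorkdayModel = WorkdayModel()) -> float:
    """Effective working seconds per day after hourly breaks.

    With the defaults (8 h, 15 min break per hour) this is 21600 s — six
    effective hours.
    """
    return model.hours_per_day * (60.0 - model.break_minutes_per_hour) * 60.0


def statements_per_day(
    mean_seconds_per_statement: float, model: WorkdayModel = WorkdayModel()
) -> int:
    """Statements an expert evaluates per day (floor division).

    Flooring matters: 21600 s / 35 s = 617.14... -> 617.
    """
    if mean_seconds_per_statement <= 0:
        raise ValueError("mean_seconds_per_statement must be positive")
    return int(math.floor(effective_seconds(model) / mean_seconds_per_statement))


def articles_per_day(
    statements_per_day_count: int, statements_per_article: float = 40.0
) -> int:
    """Articles an expert evaluates per day (floor division)."""
    if statements_per_article <= 0:
        raise ValueError("statements_per_article must be positive")
    return int(math.floor(statements_per_day_count / statements_per_article))


def time_summary(corpus: Corpus, quantiles: tuple[float, ...] = (0.25, 0.75, 0.9)) -> pd.DataFrame:
    """Per-topic summary of recorded annotation times (seconds).

    Sentences without a recorded time are ignored; the ``n`` column
    reports how many sentences were used per topic.  An 'all' row pools
    every topic.  Raises if no sentence carries a time at all.
    """
    rows = [
        {"topic": s.topic, "t": s.annotation_time_seconds}
        for s in corpus.sentences()
        if s.annotation_time_seconds is not None
    ]
    if not rows:
        raise ValueError("no annotation times present in the corpus")
    df = pd.DataFrame(rows)

    def summarize(g: pd.Series) -> dict:
        out = {
            "n": int(g.size),
            "mean_s": float(g.mean()),
            "median_s": float(g.median()),
        }
        for q in quantiles:
            out[f"q{int(q * 100)}_s"] = float(g.quantile(q))
        return out

    per_topic = {topic: summarize(g["t"]) for topic, g in df.groupby("topic")}
    per_topic["all"] = summarize(df["t"])
    out = pd.DataFrame(per_topic).T
    out["n"] = out["n"].astype(int)
    out.index.name = "topic"
    return out
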