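"""Sentence-level annotated corpora and context triplets.

A corpus is a set of online articles, each split into sentences that a
medical expert has labelled CRED (credible), NEU (neutral: no medical
factual content) or NONCRED (non-credible).  Because credibility often
depends on surrounding context, the classification unit downstream is not
the sentence but the *triplet*: three consecutive, non-overlapping
sentences of one article.  A triplet is *negative* if any member is
NONCRED and *positive* if all members are CRED or NEU.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "LABELS",
    "POSITIVE",
    "NEGATIVE",
    "LabeledSentence",
    "Article",
    "Triplet",
    "Corpus",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "write_triplets",
    "segment_sentences",
    "build_triplets",
    "propagate_label",
    "corpus_summary",
]

LABELS = ("CRED", "NEU", "NONCRED")
POSITIVE = "positive"
NEGATIVE = "negative"

#: context-depth codes: 0 -> no surrounding sentences needed, 1 -> one
#: sentence needed, 2 -> more than one needed.
CONTEXT_DEPTHS = (0, 1, 2)


class CorpusValidationError(ValueError):
    """Raised when an input corpus violates the schema contract."""


@dataclass(frozen=True)
class LabeledSentence:
    """One expert-annotated sentence with its article/topic metadata."""

    article_id: str
    topic: str
    position: int
    text: str
    label: str | None
    annotation_time_seconds: float | None = None
    context_depth: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise CorpusValidationError(
                f"unknown label {self.label!r} for sentence "
                f"({self.article_id!r}, {self.position}); expected one of {LABELS}"
            )
        if self.position < 0:
            raise CorpusValidationError("position must be a non-negative integer")
        if self.annotation_time_seconds is not None and not self.annotation_time_seconds > 0:
            raise CorpusValidationError("annotation_time_seconds must be > 0 when present")
        if self.context_depth is not None and self.context_depth not in CONTEXT_DEPTHS:
            raise CorpusValidationError(
                f"context_depth must be one of {CONTEXT_DEPTHS}, got {self.context_depth}"
            )


@dataclass
class Article:
    """Ordered sentences of one article; positions strictly increasing."""

    article_id: str
    topic: str
    sentences: list[LabeledSentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sentences:
            if s.article_id != self.article_id or s.topic != self.topic:
                raise CorpusValidationError(
                    f"sentence ({s.article_id!r}, {s.position}) does not belong to "
                    f"article {self.article_id!r} / topic {self.topic!r}"
                )
        positions = [s.position for s in self.sentences]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise CorpusValidationError(
                f"positions of article {self.article_id!r} are not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class Triplet:
    """Three consecutive same-article sentences with a propagated binary label."""

    triplet_id: str
    article_id: str
    topic: str
    members: tuple[LabeledSentence, LabeledSentence, LabeledSentence]
    binary_label: str

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise CorpusValidationError("a triplet has exactly 3 members")
        if self.binary_label not in (POSITIVE, NEGATIVE):
            raise CorpusValidationError(f"bad binary label {self.binary_label!r}")

    @property
    def text(self) -> str:
        """Member texts joined into one paragraph-like unit."""
        return " ".join(m.text for m in self.members)

    @property
    def positions(self) -> tuple[int, int, int]:
        return tuple(m.position for m in self.members)  # type: ignore[return-value]


@dataclass
class Corpus:
    """Articles grouped by topic; every article lives under exactly one topic."""

    topics: dict[str, list[Article]] = field(default_factory=dict)

    def articles(self) -> Iterator[Article]:
        for arts in self.topics.values():
            yield from arts

    def sentences(self) -> Iterator[LabeledSentence]:
        for art in self.articles():
            yield from art.sentences

    @property
    def n_sentences(self) -> int:
        return sum(len(a) for a in self.articles())

    @property
    def n_articles(self) -> int:
        return sum(len(v) for v in self.topics.values())


_REQUIRED_COLUMNS = ("article_id", "topic", "position", "text", "label")
_OPTIONAL_COLUMNS = ("annotation_time_seconds", "context_depth")


def _detect_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        if format not in ("delimited", "json-lines"):
            raise ValueError(f"format must be 'delimited' or 'json-lines', got {format!r}")
        return format
    suffix = Path(path).suffix.lower()
    return "json-lines" if suffix in (".jsonl", ".ndjson", ".json") else "delimited"


def _read_table(path: Path, format: str) -> pd.DataFrame:
    if format == "json-lines":
        return pd.read_json(
            path, lines=True, precise_float=True,
            dtype={"article_id": str, "topic": str},
        )
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(
        path, sep=sep, float_precision="round_trip",
        dtype={"article_id": str, "topic": str, "label": str, "text": str},
    )


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read an annotated sentence corpus from a delimited or JSON-lines file.

    The file must provide columns ``article_id, topic, position, text,
    label`` and may provide ``annotation_time_seconds`` and
    ``context_depth``.  Sentences are grouped by topic and article and
    sorted by position.

    Raises
    ------
    CorpusValidationError
        On an unknown label value or a duplicate ``(article_id, position)``,
        naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path, _detect_format(path, format))

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusValidationError(f"missing required columns: {missing}")

    bad = df.loc[~df["label"].isin(LABELS)]
    if len(bad):
        row = bad.iloc[0]
        raise CorpusValidationError(
            f"unknown label {row['label']!r} at row {bad.index[0]} "
            f"(article {row['article_id']!r}, position {row['position']})"
        )
    dupes = df.duplicated(subset=["article_id", "position"], keep=False)
    if dupes.any():
        row = df.loc[dupes].iloc[0]
        raise CorpusValidationError(
            f"duplicate (article_id, position) = ({row['article_id']!r}, {row['position']})"
        )

    def _opt_float(v) -> float | None:
        return None if pd.isna(v) else float(v)

    def _opt_int(v) -> int | None:
        return None if pd.isna(v) else int(v)

    corpus = Corpus()
    for (topic, article_id), grp in sorted(
        df.groupby(["topic", "article_id"], sort=False), key=lambda kv: kv[0]
    ):
        grp = grp.sort_values("position")
        sentences = [
            LabeledSentence(
                article_id=str(r.article_id),
                topic=str(r.topic),
                position=int(r.position),
                text=str(r.text),
                label=str(r.label),
                annotation_time_seconds=_opt_float(getattr(r, "annotation_time_seconds", None)),
                context_depth=_opt_int(getattr(r, "context_depth", None)),
            )
            for r in grp.itertuples()
        ]
        corpus.topics.setdefault(str(topic), []).append(
            Article(article_id=str(article_id), topic=str(topic), sentences=sentences)
        )
    return corpus


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    rows = [
        {
            "article_id": s.article_id,
            "topic": s.topic,
            "position": s.position,
            "text": s.text,
            "label": s.label,
            "annotation_time_seconds": s.annotation_time_seconds,
            "context_depth": s.context_depth,
        }
        for s in corpus.sentences()
    ]
    df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))
    df["context_depth"] = df["context_depth"].astype("Int64")
    return df


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus back to disk in the same schema ``read_corpus`` reads."""
    path = Path(path)
    fmt = _detect_format(path, format)
    df = corpus_to_frame(corpus)
    if fmt == "json-lines":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                clean = {k: v for k, v in rec.items() if v is not None and not pd.isna(v)}
                fh.write(json.dumps(clean, ensure_ascii=False) + "\n")
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df.to_csv(path, sep=sep, index=False)


def write_triplets(triplets: Sequence[Triplet], path: str | Path) -> None:
    """Export triplets as a delimited table (one row per triplet)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        {
            "triplet_id": [t.triplet_id for t in triplets],
            "article_id": [t.article_id for t in triplets],
            "topic": [t.topic for t in triplets],
            "positions": ["|".join(map(str, t.positions)) for t in triplets],
            "binary_label": [t.binary_label for t in triplets],
        }
    ).to_csv(path, sep=sep, index=False)


#: words after which a terminal period does not end a sentence
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr.", "mr.", "mrs.", "ms.", "prof.", "st.", "jr.", "sr.",
        "vs.", "etc.", "e.g.", "i.e.", "cf.", "al.", "fig.", "no.",
        "approx.", "dept.", "inc.", "ltd.", "vol.", "pp.",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def segment_sentences(
    raw_text: str, abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS
) -> list[str]:
    """Split raw text into sentences on terminal punctuation.

    The default segmenter is rule-based: it breaks after runs of ``.!?``
    followed by whitespace, except when the token ending at the period is
    on the abbreviation exception list.  The concatenation of the returned
    sentences covers the input text (modulo surrounding whitespace).  A
    smarter segmenter (e.g. a dependency-parser pipeline) can be used
    instead by splitting upstream and feeding sentences directly into
    :func:`read_corpus` inputs.
    """
    if not raw_text or not raw_text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(raw_text):
        prefix = raw_text[: m.end()]
        last_word = prefix.rsplit(None, 1)[-1].lower() if prefix.split() else ""
        if last_word in abbreviations:
            continue
        chunk = raw_text[start : m.end()].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = raw_text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def propagate_label(labels: Sequence[str]) -> str:
    """Propagate three sentence labels to one binary triplet label.

    The triplet is *negative* if any of the three sentences is NONCRED,
    and *positive* if all three are CRED or NEU.
    """
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 labels, got {len(labels)}")
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
    return NEGATIVE if "NONCRED" in labels else POSITIVE


def build_triplets(article: Article, remainder: str = "drop") -> list[Triplet]:
    """Build consecutive non-overlapping triplets from one article.

    Sentences are taken in position order and chunked into blocks of
    three: sentence indices (0,1,2), (3,4,5), ...  Triplets never cross
    article boundaries.  The trailing 1-2 sentences of an article are
    dropped by default; ``remainder='pad'`` repeats the last sentence to
    complete the final block instead.
    """
    if remainder not in ("drop", "pad"):
        raise ValueError(f"remainder must be 'drop' or 'pad', got {remainder!r}")
    sentences = sorted(article.sentences, key=lambda s: s.position)
    for s in sentences:
        if s.label is None:
            raise CorpusValidationError(
                f"sentence ({s.article_id!r}, {s.position}) is unlabeled"
            )
    if remainder == "pad" and sentences and len(sentences) % 3:
        # a 1- or 2-sentence article still yields one (padded) triplet
        sentences = sentences + [sentences[-1]] * (3 - len(sentences) % 3)
    triplets: list[Triplet] = []
    for k in range(len(sentences) // 3):
        members = tuple(sentences[3 * k : 3 * k + 3])
        triplets.append(
            Triplet(
                triplet_id=f"{article.article_id}:{k}",
                article_id=article.article_id,
                topic=article.topic,
                members=members,  # type: ignore[arg-type]
                binary_label=propagate_label([m.label for m in members]),
            )
        )
    return triplets


@dataclass
class CorpusSummary:
    """Per-topic class counts and per-class context-depth percentages."""

    class_counts: pd.DataFrame  # index: topic; columns: CRED, NEU, NONCRED
    context_depth_pct: pd.DataFrame  # index: label; columns: '0', '1', '>1'

    @property
    def n_sentences(self) -> int:
        return int(self.class_counts.to_numpy().sum()) if len(self.class_counts) else 0


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Summarize class composition and context need.

    ``class_counts`` counts sentences of each label per topic.
    ``context_depth_pct`` gives, per label, the percentage of sentences
    needing 0 / 1 / >1 surrounding sentences of context, among the
    sentences where context depth was recorded; rows sum to 100.
    """
    df = corpus_to_frame(corpus)
    if df.empty:
        return CorpusSummary(
            class_counts=pd.DataFrame(columns=list(LABELS)),
            context_depth_pct=pd.DataFrame(columns=["0", "1", ">1"]),
        )
    counts = (
        df.pivot_table(index="topic", columns="label", values="text", aggfunc="count", fill_value=0)
        .reindex(columns=list(LABELS), fill_value=0)
        .astype(int)
    )
    counts.columns.name = None

    with_depth = df.dropna(subset=["context_depth"])
    if with_depth.empty:
        depth_pct = pd.DataFrame(columns=["0", "1", ">1"])
    else:
        tab = pd.crosstab(with_depth["label"], with_depth["context_depth"].astype(int))
        tab = tab.reindex(columns=CONTEXT_DEPTHS, fill_value=0)
        depth_pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
        depth_pct.columns = ["0", "1", ">1"]
        depth_pct.index.name = None
        depth_pct.columns.name = None
    return CorpusSummary(class_counts=counts, context_depth_pct=depth_pct)
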