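"""Family-tagged feature extraction for sentence triplets.

Each triplet is turned into one numeric row built from up to six feature
families:

* a *lexical* family — either TF-IDF over lowercased lemma tokens or an
  ingested embedding-vector block (one per run, never both);
* *stylometric* families — dependency-relation counts (DEP), part-of-speech
  counts (POS), named-entity counts (NER), polarity/subjectivity (SENT) and
  category-lexicon rates (LEXICON).

Taggers and parsers are pluggable callables; the defaults shipped here are
deterministic rule-based taggers, a gazetteer+regex entity tagger, and small
bundled polarity/subjectivity/category lexicons, so the whole pipeline runs
offline with no model downloads.  Vocabulary, idf weights and
standardization statistics are always fitted on a declared training
partition only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Triplet

__all__ = [
    "FAMILIES",
    "FeatureSpec",
    "Standardization",
    "FeatureMatrix",
    "FeatureConfigError",
    "FeatureConfig",
    "CategoryLexicon",
    "tokenize_normalize",
    "simple_lemmatizer",
    "fit_tfidf",
    "TfidfFeaturizer",
    "heuristic_pos_tagger",
    "heuristic_dependency_parser",
    "dependency_label_counts",
    "pos_counts",
    "named_entity_counts",
    "sentiment_scores",
    "lexicon_category_counts",
    "load_embeddings",
    "assemble_features",
    "standardize_features",
    "TripletFeaturizer",
    "default_lexicon",
    "default_gazetteer",
]

FAMILIES = ("TFIDF", "EMB", "DEP", "POS", "NER", "SENT", "LEXICON")
LEXICAL_FAMILIES = ("TFIDF", "EMB")
NER_CATEGORIES = ("PERSON", "ORGANIZATION", "PRODUCT", "NUMBER")


class FeatureConfigError(ValueError):
    """Raised on an inconsistent feature configuration."""


@dataclass(frozen=True)
class FeatureSpec:
    """One named column of a feature matrix, tagged with its family."""

    family: str
    name: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FeatureConfigError(f"unknown feature family {self.family!r}")

    @property
    def column(self) -> str:
        return f"{self.family}:{self.name}"


@dataclass
class Standardization:
    """Per-column (mean, sd) fitted on a declared partition of rows."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: list[str]


@dataclass
class FeatureMatrix:
    """Triplet-by-feature real matrix with family-tagged columns."""

    row_ids: list[str]
    specs: list[FeatureSpec]
    values: np.ndarray
    standardization: Standardization | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.specs)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.specs)} specs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        seen = set()
        for s in self.specs:
            key = (s.family, s.name)
            if key in seen:
                raise ValueError(f"duplicate feature spec {key}")
            seen.add(key)

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.specs)

    def family_indices(self, family: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specs) if s.family == family], dtype=int)

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        index = {rid: i for i, rid in enumerate(self.row_ids)}
        return self.values[[index[i] for i in ids]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=[s.column for s in self.specs])

    def save(self, values_path: str | Path, header_path: str | Path) -> None:
        """Export as a delimited value table plus a JSON header of specs."""
        self.to_dataframe().to_csv(values_path, index_label="triplet_id")
        header = {
            "specs": [{"family": s.family, "name": s.name, "column_index": i}
                      for i, s in enumerate(self.specs)],
            "standardized": self.standardization is not None,
        }
        Path(header_path).write_text(json.dumps(header, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# tokenization

_WORD_RE = re.compile(r"[a-z0-9][a-z0-9']*")
_TAG_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z']*|\d[\d.,]*|[.!?,;:]")


def simple_lemmatizer(token: str) -> str:
    """Tiny rule-based English lemmatizer (plural stripping).

    Good enough to map e.g. 'statins' -> 'statin'; a full lemmatizer can be
    plugged in wherever a ``lemmatizer`` argument is accepted.
    """
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if (
        token.endswith("s")
        and len(token) > 3
        and not token.endswith(("ss", "us", "is", "'s"))
    ):
        return token[:-1]
    return token


def tokenize_normalize(
    text: str, lemmatizer: Callable[[str], str] | None = None
) -> list[str]:
    """Lowercase word tokens, optionally lemmatized.

    Lowercasing is always applied; the lemmatizer defaults to identity so
    the package carries no model dependency.
    """
    tokens = _WORD_RE.findall(text.lower())
    if lemmatizer is not None:
        tokens = [lemmatizer(t) for t in tokens]
    return tokens


# ---------------------------------------------------------------------------
# TF-IDF (scikit-learn behind the surface)


def _passthrough(tokens):
    return tokens


class TfidfFeaturizer:
    """Smoothed-idf, L2-row-normalized TF-IDF over pre-tokenized documents.

    idf(t) = ln((1+N)/(1+df(t))) + 1; rows are L2-normalized; tokens unseen
    in the training partition are ignored at transform time.
    """

    def __init__(self, min_df: int = 2):
        self.min_df = min_df
        self._vec: TfidfVectorizer | None = None

    def fit(self, token_lists: Sequence[list[str]]) -> "TfidfFeaturizer":
        if len(token_lists) == 0:
            raise ValueError("cannot fit TF-IDF on an empty training set")
        self._vec = TfidfVectorizer(
            analyzer=_passthrough,
            min_df=self.min_df,
            norm="l2",
            smooth_idf=True,
            sublinear_tf=False,
        )
        try:
            self._vec.fit(token_lists)
        except ValueError as e:  # empty vocabulary at this min_df
            raise ValueError(f"TF-IDF fit produced an empty vocabulary: {e}") from e
        return self

    @property
    def vocabulary(self) -> list[str]:
        self._check_fitted()
        return list(self._vec.get_feature_names_out())

    def idf(self, term: str) -> float:
        self._check_fitted()
        idx = self._vec.vocabulary_.get(term)
        if idx is None:
            raise KeyError(term)
        return float(self._vec.idf_[idx])

    def transform(self, token_lists: Sequence[list[str]]) -> np.ndarray:
        self._check_fitted()
        return self._vec.transform(token_lists).toarray()

    def specs(self) -> list[FeatureSpec]:
        return [FeatureSpec("TFIDF", t) for t in self.vocabulary]

    def _check_fitted(self) -> None:
        if self._vec is None:
            raise RuntimeError("TfidfFeaturizer is not fitted")


def fit_tfidf(train_token_lists: Sequence[list[str]], min_df: int = 2) -> TfidfFeaturizer:
    """Fit the TF-IDF vocabulary and idf weights on the training partition."""
    return TfidfFeaturizer(min_df=min_df).fit(train_token_lists)


# ---------------------------------------------------------------------------
# rule-based taggers (deterministic offline fallbacks)

_DET = {"the", "a", "an", "this", "that", "these", "those", "every", "each",
        "some", "any", "no", "all"}
_PRON = {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her",
         "us", "them", "my", "your", "his", "its", "our", "their", "mine"}
_ADP = {"of", "in", "on", "at", "by", "with", "from", "for", "about", "into",
        "over", "under", "between", "against", "during", "without"}
_CCONJ = {"and", "or", "but", "nor"}
_SCONJ = {"because", "although", "while", "if", "when", "whether", "since",
          "unless", "however"}
_AUX = {"is", "are", "was", "were", "be", "been", "am", "do", "does", "did",
        "have", "has", "had", "will", "would", "can", "could", "should",
        "may", "might", "must"}


def heuristic_pos_tagger(text: str) -> list[str]:
    """Deterministic rule-based part-of-speech tagger.

    Closed-class words are looked up; open-class words are tagged by
    suffix; digits -> NUM, sentence punctuation -> PUNCT.  One tag per
    token (a partition of the token stream).
    """
    tags = []
    for tok in _TAG_TOKEN_RE.findall(text):
        low = tok.lower()
        if tok[0].isdigit():
            tags.append("NUM")
        elif tok == "!":
            # exclamations are a stylometric cue of their own
            tags.append("EXCL")
        elif tok in ".?,;:":
            tags.append("PUNCT")
        elif low in _DET:
            tags.append("DET")
        elif low in _PRON:
            tags.append("PRON")
        elif low in _ADP:
            tags.append("ADP")
        elif low in _CCONJ:
            tags.append("CCONJ")
        elif low in _SCONJ:
            tags.append("SCONJ")
        elif low in _AUX:
            tags.append("AUX")
        elif low.endswith("ly"):
            tags.append("ADV")
        elif low.endswith(("ing", "ed", "ize", "ise")):
            tags.append("VERB")
        elif low.endswith(("ous", "ful", "ive", "able", "ical", "ic", "al")):
            tags.append("ADJ")
        else:
            tags.append("NOUN")
    return tags


_POS_TO_DEP = {
    "DET": "det", "NUM": "nummod", "ADV": "advmod", "ADJ": "amod",
    "ADP": "case", "CCONJ": "cc", "SCONJ": "mark", "AUX": "aux",
    "PUNCT": "punct", "EXCL": "punct",
}


def heuristic_dependency_parser(text: str) -> list[str]:
    """Deterministic dependency-relation tagger (one relation per token).

    Relations are derived from the rule-based POS tags: the first verb is
    the root, nominals before it are subjects, nominals after it objects.
    This emulates the granularity (not the accuracy) of counting the base
    elements of a dependency tree.
    """
    pos = heuristic_pos_tagger(text)
    rels: list[str] = []
    seen_verb = False
    for tag in pos:
        if tag == "VERB":
            rels.append("conj" if seen_verb else "root")
            seen_verb = True
        elif tag in ("NOUN", "PRON"):
            rels.append("obj" if seen_verb else "nsubj")
        else:
            rels.append(_POS_TO_DEP[tag])
    return rels


def _counts(tags: Iterable[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for t in tags:
        out[t] = out.get(t, 0) + 1
    return out


def dependency_label_counts(
    text: str, parser: Callable[[str], list[str]] | None = None
) -> dict[str, int]:
    """Count dependency-relation tags in a text (pluggable parser)."""
    parser = parser if parser is not None else heuristic_dependency_parser
    return _counts(parser(text))


def pos_counts(text: str, tagger: Callable[[str], list[str]] | None = None) -> dict[str, int]:
    """Count part-of-speech tags in a text (pluggable tagger)."""
    tagger = tagger if tagger is not None else heuristic_pos_tagger
    return _counts(tagger(text))


# ---------------------------------------------------------------------------
# named entities (gazetteer + regex fallback)

_CAP_SPAN_RE = re.compile(r"(?:[A-Z][\w.&-]*)(?:\s[A-Z][\w.&-]*)*")
_NUMBER_RE = re.compile(r"(?<![\w.])\d[\d.,]*")


def _load_tsv_pairs(name: str) -> list[tuple[str, str]]:
    text = resources.files("credfilter").joinpath(f"data/{name}").read_text(encoding="utf-8")
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("\t")
        pairs.append((key, val))
    return pairs


@lru_cache(maxsize=1)
def default_gazetteer() -> dict[str, str]:
    """Bundled entity gazetteer: surface form -> category."""
    return dict(_load_tsv_pairs("gazetteer.tsv"))


def named_entity_counts(
    text: str, gazetteer: Mapping[str, str] | None = None
) -> dict[str, int]:
    """Count named entities per category with a gazetteer+regex tagger.

    Capitalized (possibly multiword) spans are looked up in the gazetteer,
    longest match first; digit patterns count as NUMBER.  Categories with
    no hits report zero.
    """
    gaz = default_gazetteer() if gazetteer is None else dict(gazetteer)
    categories = sorted(set(gaz.values()) | set(NER_CATEGORIES))
    out = {c: 0 for c in categories}
    for m in _CAP_SPAN_RE.finditer(text):
        words = m.group(0).split()
        i = 0
        while i < len(words):
            matched = False
            for j in range(len(words), i, -1):
                span = " ".join(words[i:j])
                if span in gaz:
                    out[gaz[span]] += 1
                    i = j
                    matched = True
                    break
            if not matched:
                i += 1
    out["NUMBER"] += len(_NUMBER_RE.findall(text))
    return out


# ---------------------------------------------------------------------------
# sentiment (polarity + subjectivity)


@lru_cache(maxsize=1)
def default_polarity_lexicon() -> dict[str, float]:
    return {w: float(s) for w, s in _load_tsv_pairs("polarity.txt")}


@lru_cache(maxsize=1)
def default_subjectivity_lexicon() -> frozenset[str]:
    text = resources.files("credfilter").joinpath("data/subjectivity.txt").read_text("utf-8")
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def sentiment_scores(
    text: str,
    polarity_lexicon: Mapping[str, float] | None = None,
    subjectivity_lexicon: frozenset[str] | set[str] | None = None,
) -> tuple[float, float]:
    """Lexicon-based (polarity, subjectivity) of a text.

    Polarity is the mean signed score of matched polarity-lexicon words
    (0 if none match), bounded in [-1, 1].  Subjectivity is the fraction
    of tokens matched by the subjectivity lexicon, in [0, 1].
    """
    pol_lex = polarity_lexicon if polarity_lexicon is not None else default_polarity_lexicon()
    sub_lex = (
        subjectivity_lexicon if subjectivity_lexicon is not None
        else default_subjectivity_lexicon()
    )
    tokens = tokenize_normalize(text)
    if not tokens:
        return (0.0, 0.0)
    scores = [pol_lex[t] for t in tokens if t in pol_lex]
    polarity = float(np.mean(scores)) if scores else 0.0
    subjectivity = sum(1 for t in tokens if t in sub_lex) / len(tokens)
    return (polarity, float(subjectivity))


# ---------------------------------------------------------------------------
# category lexicon (LIWC-format dialect)


@dataclass
class CategoryLexicon:
    """Category word lists with terminal-wildcard patterns (``stem*``).

    Reads the percent-delimited dictionary dialect: a header block between
    two ``%`` lines mapping numeric category ids to names, then one line
    per word/stem listing the ids of the categories it belongs to.
    """

    categories: dict[str, list[str]]

    def __post_init__(self) -> None:
        self._exact: dict[str, list[str]] = {}
        self._prefixes: list[tuple[str, str]] = []
        for cat, patterns in self.categories.items():
            for p in patterns:
                p = p.lower()
                if p.endswith("*"):
                    self._prefixes.append((p[:-1], cat))
                else:
                    self._exact.setdefault(p, []).append(cat)
        self._cache: dict[str, dict[str, int]] = {}

    @classmethod
    def from_liwc_file(cls, path: str | Path) -> "CategoryLexicon":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls._parse(lines)

    @classmethod
    def _parse(cls, lines: list[str]) -> "CategoryLexicon":
        if not lines or lines[0].strip() != "%":
            raise ValueError("category dictionary must start with a '%' header line")
        idmap: dict[str, str] = {}
        i = 1
        while i < len(lines) and lines[i].strip() != "%":
            parts = lines[i].split()
            if len(parts) >= 2:
                idmap[parts[0]] = parts[1]
            i += 1
        categories: dict[str, list[str]] = {name: [] for name in idmap.values()}
        for line in lines[i + 1 :]:
            parts = line.split()
            if len(parts) < 2:
                continue
            word = parts[0].lower()
            for cid in parts[1:]:
                if cid in idmap:
                    categories[idmap[cid]].append(word)
        return cls(categories)

    def match(self, token: str) -> list[str]:
        """Categories a (lowercase) token belongs to."""
        cats = list(self._exact.get(token, ()))
        for prefix, cat in self._prefixes:
            if token.startswith(prefix) and cat not in cats:
                cats.append(cat)
        return cats

    def counts(self, text: str, normalize: bool = True) -> dict[str, float]:
        """Per-category word counts, or percentages of total token count.

        ``normalize=True`` (default) reports 100 * count / n_tokens, the
        convention of word-count category dictionaries; a zero-token text
        reports all categories as 0.
        """
        key = text if len(text) < 4096 else None
        if key is not None and normalize and key in self._cache:
            return dict(self._cache[key])
        tokens = tokenize_normalize(text)
        raw = {c: 0 for c in self.categories}
        for tok in tokens:
            for c in self.match(tok):
                raw[c] += 1
        if normalize:
            n = len(tokens)
            out = {c: (100.0 * v / n if n else 0.0) for c, v in raw.items()}
            if key is not None:
                self._cache[key] = dict(out)
            return out
        return {c: float(v) for c, v in raw.items()}


@lru_cache(maxsize=1)
def default_lexicon() -> CategoryLexicon:
    """Bundled open 15-category lexicon (a licensed dictionary in the same
    file format can be substituted via :meth:`CategoryLexicon.from_liwc_file`)."""
    text = resources.files("credfilter").joinpath("data/lexicon.dic").read_text("utf-8")
    return CategoryLexicon._parse(text.splitlines())


def lexicon_category_counts(
    text: str, lexicon: CategoryLexicon | None = None, normalize: bool = True
) -> dict[str, float]:
    """Count (or percent) category-lexicon words in a text."""
    lex = lexicon if lexicon is not None else default_lexicon()
    return lex.counts(text, normalize=normalize)


# ---------------------------------------------------------------------------
# embedding ingestion


def load_embeddings(matrix_file: str | Path, ids: Sequence[str]) -> tuple[np.ndarray, list[FeatureSpec]]:
    """Load precomputed per-triplet embedding vectors from a TSV file.

    The file has one row per triplet: id followed by the numeric vector.
    Rows are returned in the order of ``ids``.  A missing or duplicated id
    or a non-numeric cell raises a ``ValueError`` naming the offender.
    """
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    for lineno, line in enumerate(Path(matrix_file).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        rid = parts[0]
        if rid in table:
            raise ValueError(f"duplicate embedding row for id {rid!r} (line {lineno})")
        try:
            vec = np.array([float(x) for x in parts[1:]], dtype=float)
        except ValueError as e:
            raise ValueError(f"non-numeric embedding cell for id {rid!r} (line {lineno}): {e}")
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise ValueError(f"inconsistent embedding width for id {rid!r} (line {lineno})")
        table[rid] = vec
    missing = [i for i in ids if i not in table]
    if missing:
        raise ValueError(f"embedding file is missing ids: {missing[:5]}")
    values = np.vstack([table[i] for i in ids]) if ids else np.empty((0, dim or 0))
    specs = [FeatureSpec("EMB", f"EMB_{j}") for j in range(values.shape[1])]
    return values, specs


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureConfig:
    """Which families to extract and with which plugins.

    Exactly one lexical family must be chosen ('tfidf' or 'emb'); the
    stylometric families can be toggled individually.
    """

    lexical: str = "tfidf"
    use_dep: bool = True
    use_pos: bool = True
    use_ner: bool = True
    use_sent: bool = True
    use_lexicon: bool = True
    min_df: int = 2
    normalize_lexicon: bool = True
    lexicon: CategoryLexicon | None = None
    embeddings_path: str | None = None
    lemmatizer: Callable[[str], str] | None = None
    pos_tagger: Callable[[str], list[str]] | None = None
    dep_parser: Callable[[str], list[str]] | None = None
    gazetteer: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        lex = self.lexical
        if isinstance(lex, (list, tuple, set)):
            if len(lex) != 1:
                raise FeatureConfigError(
                    f"exactly one lexical family must be selected, got {sorted(lex)}"
                )
            lex = next(iter(lex))
            object.__setattr__(self, "lexical", lex)
        if not isinstance(lex, str) or lex.lower() not in ("tfidf", "emb"):
            raise FeatureConfigError(
                f"lexical family must be 'tfidf' or 'emb' (exactly one), got {lex!r}"
            )
        self.lexical = lex.lower()


# per-text caches for the default extractors; stylometric features are
# stateless, so repeated fold-wise transforms reuse these
@lru_cache(maxsize=100_000)
def _cached_dep_counts(text: str) -> tuple[tuple[str, int], ...]:
    return tuple(sorted(dependency_label_counts(text).items()))


@lru_cache(maxsize=100_000)
def _cached_pos_counts(text: str) -> tuple[tuple[str, int], ...]:
    return tuple(sorted(pos_counts(text).items()))


@lru_cache(maxsize=100_000)
def _cached_ner_counts(text: str) -> tuple[tuple[str, int], ...]:
    return tuple(sorted(named_entity_counts(text).items()))


@lru_cache(maxsize=100_000)
def _cached_sentiment(text: str) -> tuple[float, float]:
    return sentiment_scores(text)


def _family_frame(
    texts: Sequence[str], family: str, config: FeatureConfig
) -> pd.DataFrame:
    rows: list[dict[str, float]]
    if family == "DEP":
        if config.dep_parser is not None:
            rows = [dependency_label_counts(t, config.dep_parser) for t in texts]
        else:
            rows = [dict(_cached_dep_counts(t)) for t in texts]
    elif family == "POS":
        if config.pos_tagger is not None:
            rows = [pos_counts(t, config.pos_tagger) for t in texts]
        else:
            rows = [dict(_cached_pos_counts(t)) for t in texts]
    elif family == "NER":
        if config.gazetteer is not None:
            rows = [named_entity_counts(t, config.gazetteer) for t in texts]
        else:
            rows = [dict(_cached_ner_counts(t)) for t in texts]
    elif family == "SENT":
        vals = [_cached_sentiment(t) for t in texts]
        rows = [{"polarity": p, "subjectivity": s} for p, s in vals]
    elif family == "LEXICON":
        lex = config.lexicon if config.lexicon is not None else default_lexicon()
        rows = [lex.counts(t, normalize=config.normalize_lexicon) for t in texts]
    else:  # pragma: no cover
        raise ValueError(family)
    df = pd.DataFrame(rows, dtype=float).fillna(0.0)
    return df.reindex(sorted(df.columns), axis=1)


def _enabled_stylometric(config: FeatureConfig) -> list[str]:
    fams = []
    if config.use_dep:
        fams.append("DEP")
    if config.use_pos:
        fams.append("POS")
    if config.use_ner:
        fams.append("NER")
    if config.use_sent:
        fams.append("SENT")
    if config.use_lexicon:
        fams.append("LEXICON")
    return fams


class TripletFeaturizer:
    """Fit-on-train / transform-anywhere featurizer over triplets.

    ``fit`` learns everything partition-dependent — the TF-IDF vocabulary
    and idf weights, the stylometric column set, and the per-column
    standardization statistics — from the training triplets only.
    ``transform`` maps any triplets into exactly that column space, so
    held-out rows can never influence the representation.
    """

    def __init__(self, config: FeatureConfig | None = None, standardize: bool = True):
        self.config = config if config is not None else FeatureConfig()
        self.standardize = standardize

    # -- sklearn-style param plumbing -------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "standardize": self.standardize}

    def set_params(self, **params) -> "TripletFeaturizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    def fit(self, triplets: Sequence[Triplet], y=None) -> "TripletFeaturizer":
        cfg = self.config
        texts = [t.text for t in triplets]
        raw = self._raw_blocks(triplets, fit=True)
        matrix = FeatureMatrix(
            row_ids=[t.triplet_id for t in triplets],
            specs=raw[0],
            values=raw[1],
        )
        self.columns_ = [c.column for c in matrix.specs]
        if self.standardize:
            mean = matrix.values.mean(axis=0)
            sd = matrix.values.std(axis=0)
            self.mean_, self.sd_ = mean, sd
        self.fitted_ids_ = list(matrix.row_ids)
        return self

    def _raw_blocks(self, triplets: Sequence[Triplet], fit: bool) -> tuple[list[FeatureSpec], np.ndarray]:
        cfg = self.config
        texts = [t.text for t in triplets]
        ids = [t.triplet_id for t in triplets]
        specs: list[FeatureSpec] = []
        blocks: list[np.ndarray] = []
        # lexical family
        if cfg.lexical == "tfidf":
            token_lists = [tokenize_normalize(t, cfg.lemmatizer) for t in texts]
            if fit:
                self.tfidf_ = fit_tfidf(token_lists, min_df=cfg.min_df)
            specs.extend(self.tfidf_.specs())
            blocks.append(self.tfidf_.transform(token_lists))
        else:
            if cfg.embeddings_path is None:
                raise FeatureConfigError("lexical='emb' requires embeddings_path")
            values, emb_specs = load_embeddings(cfg.embeddings_path, ids)
            specs.extend(emb_specs)
            blocks.append(values)
        # stylometric families
        for family in _enabled_stylometric(cfg):
            df = _family_frame(texts, family, cfg)
            if fit:
                setattr(self, f"_cols_{family}", list(df.columns))
            cols = getattr(self, f"_cols_{family}")
            df = df.reindex(columns=cols, fill_value=0.0)
            specs.extend(FeatureSpec(family, c) for c in cols)
            blocks.append(df.to_numpy(dtype=float))
        values = np.hstack(blocks) if blocks else np.empty((len(ids), 0))
        return specs, values

    def transform(self, triplets: Sequence[Triplet]) -> FeatureMatrix:
        if not hasattr(self, "columns_"):
            raise RuntimeError("TripletFeaturizer is not fitted")
        specs, values = self._raw_blocks(triplets, fit=False)
        std = None
        if self.standardize:
            sd = np.where(self.sd_ > 0, self.sd_, 1.0)
            values = (values - self.mean_) / sd
            std = Standardization(mean=self.mean_.copy(), sd=self.sd_.copy(),
                                  fitted_on=list(self.fitted_ids_))
        return FeatureMatrix(
            row_ids=[t.triplet_id for t in triplets],
            specs=specs,
            values=values,
            standardization=std,
        )

    def fit_transform(self, triplets: Sequence[Triplet], y=None) -> FeatureMatrix:
        return self.fit(triplets, y).transform(triplets)


def standardize_features(matrix: FeatureMatrix, fit_ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Return a standardized copy of a raw feature matrix.

    Per-column mean and sd are fitted on ``fit_ids`` (default: all rows)
    and applied to every row.  Constant columns are centered but not
    scaled.
    """
    fit_ids = list(fit_ids) if fit_ids is not None else list(matrix.row_ids)
    fit_rows = matrix.rows(fit_ids)
    mean = fit_rows.mean(axis=0)
    sd = fit_rows.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    return FeatureMatrix(
        row_ids=list(matrix.row_ids),
        specs=list(matrix.specs),
        values=(matrix.values - mean) / scale,
        standardization=Standardization(mean=mean, sd=sd, fitted_on=fit_ids),
    )


def assemble_features(
    triplets: Sequence[Triplet],
    config: FeatureConfig | None = None,
    fit_ids: Sequence[str] | None = None,
    standardize: bool = True,
) -> FeatureMatrix:
    """Build the full family-tagged feature matrix for a set of triplets.

    All partition-dependent statistics (TF-IDF vocabulary/idf, column
    sets, standardization) are fitted on the rows named by ``fit_ids``
    (default: all rows) and applied everywhere.
    """
    config = config if config is not None else FeatureConfig()
    featurizer = TripletFeaturizer(config, standardize=standardize)
    if fit_ids is None:
        fit_subset = list(triplets)
    else:
        wanted = set(fit_ids)
        fit_subset = [t for t in triplets if t.triplet_id in wanted]
        if not fit_subset:
            raise ValueError("fit_ids selects no triplets")
    featurizer.fit(fit_subset)
    return featurizer.transform(triplets)
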