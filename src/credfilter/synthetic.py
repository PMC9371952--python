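"""Seed-deterministic synthetic corpora with the pipeline's assumed structure.

The generator emulates a sentence-level credibility-annotated corpus of
online medical articles: per-topic three-class label streams with
configurable class proportions, within-article clustering of non-credible
sentences (a first-order persistence chain), class-specific marker
vocabularies mixed into background unigram text, stylometric deltas for
the non-credible class (certainty words, exclamations, organization
mentions), long-tailed lognormal annotation times, and per-class
context-need rates.  Closed-form oracles for the induced triplet-level
negative rate make every downstream stage testable without any real data.

Text is a unigram mixture, not grammatical prose: every downstream feature
family operates on tokens and counts, so token statistics are the part of
real data that matters here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import Article, Corpus, LabeledSentence, Triplet, build_triplets

__all__ = [
    "TopicConfig",
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_triplets",
    "expected_triplet_negative_rate",
    "default_presets",
    "small_preset",
]

CRED_MARKERS = (
    "study", "trial", "randomized", "evidence", "dose", "guideline",
    "association", "risk",
)
NONCRED_MARKERS = (
    "miracle", "detox", "toxin", "bigpharma", "coverup", "suppressed",
    "cure", "remedy",
)
NEU_MARKERS = (
    "website", "click", "share", "comment", "page", "read", "article",
    "today",
)
_MARKERS = {"CRED": CRED_MARKERS, "NONCRED": NONCRED_MARKERS, "NEU": NEU_MARKERS}

CERTAINTY_WORDS = ("always", "never", "proven", "guaranteed", "definitely")

#: generic background unigrams shared by all classes
BACKGROUND_VOCAB = (
    "the a an and or but of to in for with on about people health body"
    " doctor patient year time day way thing part number group problem"
    " question work life hand place case point company week month night"
    " water food heart blood level system result research report news"
    " information story fact idea reason change effect cause treatment"
    " medicine drug test sign symptom care help need use make take find"
    " give tell ask show feel leave call keep begin seem talk turn start"
    " might could would should many much more most other some any new"
    " good high low long great little own old right big different small"
    " large next early young important few public bad same able"
).split()

#: context-depth probabilities per class over {0 sentences, 1, >1},
#: mirroring observed per-class context-need rates
DEFAULT_CONTEXT_PROBS = {
    "CRED": (0.8007, 0.1883, 0.0018),
    "NONCRED": (0.7127, 0.2660, 0.0037),
    "NEU": (0.8830, 0.1103, 0.0004),
}


@dataclass(frozen=True)
class TopicConfig:
    """Generator parameters for one topic."""

    name: str
    n_articles: int = 25
    sentences_per_article: float = 40.0  # Poisson mean, floored at 6
    class_probs: tuple[float, float, float] = (0.55, 0.266, 0.184)  # CRED, NEU, NONCRED
    rho: float = 0.5  # persistence: repeat previous class with this probability
    mean_time_s: float = 25.0  # mean annotation time (lognormal)
    context_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_PROBS)
    )

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.class_probs):
            raise ValueError(f"class probabilities must be a distribution, got {self.class_probs}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.mean_time_s <= 0:
            raise ValueError("mean_time_s must be positive")

    @property
    def p_noncred(self) -> float:
        return self.class_probs[2]


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus-wide generator parameters.

    ``marker_rate`` is the per-token probability of drawing a marker from
    each non-own class pool; the own-class pool is elevated by
    ``elevation_ratio``.  The non-credible stylometric deltas (certainty
    words, terminal exclamation marks, organization mentions) default to
    the corresponding base rate multiplied by the same elevation ratio, so
    ratio 1 means no class signal of any kind and larger ratios
    strengthen the lexical and stylometric signals together; each
    non-credible rate can also be overridden independently.
    """

    topics: tuple[TopicConfig, ...] = (TopicConfig(name="topic"),)
    marker_rate: float = 0.08
    elevation_ratio: float = 3.0
    certainty_rate: float = 0.02
    certainty_rate_noncred: float | None = None  # default: base * elevation_ratio
    exclaim_rate: float = 0.1
    exclaim_rate_noncred: float | None = None
    org_rate: float = 0.015
    org_rate_noncred: float | None = None
    time_sigma: float = 0.6  # lognormal shape of annotation times
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elevation_ratio < 1.0:
            raise ValueError("elevation_ratio must be >= 1")
        for name in ("certainty_rate_noncred", "exclaim_rate_noncred", "org_rate_noncred"):
            if getattr(self, name) is None:
                base = getattr(self, name.removesuffix("_noncred"))
                object.__setattr__(self, name, min(1.0, base * self.elevation_ratio))
        own = self.marker_rate * self.elevation_ratio
        if own + 2 * self.marker_rate + self.certainty_rate_noncred >= 1:
            raise ValueError("marker rates leave no room for background text")


@dataclass
class GroundTruth:
    """Per-sentence truth emitted alongside the corpus."""

    sentences: pd.DataFrame  # article_id, position, topic, label, n_markers
    config: GeneratorConfig

    def write(self, path) -> None:
        self.sentences.to_json(path, orient="records", lines=True)


_LABELS = ("CRED", "NEU", "NONCRED")


def _label_chain(rng: np.random.Generator, n: int, probs: np.ndarray, rho: float) -> list[str]:
    labels = [_LABELS[rng.choice(3, p=probs)]]
    for _ in range(n - 1):
        if rng.random() < rho:
            labels.append(labels[-1])
        else:
            labels.append(_LABELS[rng.choice(3, p=probs)])
    return labels


def _background_weights() -> np.ndarray:
    ranks = np.arange(1, len(BACKGROUND_VOCAB) + 1, dtype=float)
    w = 1.0 / ranks  # zipf-ish long tail
    return w / w.sum()


def _sentence_text(
    rng: np.random.Generator, label: str, cfg: GeneratorConfig, bg_w: np.ndarray
) -> tuple[str, int]:
    length = int(rng.integers(14, 27))
    own_rate = cfg.marker_rate * cfg.elevation_ratio
    cert_rate = cfg.certainty_rate_noncred if label == "NONCRED" else cfg.certainty_rate
    others = [l for l in _LABELS if l != label]
    u = rng.random(length)
    pool_pick = rng.integers(0, 8, size=length)  # all marker pools have 8 entries
    cert_pick = rng.integers(0, len(CERTAINTY_WORDS), size=length)
    bg_pick = rng.choice(len(bg_w), size=length, p=bg_w)
    b1 = own_rate
    b2 = b1 + cfg.marker_rate
    b3 = b2 + cfg.marker_rate
    b4 = b3 + cert_rate
    tokens: list[str] = []
    n_markers = 0
    for i in range(length):
        if u[i] < b1:
            tokens.append(_MARKERS[label][pool_pick[i]])
            n_markers += 1
        elif u[i] < b2:
            tokens.append(_MARKERS[others[0]][pool_pick[i]])
        elif u[i] < b3:
            tokens.append(_MARKERS[others[1]][pool_pick[i]])
        elif u[i] < b4:
            tokens.append(CERTAINTY_WORDS[cert_pick[i]])
        else:
            tokens.append(BACKGROUND_VOCAB[bg_pick[i]])
    org_rate = cfg.org_rate_noncred if label == "NONCRED" else cfg.org_rate
    if rng.random() < org_rate:
        tokens.insert(int(rng.integers(len(tokens))), "Pfizer")
    exclaim = cfg.exclaim_rate_noncred if label == "NONCRED" else cfg.exclaim_rate
    terminal = "!" if rng.random() < exclaim else "."
    return " ".join(tokens) + terminal, n_markers


def generate_corpus(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[Corpus, GroundTruth]:
    """Generate a labelled synthetic corpus; fully deterministic per seed.

    Sentence classes follow a first-order chain per article: with
    probability rho the previous class repeats, otherwise a fresh class is
    drawn from the topic's class probabilities (rho=0 gives iid labels).
    Annotation times are lognormal with the topic's configured mean;
    context depth is sampled from the per-class distributions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bg_w = _background_weights()
    corpus = Corpus()
    truth_rows = []
    for topic in config.topics:
        probs = np.asarray(topic.class_probs, dtype=float)
        probs = probs / probs.sum()
        mu = np.log(topic.mean_time_s) - config.time_sigma**2 / 2
        articles = []
        for a in range(topic.n_articles):
            article_id = f"{topic.name}-a{a:03d}"
            n_s = max(6, int(rng.poisson(topic.sentences_per_article)))
            labels = _label_chain(rng, n_s, probs, topic.rho)
            sentences = []
            for pos, label in enumerate(labels):
                text, n_markers = _sentence_text(rng, label, config, bg_w)
                cps = np.asarray(topic.context_probs[label], dtype=float)
                cps = cps / cps.sum()
                depth = int(rng.choice(3, p=cps))
                time_s = float(np.exp(rng.normal(mu, config.time_sigma)))
                sentences.append(
                    LabeledSentence(
                        article_id=article_id,
                        topic=topic.name,
                        position=pos,
                        text=text,
                        label=label,
                        annotation_time_seconds=time_s,
                        context_depth=depth,
                    )
                )
                truth_rows.append(
                    {
                        "article_id": article_id,
                        "position": pos,
                        "topic": topic.name,
                        "label": label,
                        "n_markers": n_markers,
                    }
                )
            articles.append(Article(article_id=article_id, topic=topic.name, sentences=sentences))
        corpus.topics[topic.name] = articles
    truth = GroundTruth(sentences=pd.DataFrame(truth_rows), config=config)
    return corpus, truth


def generate_triplets(
    topic: TopicConfig,
    n_triplets: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[Triplet]:
    """Generate articles for one topic until at least ``n_triplets`` exist,
    then truncate to exactly that many."""
    config = config if config is not None else GeneratorConfig()
    per_article = max(1, int(topic.sentences_per_article) // 3)
    n_articles = int(np.ceil(n_triplets / per_article)) + 2
    cfg = replace(config, topics=(replace(topic, n_articles=n_articles),))
    corpus, _ = generate_corpus(cfg, seed=seed)
    triplets: list[Triplet] = []
    for article in corpus.articles():
        triplets.extend(build_triplets(article))
        if len(triplets) >= n_triplets:
            break
    if len(triplets) < n_triplets:
        raise RuntimeError("generator produced too few triplets; increase n_articles")
    return triplets[:n_triplets]


def expected_triplet_negative_rate(p_noncred: float, rho: float = 0.0) -> float:
    """Expected fraction of negative triplets under the generator's chain.

    For iid labels (rho=0) this is the closed form 1 - (1 - p)^3.  For
    rho > 0 the 3-step persistence chain is enumerated: only membership in
    the non-credible class matters, so the 27 label paths collapse onto
    the 8 paths of the 2-state (NONCRED vs not) chain, whose stationary
    start distribution is (p, 1-p).
    """
    p = float(p_noncred)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_noncred must lie in [0, 1], got {p}")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if rho == 0.0:
        return 1.0 - (1.0 - p) ** 3
    start = {True: p, False: 1.0 - p}
    trans = {
        (True, True): rho + (1 - rho) * p,
        (False, True): (1 - rho) * p,
        (True, False): (1 - rho) * (1 - p),
        (False, False): rho + (1 - rho) * (1 - p),
    }
    prob_negative = 0.0
    for s1 in (True, False):
        for s2 in (True, False):
            for s3 in (True, False):
                if s1 or s2 or s3:
                    prob_negative += start[s1] * trans[(s1, s2)] * trans[(s2, s3)]
    return prob_negative


def default_presets() -> tuple[TopicConfig, ...]:
    """Ten topic presets with realistic class mixes and mean times.

    The class-count triples (CRED, NEU, NONCRED) mirror a published
    ten-topic annotated corpus; they are presets for realistic simulation,
    not claims about any particular dataset.
    """
    rows = [
        # name, CRED, NEU, NONCRED, mean_time_s
        ("antioxidants", 375, 175, 144, 18.0),
        ("heart-supplements", 221, 124, 78, 19.0),
        ("cholesterol-statins", 1058, 565, 406, 20.0),
        ("csection-vs-birth", 275, 53, 31, 22.0),
        ("children-antibiotics", 298, 52, 82, 24.0),
        ("diet-autism", 236, 71, 124, 25.0),
        ("steroids-for-kids", 560, 101, 40, 26.0),
        ("vaccination", 730, 223, 309, 27.0),
        ("allergy-testing", 790, 398, 214, 28.0),
        ("psychiatry", 1194, 676, 402, 35.0),
    ]
    presets = []
    for name, c, u, n, t in rows:
        total = c + u + n
        presets.append(
            TopicConfig(
                name=name,
                n_articles=max(4, int(round(total / 40.0))),
                class_probs=(c / total, u / total, n / total),
                mean_time_s=t,
            )
        )
    return tuple(presets)


def small_preset(n_topics: int = 2, n_articles: int = 30, seed: int = 0) -> GeneratorConfig:
    """A small two-topic configuration for quick end-to-end runs."""
    topics = tuple(
        replace(t, n_articles=n_articles) for t in default_presets()[:n_topics]
    )
    return GeneratorConfig(topics=topics, seed=seed)
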