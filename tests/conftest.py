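import numpy as np
import pytest

from credfilter.corpus import Article, LabeledSentence, Triplet, build_triplets
from credfilter.synthetic import GeneratorConfig, TopicConfig, generate_triplets


def make_article(labels, topic="t", article_id="a1", texts=None):
    sentences = [
        LabeledSentence(
            article_id=article_id,
            topic=topic,
            position=i,
            text=texts[i] if texts else f"sentence number {i} about health.",
            label=lab,
        )
        for i, lab in enumerate(labels)
    ]
    return Article(article_id=article_id, topic=topic, sentences=sentences)


@pytest.fixture
def small_article():
    return make_article(["CRED", "NEU", "NONCRED", "CRED", "CRED", "NEU"])


@pytest.fixture(scope="session")
def signal_triplets():
    """300 synthetic triplets with class signal, for model-level tests."""
    topic = TopicConfig(name="sig")
    trips = generate_triplets(topic, 300, config=GeneratorConfig(), seed=11)
    return trips


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
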