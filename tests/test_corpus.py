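import itertools

import numpy as np
import pandas as pd
import pytest

from credfilter.corpus import (
    LABELS,
    CorpusValidationError,
    LabeledSentence,
    build_triplets,
    corpus_summary,
    propagate_label,
    read_corpus,
    segment_sentences,
    write_corpus,
)
from credfilter.synthetic import GeneratorConfig, TopicConfig, generate_corpus
from conftest import make_article


class TestReadWrite:
    def _write_sample(self, path, fmt):
        df = pd.DataFrame(
            {
                "article_id": ["a1", "a1", "a1"],
                "topic": ["vax", "vax", "vax"],
                "position": [2, 0, 1],  # deliberately out of order
                "text": ["Third, with a comma.", "First.", "Second."],
                "label": ["CRED", "NEU", "NONCRED"],
            }
        )
        if fmt == "json-lines":
            df.to_json(path, orient="records", lines=True)
        else:
            df.to_csv(path, index=False)

    @pytest.mark.parametrize("fmt,suffix", [("delimited", ".csv"), ("json-lines", ".jsonl")])
    def test_ingestion_groups_and_sorts(self, tmp_path, fmt, suffix):
        path = tmp_path / f"c{suffix}"
        self._write_sample(path, fmt)
        corpus = read_corpus(path, format=fmt)
        assert list(corpus.topics) == ["vax"]
        (article,) = corpus.topics["vax"]
        assert [s.position for s in article.sentences] == [0, 1, 2]
        assert [s.label for s in article.sentences] == ["NEU", "NONCRED", "CRED"]

    def test_unknown_label_rejected_with_row(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {"article_id": ["a"], "topic": ["t"], "position": [0],
             "text": ["x"], "label": ["TRUE"]}
        ).to_csv(path, index=False)
        with pytest.raises(CorpusValidationError, match="TRUE"):
            read_corpus(path)

    def test_duplicate_position_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {"article_id": ["a", "a"], "topic": ["t", "t"], "position": [0, 0],
             "text": ["x", "y"], "label": ["CRED", "NEU"]}
        ).to_csv(path, index=False)
        with pytest.raises(CorpusValidationError, match="duplicate"):
            read_corpus(path)

    @pytest.mark.parametrize("suffix", [".csv", ".tsv", ".jsonl"])
    def test_round_trip_preserves_everything(self, tmp_path, suffix):
        corpus, _ = generate_corpus(
            GeneratorConfig(topics=(TopicConfig(name="t", n_articles=3),)), seed=5
        )
        p1, p2 = tmp_path / f"a{suffix}", tmp_path / f"b{suffix}"
        write_corpus(corpus, p1)
        write_corpus(read_corpus(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_corpus(p2)
        orig = list(corpus.sentences())
        readback = list(back.sentences())
        assert [s.text for s in orig] == [s.text for s in readback]
        assert [s.label for s in orig] == [s.label for s in readback]
        assert [s.context_depth for s in orig] == [s.context_depth for s in readback]


class TestSegmentation:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A. B? C!", ["A.", "B?", "C!"]),
            ("", []),
            ("   ", []),
            ("No terminal punctuation", ["No terminal punctuation"]),
            ("Dr. Smith agrees. So do I.", ["Dr. Smith agrees.", "So do I."]),
            ("It works, e.g. here. And there.", ["It works, e.g. here.", "And there."]),
        ],
    )
    def test_rule_based_splitting(self, text, expected):
        assert segment_sentences(text) == expected

    def test_concatenation_covers_input(self):
        text = "One sentence here. Another one there! A third?"
        parts = segment_sentences(text)
        assert " ".join(parts) == text


class TestLabelPropagation:
    def test_any_noncred_makes_negative(self):
        assert propagate_label(["NONCRED", "CRED", "CRED"]) == "negative"
        assert propagate_label(["CRED", "NEU", "CRED"]) == "positive"

    def test_matches_brute_force_on_all_27(self):
        negatives = 0
        for combo in itertools.product(LABELS, repeat=3):
            expected = "negative" if any(l == "NONCRED" for l in combo) else "positive"
            assert propagate_label(list(combo)) == expected
            negatives += expected == "negative"
        assert negatives == 19  # 27 - 2^3 all-{CRED,NEU} combinations

    @pytest.mark.parametrize("bad", [[], ["CRED"], ["CRED"] * 4])
    def test_wrong_arity_rejected(self, bad):
        with pytest.raises(ValueError):
            propagate_label(bad)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            propagate_label(["CRED", "MAYBE", "CRED"])


class TestTriplets:
    @pytest.mark.parametrize("n,expected", [(9, 3), (10, 3), (11, 3), (12, 4), (2, 0), (0, 0)])
    def test_counts_under_drop_policy(self, n, expected):
        article = make_article(["CRED"] * n)
        assert len(build_triplets(article)) == expected

    def test_pad_policy_completes_last_block(self):
        article = make_article(["CRED"] * 4 + ["NONCRED"])
        trips = build_triplets(article, remainder="pad")
        assert len(trips) == 2
        # last sentence repeated to fill the block keeps its label
        assert trips[1].binary_label == "negative"
        assert [m.position for m in trips[1].members] == [3, 4, 4]

    def test_blocks_are_consecutive_and_disjoint(self):
        article = make_article(["CRED", "NEU", "NONCRED"] * 4)
        trips = build_triplets(article)
        used = [m.position for t in trips for m in t.members]
        assert used == list(range(12))
        assert all(t.binary_label == "negative" for t in trips)

    def test_unlabeled_sentence_rejected(self):
        art = make_article(["CRED", "NEU", "CRED"])
        art.sentences[1] = LabeledSentence(
            article_id="a1", topic="t", position=1, text="x", label=None
        )
        with pytest.raises(CorpusValidationError, match="unlabeled"):
            build_triplets(art)


class TestSummary:
    def test_context_depth_percentages(self):
        labels = ["CRED"] * 5
        art = make_article(labels)
        art.sentences = [
            LabeledSentence("a1", "t", i, "x", "CRED", context_depth=(1 if i == 4 else 0))
            for i in range(5)
        ]
        from credfilter.corpus import Corpus

        summary = corpus_summary(Corpus(topics={"t": [art]}))
        row = summary.context_depth_pct.loc["CRED"]
        assert row["0"] == pytest.approx(80.0)
        assert row["1"] == pytest.approx(20.0)
        assert row[">1"] == pytest.approx(0.0)
        assert summary.class_counts.loc["t", "CRED"] == 5

    def test_empty_corpus(self):
        from credfilter.corpus import Corpus

        summary = corpus_summary(Corpus())
        assert summary.n_sentences == 0
        assert summary.class_counts.empty

    def test_simulated_depth_proportions_recovered(self):
        probs = (0.8, 0.19, 0.01)
        topic = TopicConfig(
            name="t", n_articles=50,
            context_probs={lab: probs for lab in ("CRED", "NEU", "NONCRED")},
        )
        corpus, _ = generate_corpus(GeneratorConfig(topics=(topic,)), seed=7)
        summary = corpus_summary(corpus)
        n = summary.n_sentences
        assert n >= 1500
        pooled = summary.context_depth_pct.mul(
            summary.class_counts.sum(axis=0), axis=0
        ).sum(axis=0) / n
        for pct, p in zip(pooled, probs):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(pct / 100 - p) <= 3 * se + 1e-12
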