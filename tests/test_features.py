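import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from credfilter.features import (
    CategoryLexicon,
    FeatureConfig,
    FeatureConfigError,
    TripletFeaturizer,
    assemble_features,
    dependency_label_counts,
    fit_tfidf,
    heuristic_dependency_parser,
    heuristic_pos_tagger,
    lexicon_category_counts,
    load_embeddings,
    named_entity_counts,
    pos_counts,
    sentiment_scores,
    simple_lemmatizer,
    standardize_features,
    tokenize_normalize,
)
from credfilter.synthetic import GeneratorConfig, TopicConfig, generate_triplets


class TestTokenization:
    def test_lemmatizer_normalizes_plurals(self):
        assert tokenize_normalize("Statins deplete CoQ10", simple_lemmatizer) == [
            "statin", "deplete", "coq10",
        ]

    def test_empty_text(self):
        assert tokenize_normalize("") == []

    def test_case_folding_collapses(self):
        assert tokenize_normalize("THE the The") == ["the"] * 3


class TestTfidf:
    def test_ubiquitous_term_has_idf_one(self):
        model = fit_tfidf([["a", "b"], ["a", "c"]], min_df=1)
        assert model.idf("a") == pytest.approx(1.0)

    def test_smoothed_idf_closed_form(self):
        # N=2 docs, term in 1 of them: ln(3/2) + 1
        model = fit_tfidf([["a", "b"], ["a", "c"]], min_df=1)
        assert model.idf("b") == pytest.approx(math.log(3 / 2) + 1, abs=1e-6)

    def test_rows_unit_l2_or_zero(self):
        model = fit_tfidf([["a", "b"], ["a", "c"], ["b", "b", "c"]], min_df=1)
        X = model.transform([["a", "b"], ["zzz"], []])
        norms = np.linalg.norm(X, axis=1)
        assert norms[0] == pytest.approx(1.0)
        assert norms[1] == 0.0  # fully out-of-vocabulary
        assert norms[2] == 0.0  # empty document

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_tfidf([], min_df=1)


class TestTaggerFamilies:
    def test_stub_parser_counts(self):
        stub = lambda text: ["dep"] * len(text.split())
        assert dependency_label_counts("one two three four five", stub) == {"dep": 5}

    def test_stub_tagger_counts(self):
        stub = lambda text: ["NOUN"] * len(text.split())
        assert pos_counts("a b c d", stub) == {"NOUN": 4}

    @pytest.mark.parametrize("fn", [dependency_label_counts, pos_counts])
    def test_empty_text_all_zero(self, fn):
        assert fn("") == {}

    def test_one_tag_per_token(self):
        text = "The doctor said that 5 vaccines are safe."
        pos = heuristic_pos_tagger(text)
        dep = heuristic_dependency_parser(text)
        assert len(pos) == len(dep)
        assert sum(pos_counts(text).values()) == len(pos)
        assert sum(dependency_label_counts(text).values()) == len(dep)


class TestNamedEntities:
    def test_gazetteer_and_number(self):
        counts = named_entity_counts(
            "Pfizer reported 30 cases", gazetteer={"Pfizer": "ORGANIZATION"}
        )
        assert counts["ORGANIZATION"] == 1
        assert counts["NUMBER"] == 1
        assert counts["PERSON"] == 0

    def test_multiword_span_matches_longest_first(self):
        counts = named_entity_counts("Experts at Mayo Clinic disagree")
        assert counts["ORGANIZATION"] == 1

    def test_no_hits_all_zero(self):
        counts = named_entity_counts("nothing capitalized or numeric here")
        assert all(v == 0 for v in counts.values())


class TestSentiment:
    def test_empty_text(self):
        assert sentiment_scores("") == (0.0, 0.0)

    def test_pure_positive_is_bounded_at_one(self):
        lex = {"good": 1.0}
        pol, _ = sentiment_scores("good good good", polarity_lexicon=lex)
        assert pol == pytest.approx(1.0)

    def test_balanced_words_cancel(self):
        lex = {"good": 1.0, "bad": -1.0}
        pol, _ = sentiment_scores("good bad good bad", polarity_lexicon=lex)
        assert pol == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="abcxyz !?.", max_size=120))
    def test_bounds_on_fuzzed_text(self, text):
        pol, sub = sentiment_scores(text)
        assert -1.0 <= pol <= 1.0
        assert 0.0 <= sub <= 1.0


class TestCategoryLexicon:
    def test_counts_and_percentages(self):
        lex = CategoryLexicon({"certain": ["always", "never"]})
        raw = lex.counts("never say never", normalize=False)
        assert raw["certain"] == 2.0
        pct = lex.counts("never say never", normalize=True)
        assert pct["certain"] == pytest.approx(200 / 3, abs=0.01)

    def test_wildcard_matches_prefix(self):
        lex = CategoryLexicon({"cause": ["caus*"]})
        assert lex.counts("causes causation cautious", normalize=False)["cause"] == 2.0

    def test_empty_text_zero(self):
        lex = CategoryLexicon({"certain": ["always"]})
        assert lex.counts("", normalize=True) == {"certain": 0.0}

    def test_liwc_format_parsing(self, tmp_path):
        dic = tmp_path / "x.dic"
        dic.write_text("%\n1\talpha\n2\tbeta\n%\nfoo\t1\nbar\t1\t2\nbaz*\t2\n")
        lex = CategoryLexicon.from_liwc_file(dic)
        assert lex.counts("foo bar bazaar", normalize=False) == {"alpha": 2.0, "beta": 2.0}

    def test_bundled_lexicon_loads(self):
        counts = lexicon_category_counts("never always maybe", normalize=False)
        assert counts["certain"] == 2.0
        assert counts["tentat"] == 1.0


class TestEmbeddings:
    def _write(self, path, rows):
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows))

    def test_load_in_id_order(self, tmp_path):
        f = tmp_path / "emb.tsv"
        self._write(f, [["b", 1, 2], ["a", 3, 4], ["c", 5, 6]])
        values, specs = load_embeddings(f, ["a", "b", "c"])
        assert values.shape == (3, 2)
        assert values[0].tolist() == [3.0, 4.0]
        assert [s.name for s in specs] == ["EMB_0", "EMB_1"]

    def test_missing_id_named(self, tmp_path):
        f = tmp_path / "emb.tsv"
        self._write(f, [["a", 1.0]])
        with pytest.raises(ValueError, match="missing"):
            load_embeddings(f, ["a", "zzz"])

    def test_duplicate_id_rejected(self, tmp_path):
        f = tmp_path / "emb.tsv"
        self._write(f, [["a", 1.0], ["a", 2.0]])
        with pytest.raises(ValueError, match="duplicate"):
            load_embeddings(f, ["a"])

    def test_non_numeric_cell_rejected(self, tmp_path):
        f = tmp_path / "emb.tsv"
        f.write_text("a\t1.0\tnope\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_embeddings(f, ["a"])


class TestAssembly:
    def test_family_tagged_concatenation(self, signal_triplets):
        matrix = assemble_features(signal_triplets[:50], FeatureConfig(min_df=1))
        families = {s.family for s in matrix.specs}
        assert families == {"TFIDF", "DEP", "POS", "NER", "SENT", "LEXICON"}
        assert matrix.values.shape[0] == 50

    def test_both_lexical_families_rejected(self):
        with pytest.raises(FeatureConfigError, match="exactly one"):
            FeatureConfig(lexical=["tfidf", "emb"])
        with pytest.raises(FeatureConfigError):
            FeatureConfig(lexical="tfidf+emb")

    def test_standardized_training_columns(self, signal_triplets):
        trips = signal_triplets[:60]
        matrix = assemble_features(trips, FeatureConfig(min_df=1), standardize=True)
        means = matrix.values.mean(axis=0)
        sds = matrix.values.std(axis=0)
        nonconstant = matrix.standardization.sd > 0
        assert np.all(np.abs(means[nonconstant]) < 1e-6)
        assert np.allclose(sds[nonconstant], 1.0, atol=1e-6)

    def test_raw_tfidf_rows_unit_norm(self, signal_triplets):
        trips = signal_triplets[:40]
        matrix = assemble_features(trips, FeatureConfig(min_df=1), standardize=False)
        block = matrix.values[:, matrix.family_indices("TFIDF")]
        norms = np.linalg.norm(block, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))

    def test_no_leakage_from_heldout_rows(self, signal_triplets):
        train, held = signal_triplets[:40], signal_triplets[40:60]
        featurizer = TripletFeaturizer(FeatureConfig(min_df=1)).fit(train)
        single = featurizer.transform([held[0]])
        batch = featurizer.transform(held)
        assert np.allclose(single.values[0], batch.values[0])

    def test_deterministic_given_fixed_plugins(self, signal_triplets):
        trips = signal_triplets[:30]
        m1 = assemble_features(trips, FeatureConfig(min_df=1))
        m2 = assemble_features(trips, FeatureConfig(min_df=1))
        assert np.array_equal(m1.values, m2.values)
        assert m1.specs == m2.specs

    def test_standardize_fit_partition_only(self, signal_triplets):
        trips = signal_triplets[:50]
        raw = assemble_features(trips, FeatureConfig(min_df=1), standardize=False)
        fit_ids = raw.row_ids[:30]
        std = standardize_features(raw, fit_ids=fit_ids)
        fit_block = std.rows(fit_ids)
        nonconstant = std.standardization.sd > 0
        assert np.all(np.abs(fit_block.mean(axis=0)[nonconstant]) < 1e-6)
        assert std.standardization.fitted_on == list(fit_ids)
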