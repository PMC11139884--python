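"""Feature families: worked oracles, registry arithmetic, invariants."""

import numpy as np
import pytest

from ptsdlang.corpus_io import LexiconResource, Transcript, tokenize
from ptsdlang.features import (
    disfluency_features,
    emotion_features,
    extract_all,
    lexical_field_rates,
    morphosyntactic_features,
    passive_voice_features,
    readability_features,
    reduce_features,
    textual_features,
)
from ptsdlang.registry import FeatureTable, default_registry
from ptsdlang.tagging import LexiconFieldTagger

from .conftest import doc


class TestRegistry:
    def test_group_sizes_as_printed(self):
        reg = default_registry()
        assert reg.group_sizes() == {
            "textual": 2, "sentiment_emotion": 27, "lexical": 4,
            "morphosyntactic": 18, "syntactic_passive": 4, "disfluency": 9,
            "readability": 5, "graph": 12,
        }

    def test_retained_counts(self):
        reg = default_registry()
        retained = reg.retained_names
        sentiment = [n for n in retained
                     if reg.group(n) == "sentiment_emotion"]
        passive = [n for n in retained if reg.group(n) == "syntactic_passive"]
        assert len(sentiment) == 6
        assert passive == ["passive_count_norm"]

    def test_json_round_trip(self):
        reg = default_registry()
        from ptsdlang.registry import FeatureRegistry

        back = FeatureRegistry.from_json(reg.to_json())
        assert back.names == reg.names
        assert back.retained_names == reg.retained_names


class TestTextual:
    @pytest.mark.parametrize("text,words,sentences", [
        ("Il court. Elle dort.", 4, 2),
        ("", 0, 0),
        ("Je… je voulais.", 3, 1),  # "…" excluded from word count
    ])
    def test_counts(self, text, words, sentences):
        f = textual_features(doc(text))
        assert f["words_number"] == words
        assert f["sentence_number"] == sentences


class TestEmotion:
    def _lex(self):
        return LexiconResource("t", {
            ("bien", "positive"): 1.0, ("mort", "negative"): 1.0,
        }, match_policy="surface")

    def test_unweighted_category_rates(self):
        d = doc("mort mort bien")
        from ptsdlang.features.emotion import _iter_matches

        lex = self._lex()
        assert sum(_iter_matches(d, lex, "positive")) == 1.0
        assert sum(_iter_matches(d, lex, "negative")) == 2.0

    def test_weighted_happiness_mean(self):
        lex = LexiconResource("h", {
            ("bien", "labmt_happiness"): 7.0, ("mort", "labmt_happiness"): 2.0,
        }, match_policy="surface")
        f = emotion_features(doc("mort mort bien"), [lex])
        assert f["labmt_happiness"] == pytest.approx((2 + 2 + 7) / 3)

    def test_empty_document_sentinels(self):
        f = emotion_features(doc(""), [self._lex()])
        assert all(v == 0.0 for v in f.values())


class TestLexicalFields:
    def test_body_rate(self):
        lex = LexiconResource("b", {("sang", "BODY"): 1.0},
                              match_policy="surface")
        tagger = LexiconFieldTagger(lexicons=[lex])
        f = lexical_field_rates(doc("le sang coulait"), tagger)
        assert f["model_body"] == pytest.approx(1 / 3)

    def test_no_matches_zero(self):
        tagger = LexiconFieldTagger(lexicons=[])
        f = lexical_field_rates(doc("rien du tout"), tagger)
        assert set(f.values()) == {0.0}

    def test_context_override_behind(self):
        # "derrière" after a determiner is a body word; as a spatial
        # preposition it is not tagged
        lex = LexiconResource("b", {("derrière", "BODY"): 1.0},
                              match_policy="surface")
        tagger = LexiconFieldTagger(lexicons=[lex])
        spatial = lexical_field_rates(doc("ils sont venus de derrière"), tagger)
        body = lexical_field_rates(doc("le derrière"), tagger)
        assert spatial["model_body"] == 0.0
        assert body["model_body"] > 0.0


class TestMorpho:
    def test_present_proportion_among_finite_verbs(self):
        f = morphosyntactic_features(doc("Je cours. Je courais."))
        assert f["verb_present"] == pytest.approx(0.5)
        assert f["verb_past"] == pytest.approx(0.5)

    @pytest.mark.parametrize("text,value", [
        ("On est entré au Bataclan à 20h45", "on_we"),
        ("On m'a marché dessus", "on_someone"),
        ("on n'est jamais mieux servi que par soi même", "on_generic"),
    ])
    def test_on_pronoun_values(self, text, value):
        f = morphosyntactic_features(doc(text))
        assert f[value] == pytest.approx(1.0)

    def test_zero_verbs_gives_tense_sentinel(self):
        f = morphosyntactic_features(doc("le chat"))
        assert f["verb_present"] == 0.0
        assert f["verb_past"] == 0.0

    def test_proportions_in_unit_interval(self, small_docs):
        for d in small_docs[:10]:
            f = morphosyntactic_features(d)
            for name, v in f.items():
                assert 0.0 <= v <= 1.0, name


class TestPassive:
    def test_agented_periphrastic_passive(self):
        f = passive_voice_features(doc("Il a été blessé par une balle."))
        assert f["passive_count"] == 1
        assert f["passive_agented_count"] == 1

    def test_motion_verb_compound_past_is_not_passive(self):
        f = passive_voice_features(doc("Elle est partie."))
        assert f["passive_count"] == 0

    def test_agentless_passive(self):
        f = passive_voice_features(doc("Il a été blessé."))
        assert f["passive_count"] == 1
        assert f["passive_agentless_count"] == 1

    def test_empty_document(self):
        f = passive_voice_features(doc(""))
        assert set(f.values()) == {0.0}


class TestDisfluency:
    def test_worked_example_rates(self):
        f = disfluency_features(doc("je… je voulais euh par… partir"))
        assert f["filler_rate"] == pytest.approx(1 / 5)
        assert f["silent_break_after_word_rate"] == pytest.approx(2 / 5)
        assert f["word_repetition_rate"] == pytest.approx(1 / 5)
        assert f["truncation_rate"] == pytest.approx(1 / 5)

    def test_pure_filler_rate_one(self):
        assert disfluency_features(doc("euh euh"))["filler_rate"] == 1.0

    def test_fluent_text_all_zero(self):
        f = disfluency_features(doc("Il court vite."))
        assert set(f.values()) == {0.0}

    def test_composite_is_sum_of_components(self):
        f = disfluency_features(doc("je… je voulais euh par… partir"))
        parts = [v for k, v in f.items() if k != "score_disfluencies"]
        assert f["score_disfluencies"] == pytest.approx(sum(parts))


class TestReadability:
    def test_type_token_ratio(self):
        f = readability_features(doc("le chat le chat"))
        assert f["token_ratio_score"] == pytest.approx(0.5)

    def test_single_word_boundary(self):
        assert readability_features(doc("chat"))["token_ratio_score"] == 1.0

    def test_words_per_sentence(self):
        f = readability_features(doc("Il court. Elle dort."))
        assert f["words_per_sentence"] == pytest.approx(2.0)


class TestExtractAll:
    def test_shape_and_column_order(self, small_docs, lexicons):
        table = extract_all(small_docs[:10], lexicons)
        reg = default_registry()
        assert table.values.shape == (10, len(reg))
        assert table.names == reg.names

    def test_duplicate_document_identical_rows(self, small_docs, lexicons):
        d = small_docs[0]
        table = extract_all([d, d], lexicons)
        np.testing.assert_array_equal(table.values[0], table.values[1])

    def test_degenerate_one_token_document_no_nan(self, lexicons):
        d = tokenize(Transcript("tiny", "mort"))
        table = extract_all([d], lexicons)
        assert np.isfinite(table.values).all()

    def test_permutation_stability(self, small_docs, lexicons):
        fwd = extract_all(small_docs[:6], lexicons)
        rev = extract_all(small_docs[:6][::-1], lexicons)
        for i, d in enumerate(fwd.doc_ids):
            j = rev.doc_ids.index(d)
            np.testing.assert_array_equal(fwd.values[i], rev.values[j])

    def test_doubling_document_preserves_rates(self, lexicons):
        text = ("je cours dans la rue . il a été blessé par une balle . "
                "on marche toujours euh dans le noir . elle dormait . ")
        single = tokenize(Transcript("x", text))
        double = tokenize(Transcript("x", text + text))
        t1 = extract_all([single], lexicons)
        t2 = extract_all([double], lexicons)
        reg = default_registry()
        for j, name in enumerate(reg.names):
            group = reg.group(name)
            v1, v2 = t1.values[0, j], t2.values[0, j]
            if name in ("words_number", "sentence_number", "passive_count",
                        "passive_agented_count", "passive_agentless_count"):
                assert v2 == pytest.approx(2 * v1)
            elif group in ("disfluency", "lexical", "morphosyntactic") or (
                group == "sentiment_emotion"
            ):
                # rate features are unchanged by self-concatenation
                assert v2 == pytest.approx(v1, abs=1e-9)


class TestReduce:
    def test_reduction_keeps_six_sentiment_and_one_passive(self, small_table):
        reduced = reduce_features(small_table)
        reg = small_table.registry
        groups = [reg.group(n) for n in reduced.names]
        assert groups.count("sentiment_emotion") == 6
        assert [n for n in reduced.names
                if reg.group(n) == "syntactic_passive"] == ["passive_count_norm"]

    def test_reduction_is_idempotent(self, small_table):
        once = reduce_features(small_table)
        twice = reduce_features(once)
        assert twice.names == once.names
        np.testing.assert_array_equal(twice.values, once.values)

    def test_unknown_column_passes_with_warning(self, small_table):
        names = small_table.names + ["mystery"]
        values = np.hstack([small_table.values,
                            np.ones((len(small_table), 1))])
        table = FeatureTable(small_table.doc_ids, values,
                             small_table.registry, names=names)
        with pytest.warns(UserWarning, match="mystery"):
            reduced = reduce_features(table)
        assert "mystery" in reduced.names
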