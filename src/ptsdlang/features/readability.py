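"""Readability / lexical-diversity features.

* ``token_ratio_score`` — type/token ratio over word tokens,
* ``noun_ratio_score`` — noun types / noun tokens,
* ``adverb_ratio_score`` — adverb types / adverb tokens,
* ``words_per_sentence`` — mean words per sentence,
* ``lexical_density`` — content words (nouns, verbs, adjectives, adverbs,
  proper nouns) per word token.

Ratios are in (0, 1] for non-empty documents; empty documents get the zero
sentinel.
"""

from __future__ import annotations

_CONTENT_POS = {"NOUN", "VERB", "ADJ", "ADV", "PROPN"}


def _type_token(tokens) -> float:
    if not tokens:
        return 0.0
    types = {t.surface.lower() for t in tokens}
    return len(types) / len(tokens)


def readability_features(doc) -> dict:
    words = doc.words
    if not words:
        return dict.fromkeys(
            ("token_ratio_score", "noun_ratio_score", "adverb_ratio_score",
             "words_per_sentence", "lexical_density"), 0.0)
    nouns = [t for t in words if t.pos == "NOUN"]
    adverbs = [t for t in words if t.pos == "ADV"]
    n_sent = len(doc.sentences)
    return {
        "token_ratio_score": _type_token(words),
        "noun_ratio_score": _type_token(nouns),
        "adverb_ratio_score": _type_token(adverbs),
        "words_per_sentence": len(words) / n_sent if n_sent else 0.0,
        "lexical_density":
            sum(1 for t in words if t.pos in _CONTENT_POS) / len(words),
    }


def textual_features(doc) -> dict:
    """Word and sentence counts (punctuation, silent breaks and truncated
    fragments excluded from the word count)."""
    return {
        "words_number": float(len(doc.words)),
        "sentence_number": float(len(doc.sentences)),
    }
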