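"""Sentiment/emotion lexicon features and lexical-field rates.

Unweighted lexicons yield per-category rates: matched-token weight summed
and divided by the word count. The valence-weighted happiness lexicon
yields the weighted mean valence of matched tokens (sentinel 0 with a
quality flag when nothing matches). Polarity/subjectivity come from a
pluggable scorer; the default is a lexicon-difference scorer built from the
positive/negative categories available in the loaded resources.
"""

from __future__ import annotations

from dataclasses import dataclass

# registry category name -> lexicon category looked up in the resources
SENTIMENT_CATEGORY_MAP = {
    "liwc_death": "liwc_death",
    "liwc_body": "liwc_body",
    "liwc_positive_emotion": "liwc_positive_emotion",
    "liwc_negative_emotion": "liwc_negative_emotion",
    **{f"ema_{c}": f"ema_{c}" for c in (
        "positive", "negative", "joy", "sadness", "anger", "fear",
        "disgust", "surprise", "guilt", "shame")},
    **{f"feel_{c}": f"feel_{c}" for c in (
        "positive", "joy", "fear", "sadness", "anger", "disgust")},
    **{f"empath_{c}": f"empath_{c}" for c in (
        "fear", "anger", "sadness", "nervousness")},
}

HAPPINESS_CATEGORY = "labmt_happiness"


@dataclass
class LexiconPolarityScorer:
    """Polarity/subjectivity from positive vs negative lexicon hits.

    polarity = (pos − neg) / (pos + neg) ∈ [−1, 1];
    subjectivity = (pos + neg) / words ∈ [0, 1].
    """

    positive_categories: tuple = ("liwc_positive_emotion", "feel_positive",
                                  "ema_positive")
    negative_categories: tuple = ("liwc_negative_emotion", "ema_negative",
                                  "feel_sadness", "feel_anger", "feel_fear")

    def score(self, doc, lexicons) -> tuple[float, float]:
        pos = sum(_category_hits(doc, lexicons, c)
                  for c in self.positive_categories)
        neg = sum(_category_hits(doc, lexicons, c)
                  for c in self.negative_categories)
        n_words = len(doc.words)
        if n_words == 0 or pos + neg == 0:
            return 0.0, 0.0
        return (pos - neg) / (pos + neg), min(1.0, (pos + neg) / n_words)


def _iter_matches(doc, lexicon, category):
    terms = lexicon.terms(category)
    if not terms:
        return
    for tok in doc.words:
        key = (tok.lemma if lexicon.match_policy == "lemma" else tok.surface).lower()
        if key in terms:
            yield terms[key]
        elif tok.surface.lower() in terms:
            yield terms[tok.surface.lower()]


def _category_hits(doc, lexicons, category) -> int:
    return sum(1 for lex in lexicons for _ in _iter_matches(doc, lex, category))


def emotion_features(doc, lexicons, scorer=None) -> dict:
    """All 27 sentiment/emotion features for one document."""
    scorer = scorer or LexiconPolarityScorer()
    n_words = len(doc.words)
    out: dict = {}
    for feat, cat in SENTIMENT_CATEGORY_MAP.items():
        if n_words == 0:
            out[feat] = 0.0
            continue
        weight_sum = sum(w for lex in lexicons
                         for w in _iter_matches(doc, lex, cat))
        out[feat] = weight_sum / n_words

    # weighted-average happiness over matched tokens
    weights = [w for lex in lexicons
               for w in _iter_matches(doc, lex, HAPPINESS_CATEGORY)]
    out["labmt_happiness"] = sum(weights) / len(weights) if weights else 0.0

    polarity, subjectivity = scorer.score(doc, lexicons)
    out["textblob_polarity"] = polarity
    out["textblob_subjectivity"] = subjectivity
    return out


def lexical_field_rates(doc, tagger) -> dict:
    """Rates of the semantic-field categories from the pluggable tagger.

    The tagger (default: lexicon/rule) returns token spans per category;
    context-sensitive taggers may override naive lexicon matches.
    """
    n_words = len(doc.words)
    counts = {"DEATH": 0, "BODY": 0, "PHYSICAL_SENSATIONS": 0, "PERCEPTION": 0}
    if n_words:
        for (start, end), cat in tagger.tag(doc.tokens):
            if cat in counts:
                counts[cat] += end - start
    return {
        "model_death": counts["DEATH"] / n_words if n_words else 0.0,
        "model_body": counts["BODY"] / n_words if n_words else 0.0,
        "model_physical_sensations":
            counts["PHYSICAL_SENSATIONS"] / n_words if n_words else 0.0,
        "model_perception": counts["PERCEPTION"] / n_words if n_words else 0.0,
    }
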