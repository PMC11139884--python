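"""Morphosyntactic features: pronoun persons, tenses, and the contextual
values of the present tense and of the pronoun "on".

Pronoun-person and word-class features are proportions of word tokens;
tense features are proportions of finite verbs; "on"-value features are
proportions of occurrences of "on". Documents with no finite verb (or no
"on") get the zero sentinel for the corresponding features.

Disambiguation rules (deterministic, overridable by a learned tagger that
emits GENERIC_PRESENT / HISTORICAL_PRESENT / ON_* spans):

* present value — *generic* if the sentence carries a genericity cue
  ("toujours", "jamais", "souvent", ...); *historical* if it carries a
  past-time anchor ("hier", "ensuite", a clock time, a past-tense verb in
  the same sentence); otherwise *enunciative* (anchored to the speech
  moment).
* "on" value — *someone* if an object clitic separates "on" from its verb
  ("On m'a marché dessus"); *generic* in sentences with a genericity cue
  ("on n'est jamais mieux servi ..."); otherwise *we* ("On est entré au
  Bataclan à 20h45").
"""

from __future__ import annotations

import re

GENERIC_CUES = frozenset(
    {"toujours", "jamais", "souvent", "généralement", "parfois", "rarement",
     "chaque", "tout", "tous", "toute", "toutes"}
)
PAST_ANCHORS = frozenset(
    {"hier", "ensuite", "puis", "soudain", "après", "avant", "lendemain",
     "veille"}
)
_CLOCK = re.compile(r"^\d{1,2}[hH]\d{0,2}$")

OBJECT_CLITICS = {
    "me", "m'", "m’", "te", "t'", "t’", "nous", "vous",
    "lui", "leur", "l'", "l’", "le", "la", "les",
}

MORPHO_FEATURE_NAMES = (
    "pron_first_sing", "pron_first_plur", "pron_second", "pron_third",
    "pron_rate", "propn_rate",
    "verb_present", "verb_past", "verb_future", "verb_conditional",
    "past_participle_rate", "auxiliary_rate",
    "present_generic", "present_historical", "present_enunciative",
    "on_we", "on_someone", "on_generic",
)


def morphosyntactic_features(doc, tagger=None) -> dict:
    """Compute the 18 morphosyntactic features of a tokenized transcript.

    ``tagger`` may be a TaggerPlugin whose categories include
    GENERIC_PRESENT / HISTORICAL_PRESENT / ON_we / ON_someone / ON_generic;
    its spans then override the deterministic contextual rules.
    """
    out = dict.fromkeys(MORPHO_FEATURE_NAMES, 0.0)
    words = doc.words
    n_words = len(words)
    if n_words == 0:
        return out

    counts = dict.fromkeys(MORPHO_FEATURE_NAMES, 0)
    finite = 0
    on_total = 0

    overrides = _tagger_overrides(doc, tagger)

    for a, b in doc.sentences:
        sent = doc.tokens[a:b]
        sent_value = _present_value_of_sentence(sent)
        for k, tok in enumerate(sent, start=a):
            if not tok.is_word:
                continue
            if tok.pos == "PRON":
                counts["pron_rate"] += 1
                person = tok.morph.get("Person")
                number = tok.morph.get("Number")
                if tok.morph.get("on"):
                    on_total += 1
                    counts[_on_value(sent, k - a, overrides.get(k))] += 1
                elif person == "1":
                    key = "pron_first_sing" if number == "Sing" else "pron_first_plur"
                    counts[key] += 1
                elif person == "2":
                    counts["pron_second"] += 1
                elif person == "3":
                    counts["pron_third"] += 1
            elif tok.pos == "PROPN":
                counts["propn_rate"] += 1
            elif tok.pos in ("VERB", "AUX"):
                if tok.pos == "AUX":
                    counts["auxiliary_rate"] += 1
                form = tok.morph.get("VerbForm")
                if form == "Part":
                    counts["past_participle_rate"] += 1
                elif form == "Fin":
                    finite += 1
                    if tok.morph.get("Mood") == "Cond":
                        counts["verb_conditional"] += 1
                    else:
                        tense = tok.morph.get("Tense", "Pres")
                        if tense == "Pres":
                            counts["verb_present"] += 1
                            value = overrides.get(k) or sent_value
                            counts[f"present_{value}"] += 1
                        elif tense == "Past":
                            counts["verb_past"] += 1
                        elif tense == "Fut":
                            counts["verb_future"] += 1

    for name in ("pron_first_sing", "pron_first_plur", "pron_second",
                 "pron_third", "pron_rate", "propn_rate",
                 "past_participle_rate", "auxiliary_rate"):
        out[name] = counts[name] / n_words
    if finite:
        for name in ("verb_present", "verb_past", "verb_future",
                     "verb_conditional"):
            out[name] = counts[name] / finite
        n_pres = counts["verb_present"]
        if n_pres:
            for v in ("generic", "historical", "enunciative"):
                out[f"present_{v}"] = counts[f"present_{v}"] / n_pres
    if on_total:
        for v in ("we", "someone", "generic"):
            out[f"on_{v}"] = counts[f"on_{v}"] / on_total
    return out


def _tagger_overrides(doc, tagger) -> dict:
    """token index -> override value from a learned tagger, if provided."""
    if tagger is None:
        return {}
    cats = set(getattr(tagger, "categories", ()))
    wanted = {"GENERIC_PRESENT": "generic", "HISTORICAL_PRESENT": "historical",
              "ENUNCIATIVE_PRESENT": "enunciative",
              "ON_we": "on_we", "ON_someone": "on_someone",
              "ON_generic": "on_generic"}
    if not (cats & set(wanted)):
        return {}
    overrides = {}
    for (start, end), cat in tagger.tag(doc.tokens):
        if cat in wanted:
            for k in range(start, end):
                overrides[k] = wanted[cat]
    return overrides


def _sentence_cues(sent) -> tuple[bool, bool]:
    generic = past = False
    for tok in sent:
        low = tok.surface.lower()
        if low in GENERIC_CUES:
            generic = True
        if low in PAST_ANCHORS or _CLOCK.match(tok.surface):
            past = True
        if tok.pos in ("VERB", "AUX") and tok.morph.get("Tense") == "Past" \
                and tok.morph.get("VerbForm") == "Fin":
            past = True
    return generic, past


def _present_value_of_sentence(sent) -> str:
    generic, past = _sentence_cues(sent)
    if generic:
        return "generic"
    if past:
        return "historical"
    return "enunciative"


def _on_value(sent, k: int, override=None) -> str:
    if override in ("on_we", "on_someone", "on_generic"):
        return override
    for tok in sent[k + 1 : k + 3]:
        low = tok.surface.lower()
        if low in OBJECT_CLITICS:
            return "on_someone"
        if tok.pos in ("VERB", "AUX"):
            break
    generic, _past = _sentence_cues(sent)
    if generic:
        return "on_generic"
    return "on_we"
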