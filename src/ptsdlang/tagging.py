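"""Rule-based French annotation backend.

A deterministic tagger built from closed-class word lists and verb-ending
heuristics. It annotates each token with a coarse UPOS tag, a crude lemma
and morphological attributes (tense, mood, verb form, person, number). It is
the default backend for :func:`ptsdlang.corpus_io.tokenize`; a learned
pipeline can be plugged in through the same ``annotate`` interface.

The tagger is intentionally conservative: it is designed so that the
morphosyntactic distinctions the feature registry needs (pronoun person,
finite-verb tense, auxiliary vs lexical "être", past participles, passive
periphrases) are recovered reliably on interview-style French, at the price
of leaving rare forms untagged (they default to NOUN).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

ELLIPSIS = "…"

# --- closed classes --------------------------------------------------------

SUBJECT_PRONOUNS = {
    "je": ("1", "Sing"), "j'": ("1", "Sing"), "j’": ("1", "Sing"),
    "tu": ("2", "Sing"),
    "il": ("3", "Sing"), "elle": ("3", "Sing"),
    "on": ("3", "Sing"),
    "nous": ("1", "Plur"), "vous": ("2", "Plur"),
    "ils": ("3", "Plur"), "elles": ("3", "Plur"),
    "c'": ("3", "Sing"), "c’": ("3", "Sing"), "ce": ("3", "Sing"),
    "ça": ("3", "Sing"), "cela": ("3", "Sing"),
}

CLITIC_PRONOUNS = {
    "me": ("1", "Sing"), "m'": ("1", "Sing"), "m’": ("1", "Sing"),
    "te": ("2", "Sing"), "t'": ("2", "Sing"), "t’": ("2", "Sing"),
    "se": ("3", "Sing"), "s'": ("3", "Sing"), "s’": ("3", "Sing"),
    "moi": ("1", "Sing"), "toi": ("2", "Sing"), "soi": ("3", "Sing"),
    "lui": ("3", "Sing"), "eux": ("3", "Plur"),
    "y": ("3", "Sing"),
}

# object clitics that can sit between "on" and its verb ("On m'a marché dessus")
OBJECT_CLITICS = {
    "me", "m'", "m’", "te", "t'", "t’", "nous", "vous",
    "lui", "leur", "l'", "l’", "le", "la", "les", "se", "s'", "s’", "en", "y",
}

DETERMINERS = {
    "le", "la", "les", "l'", "l’", "un", "une", "des", "du", "au", "aux",
    "ce", "cet", "cette", "ces", "mon", "ma", "mes", "ton", "ta", "tes",
    "son", "sa", "ses", "notre", "nos", "votre", "vos", "leurs",
    "quel", "quelle", "quels", "quelles", "chaque", "quelques", "plusieurs",
    "tout", "toute", "tous", "toutes", "aucun", "aucune",
}

PREPOSITIONS = {
    "à", "a-", "de", "d'", "d’", "en", "dans", "sur", "sous", "par", "pour",
    "avec", "sans", "chez", "vers", "entre", "contre", "depuis", "pendant",
    "avant", "après", "derrière", "devant", "jusque", "jusqu'", "dès",
}

CONJUNCTIONS = {
    "et", "ou", "mais", "donc", "or", "ni", "car",
    "que", "qu'", "qu’", "si", "quand", "comme", "parce", "lorsque",
    "puisque", "quoique",
}

ADVERBS = {
    "ne", "n'", "n’", "pas", "plus", "jamais", "toujours", "souvent",
    "très", "trop", "bien", "mal", "vite", "ici", "là", "hier", "demain",
    "aujourd'hui", "puis", "ensuite", "alors", "enfin", "encore", "déjà",
    "peut-être", "voilà", "bon", "quoi", "vraiment", "même", "aussi",
    "assez", "beaucoup", "peu", "soudain", "maintenant", "dessus", "dessous",
    "généralement", "parfois", "rarement",
}

INTERJECTIONS = {"euh", "ah", "bah", "ben", "hein", "hum", "oh", "eh", "mmh", "hmm"}

_ETRE = {
    "suis": "Pres", "es": "Pres", "est": "Pres", "sommes": "Pres",
    "êtes": "Pres", "sont": "Pres",
    "étais": "Imp", "était": "Imp", "étions": "Imp", "étiez": "Imp",
    "étaient": "Imp",
    "fus": "PS", "fut": "PS", "fûmes": "PS", "fûtes": "PS", "furent": "PS",
    "serai": "Fut", "seras": "Fut", "sera": "Fut", "serons": "Fut",
    "serez": "Fut", "seront": "Fut",
    "serais": "Cond", "serait": "Cond", "serions": "Cond", "seriez": "Cond",
    "seraient": "Cond",
    "sois": "Pres", "soit": "Pres", "soyons": "Pres", "soyez": "Pres",
    "soient": "Pres",
    "être": "Inf", "été": "Part",
}

_AVOIR = {
    "ai": "Pres", "as": "Pres", "a": "Pres", "avons": "Pres", "avez": "Pres",
    "ont": "Pres",
    "avais": "Imp", "avait": "Imp", "avions": "Imp", "aviez": "Imp",
    "avaient": "Imp",
    "eus": "PS", "eut": "PS", "eurent": "PS",
    "aurai": "Fut", "auras": "Fut", "aura": "Fut", "aurons": "Fut",
    "aurez": "Fut", "auront": "Fut",
    "aurais": "Cond", "aurait": "Cond", "aurions": "Cond", "auriez": "Cond",
    "auraient": "Cond",
    "avoir": "Inf", "eu": "Part", "eue": "Part", "eues": "Part",
}

# participles of intransitive motion/state verbs: "être + participle" is a
# compound past ("Elle est partie"), never a passive
MOTION_STATE_PARTICIPLES = {
    "allé", "venu", "parti", "arrivé", "resté", "devenu", "tombé",
    "retourné", "rentré", "entré", "sorti", "monté", "descendu", "passé",
    "né", "mort", "décédé", "apparu", "demeuré", "revenu", "parvenu",
}

_PP_ER = re.compile(r"[a-zà-ÿ]{2,}(é|ée|és|ées)$")
_PP_OTHER = re.compile(r"[a-zà-ÿ]{2,}(i|ie|is|ies|u|ue|us|ues|it|ite|its|ites)$")
_FUT = re.compile(r"[a-zà-ÿ]{2,}(rai|ras|ra|rons|rez|ront)$")
_COND = re.compile(r"[a-zà-ÿ]{2,}(?:er|ir|rr)(?:ais|ait|ions|iez|aient)$")
_IMP = re.compile(r"[a-zà-ÿ]{2,}(ais|ait|ions|iez|aient)$")
_INF = re.compile(r"[a-zà-ÿ]{2,}(er|ir)$")


def pp_lemma(surface: str) -> str:
    """Normalise a past participle to masculine singular ('parties' → 'parti')."""
    s = surface.lower()
    for suf in ("ées", "és", "ée", "ies", "ie", "ues", "ue", "ites", "ite", "es"):
        if s.endswith(suf):
            return s[: -len(suf)] + suf[0].replace("e", "")  # keep class vowel
    if s.endswith("s") and len(s) > 3:
        return s[:-1]
    if s.endswith("e") and len(s) > 3 and not s.endswith(("re", "le", "ne")):
        return s[:-1]
    return s


@dataclass
class RuleTagger:
    """Closed-class + ending-heuristic POS/lemma/morph annotator.

    ``annotate(surface, i, stream)`` receives the raw token stream
    ``[(surface, start, end), ...]`` so that contextual rules (participle
    after auxiliary, verb after subject clitic chain) can look around.
    """

    extra_verb_lemmas: frozenset = frozenset()

    def annotate(self, surface: str, i: int, stream) -> tuple[str, str, dict]:
        low = surface.lower()
        if surface == ELLIPSIS:
            return surface, "PUNCT", {"silent_break": True}
        if len(surface) == 1 and not surface.isalnum():
            return surface, "PUNCT", {}
        if surface.isdigit() or re.fullmatch(r"\d+[hH]\d*", surface):
            return low, "NUM", {}
        if low in INTERJECTIONS:
            return low, "INTJ", {}
        if low in SUBJECT_PRONOUNS:
            person, number = SUBJECT_PRONOUNS[low]
            morph = {"Person": person, "Number": number, "PronType": "Subj"}
            if low == "on":
                morph["on"] = True
            return low, "PRON", morph
        if low in CLITIC_PRONOUNS and not self._is_determiner_use(low, i, stream):
            person, number = CLITIC_PRONOUNS[low]
            return low, "PRON", {"Person": person, "Number": number,
                                 "PronType": "Clitic"}
        if low in _ETRE:
            return "être", "AUX", self._aux_morph(_ETRE[low])
        if low in _AVOIR:
            return "avoir", "AUX", self._aux_morph(_AVOIR[low])
        if low in DETERMINERS:
            return low, "DET", {}
        if low in PREPOSITIONS:
            return low, "ADP", {}
        if low in CONJUNCTIONS:
            return low, "CCONJ" if low in {"et", "ou", "mais", "donc", "or",
                                           "ni", "car"} else "SCONJ", {}
        if low in ADVERBS or low.endswith("ment") and len(low) > 5:
            return low, "ADV", {}
        return self._open_class(surface, low, i, stream)

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _aux_morph(code: str) -> dict:
        if code == "Inf":
            return {"VerbForm": "Inf"}
        if code == "Part":
            return {"VerbForm": "Part", "Tense": "Past"}
        tense = {"Pres": "Pres", "Imp": "Past", "PS": "Past",
                 "Fut": "Fut", "Cond": "Pres"}[code]
        morph = {"VerbForm": "Fin", "Tense": tense}
        if code == "Cond":
            morph["Mood"] = "Cond"
        return morph

    @staticmethod
    def _is_determiner_use(low: str, i: int, stream) -> bool:
        # "le/la/les" handled in DETERMINERS; clitic list has no overlap left
        return False

    def _prev_words(self, i: int, stream, n: int = 3) -> list[str]:
        out = []
        j = i - 1
        while j >= 0 and len(out) < n:
            s = stream[j][0]
            if s != ELLIPSIS and not (len(s) == 1 and not s.isalnum()):
                out.append(s.lower())
            j -= 1
        return out

    def _after_subject_chain(self, i: int, stream) -> bool:
        """True if a subject pronoun leads to this position through clitics,
        negation and adverbs only ('je ne le lui ai ...')."""
        hops = 0
        j = i - 1
        while j >= 0 and hops < 4:
            s = stream[j][0].lower()
            if s == ELLIPSIS or (len(s) == 1 and not s.isalnum()):
                return False
            if s in SUBJECT_PRONOUNS:
                return True
            if s in OBJECT_CLITICS or s in {"ne", "n'", "n’", "pas"} or s in ADVERBS:
                j -= 1
                hops += 1
                continue
            return False
        return False

    def _after_aux(self, i: int, stream, window: int = 3) -> bool:
        for s in self._prev_words(i, stream, window):
            if s in _ETRE or s in _AVOIR:
                return True
            if s in OBJECT_CLITICS or s in {"ne", "n'", "n’", "pas"} or s in ADVERBS:
                continue
            return False
        return False

    def _open_class(self, surface: str, low: str, i: int, stream):
        # past participle in compound-tense / passive position
        if (_PP_ER.match(low) or _PP_OTHER.match(low)) and self._after_aux(i, stream):
            lemma = pp_lemma(low)
            return lemma, "VERB", {"VerbForm": "Part", "Tense": "Past"}
        if _PP_ER.match(low) and not self._after_subject_chain(i, stream):
            # bare -é form outside a verb chain: participle/adjective
            return pp_lemma(low), "VERB", {"VerbForm": "Part", "Tense": "Past"}
        verbal = self._after_subject_chain(i, stream) or low in self.extra_verb_lemmas
        if verbal:
            if _COND.fullmatch(low):
                return low, "VERB", {"VerbForm": "Fin", "Tense": "Pres",
                                     "Mood": "Cond"}
            if _FUT.fullmatch(low):
                return low, "VERB", {"VerbForm": "Fin", "Tense": "Fut"}
            if _IMP.fullmatch(low):
                return low, "VERB", {"VerbForm": "Fin", "Tense": "Past"}
            if _INF.fullmatch(low):
                return low, "VERB", {"VerbForm": "Inf"}
            return self._present(low)
        if _INF.fullmatch(low) and self._prev_words(i, stream, 1)[:1] in (
            [w] for w in ("pour", "de", "d'", "d’", "à", "sans", "va", "vais",
                          "vas", "vont", "allons", "allez", "veux", "veut",
                          "voulais", "voulait", "peux", "peut", "pouvait",
                          "dois", "doit", "devait", "faut")
        ):
            return low, "VERB", {"VerbForm": "Inf"}
        # capitalised mid-sentence → proper noun
        if surface[:1].isupper() and not self._sentence_initial(i, stream):
            return surface, "PROPN", {}
        return self._noun_lemma(low), "NOUN", {}

    @staticmethod
    def _present(low: str):
        lemma = low
        for suf in ("ent", "ons", "ez", "es", "e"):
            if low.endswith(suf) and len(low) - len(suf) >= 2:
                lemma = low[: -len(suf)] + "er"
                break
        return lemma, "VERB", {"VerbForm": "Fin", "Tense": "Pres"}

    @staticmethod
    def _sentence_initial(i: int, stream) -> bool:
        j = i - 1
        while j >= 0:
            s = stream[j][0]
            if s in {".", "!", "?"}:
                return True
            if s == ELLIPSIS or (len(s) == 1 and not s.isalnum()):
                j -= 1
                continue
            return False
        return True

    @staticmethod
    def _noun_lemma(low: str) -> str:
        if low.endswith("s") and len(low) > 3 and not low.endswith("ss"):
            return low[:-1]
        return low


# ---------------------------------------------------------------------------
# lexical-field tagger (TaggerPlugin default implementation)

FIELD_CATEGORIES = ("DEATH", "BODY", "PHYSICAL_SENSATIONS", "PERCEPTION")


@dataclass
class LexiconFieldTagger:
    """Lexicon-backed tagger for the semantic fields of the lexical family.

    Satisfies the TaggerPlugin contract: ``tag(tokens)`` returns
    non-overlapping single-token spans per category. A small table of
    context overrides handles known lexicon traps — e.g. "derrière" is a
    body word only after a determiner ("le derrière"), not as the spatial
    preposition ("de derrière").
    """

    lexicons: list = field(default_factory=list)
    categories: tuple = FIELD_CATEGORIES

    def _index(self):
        idx: dict = {}
        for lex in self.lexicons:
            for (term, cat), _w in lex.entries.items():
                if cat.upper() in self.categories:
                    idx.setdefault(cat.upper(), {})[term] = lex.match_policy
        return idx

    def tag(self, tokens: Sequence) -> list:
        idx = self._index()
        out = []
        for i, tok in enumerate(tokens):
            if not tok.is_word:
                continue
            for cat, terms in idx.items():
                policy = terms.get(tok.lemma.lower()) or terms.get(
                    tok.surface.lower()
                )
                if policy is None:
                    continue
                if tok.surface.lower() == "derrière":
                    prev = tokens[i - 1] if i > 0 else None
                    if prev is None or prev.pos != "DET":
                        continue  # spatial use, not the body sense
                out.append(((i, i + 1), cat))
        return out
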