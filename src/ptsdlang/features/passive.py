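"""French periphrastic passive detection.

Rule: a form of the auxiliary "être" (finite in any tense, infinitive, or
the participle "été" inside a compound tense) followed by a past participle
of a transitive-capable verb, allowing at most three interveners drawn from
adverbs, negation and clitics. "être + participle" with an intransitive
motion/state participle ("Elle est partie") is a compound past, not a
passive, and is excluded by lemma list. An agent phrase introduced by
"par" (or "de") directly after the participle marks the passive as agented.

The passive is read here as a marker of reduced agency in trauma
narratives; counts are reported raw and normalised by document length.
"""

from __future__ import annotations

from ..tagging import MOTION_STATE_PARTICIPLES

_WINDOW = 3  # max interveners between auxiliary and participle
_SKIPPABLE = {"ADV", "PRON", "INTJ"}
_AGENT_MARKERS = {"par", "de", "d'", "d’"}


def passive_voice_features(doc) -> dict:
    tokens = doc.tokens
    passive = agented = 0
    for i, tok in enumerate(tokens):
        if not _is_etre_aux(tok):
            continue
        j = _find_participle(tokens, i + 1)
        if j is None:
            continue
        part = tokens[j]
        if part.lemma.lower() in MOTION_STATE_PARTICIPLES:
            continue
        if part.lemma.lower() in ("été",):  # être's own participle
            continue
        passive += 1
        if _has_agent(tokens, j + 1):
            agented += 1
    n_words = len(doc.words)
    return {
        "passive_count": float(passive),
        "passive_count_norm": passive / n_words if n_words else 0.0,
        "passive_agented_count": float(agented),
        "passive_agentless_count": float(passive - agented),
    }


def _is_etre_aux(tok) -> bool:
    return tok.pos == "AUX" and tok.lemma == "être"


def _find_participle(tokens, start: int):
    hops = 0
    for j in range(start, len(tokens)):
        tok = tokens[j]
        if tok.pos == "PUNCT":
            return None
        if tok.morph.get("VerbForm") == "Part" and tok.pos in ("VERB", "AUX"):
            if tok.lemma == "être":
                return None
            return j
        if tok.pos in _SKIPPABLE or tok.surface.lower() in ("ne", "n'", "n’", "pas"):
            hops += 1
            if hops > _WINDOW:
                return None
            continue
        return None
    return None


def _has_agent(tokens, start: int) -> bool:
    for tok in tokens[start : start + 2]:
        if tok.pos == "PUNCT":
            return False
        if tok.surface.lower() in _AGENT_MARKERS:
            return True
    return False
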