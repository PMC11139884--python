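"""Speech-disfluency features recovered from transcription marks.

Nine features, each a count divided by the number of word tokens:

* ``filler_rate`` — filler interjections ("euh", "ah", "bah", ...),
* ``hesitation_rate`` — pure hesitation markers ("euh", "hum", "mmh"),
* ``syllable_repetition_rate`` — a repeated fragment restarting a word
  ("pa pa partir"),
* ``word_repetition_rate`` — immediate repetition of the same word, looking
  across silent breaks ("je… je"),
* ``truncation_rate`` — false starts: a truncated fragment glued to "…" and
  restarted by the following word ("par… partir"),
* ``silent_break_after_word_rate`` / ``silent_break_between_words_rate`` —
  "…" attached to the preceding word vs free-standing,
* ``generic_connector_rate`` — generic discourse connectors ("donc",
  "alors", "voilà", ...),
* ``score_disfluencies`` — sum of the component rates (composite).
"""

from __future__ import annotations

from ..tagging import ELLIPSIS

DEFAULT_FILLERS = frozenset({"euh", "ah", "bah", "ben", "hein", "hum"})
HESITATION_MARKERS = frozenset({"euh", "hum", "mmh", "hmm"})
GENERIC_CONNECTORS = frozenset(
    {"donc", "alors", "voilà", "enfin", "bon", "quoi", "puis", "bref"}
)

_COMPONENTS = (
    "filler_rate", "syllable_repetition_rate", "word_repetition_rate",
    "truncation_rate", "silent_break_after_word_rate",
    "silent_break_between_words_rate", "generic_connector_rate",
    "hesitation_rate",
)


def disfluency_features(doc, filler_list=DEFAULT_FILLERS) -> dict:
    tokens = doc.tokens
    text = doc.transcript.raw_text
    n_words = len(doc.words)

    counts = dict.fromkeys(_COMPONENTS, 0)
    for i, tok in enumerate(tokens):
        low = tok.surface.lower()
        if tok.surface == ELLIPSIS:
            prev = tokens[i - 1] if i > 0 else None
            attached = (
                prev is not None
                and prev.pos != "PUNCT"
                and prev.span[1] == tok.span[0]
            )
            if attached:
                counts["silent_break_after_word_rate"] += 1
            else:
                counts["silent_break_between_words_rate"] += 1
            continue
        if tok.pos == "PUNCT":
            continue
        if tok.morph.get("truncated"):
            counts["truncation_rate"] += 1
            continue
        if low in filler_list:
            counts["filler_rate"] += 1
        if low in HESITATION_MARKERS:
            counts["hesitation_rate"] += 1
        if low in GENERIC_CONNECTORS:
            counts["generic_connector_rate"] += 1
        nxt = _next_content(tokens, i + 1)
        if nxt is not None:
            if nxt.surface.lower() == low:
                counts["word_repetition_rate"] += 1
            elif (
                len(low) < len(nxt.surface)
                and nxt.surface.lower().startswith(low)
                and not tok.morph.get("truncated")
                and len(low) <= 3
                and _next_content(tokens, i + 1, skip=1) is not None
            ):
                # repeated-syllable restart: short fragment that the next
                # word extends, without the "…" truncation mark
                counts["syllable_repetition_rate"] += 1

    if n_words == 0:
        return {**dict.fromkeys(_COMPONENTS, 0.0), "score_disfluencies": 0.0}
    rates = {k: v / n_words for k, v in counts.items()}
    rates["score_disfluencies"] = sum(rates.values())
    return rates


def _next_content(tokens, i, skip: int = 0):
    """Next non-punctuation, non-ellipsis token, optionally skipping some."""
    found = 0
    for tok in tokens[i:]:
        if tok.surface == ELLIPSIS or tok.pos == "PUNCT":
            continue
        if found == skip:
            return tok
        found += 1
    return None
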