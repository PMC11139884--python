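"""Feature registry: the named, grouped definitions of the language features.

The registry fixes the identity, order, grouping and normalisation of every
language feature, and which features survive the collinearity reduction used
for the classification protocol (sentiment family reduced to the six
valence-based scores; passive family reduced to the normalised passive
count). Group sizes are pinned: textual 2, sentiment/emotion 27, lexical 4,
morphosyntactic 18, passive 4, disfluency 9, readability 5, graph 12 —
81 features in total, 57 retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

GROUPS = (
    "textual",
    "sentiment_emotion",
    "lexical",
    "morphosyntactic",
    "syntactic_passive",
    "disfluency",
    "readability",
    "graph",
)

GROUP_SIZES = {
    "textual": 2,
    "sentiment_emotion": 27,
    "lexical": 4,
    "morphosyntactic": 18,
    "syntactic_passive": 4,
    "disfluency": 9,
    "readability": 5,
    "graph": 12,
}


@dataclass(frozen=True)
class FeatureDef:
    name: str
    group: str
    normalization: str = "none"  # none | per_token | per_sentence | per_verb | per_pronoun
    retained_for_ml: bool = True


# The six sentiment scores kept for classification are the valence-based
# ones: the two polarity/subjectivity scores, the positive-emotion lexicon
# rate, the happiness score, and the two positive/negative emotion rates.
RETAINED_SENTIMENT = (
    "textblob_polarity",
    "textblob_subjectivity",
    "feel_positive",
    "labmt_happiness",
    "liwc_positive_emotion",
    "liwc_negative_emotion",
)

SENTIMENT_FEATURES = (
    # LIWC-style category rates (4)
    "liwc_death", "liwc_body", "liwc_positive_emotion", "liwc_negative_emotion",
    # EMA-style emotion-category rates (10)
    "ema_positive", "ema_negative", "ema_joy", "ema_sadness", "ema_anger",
    "ema_fear", "ema_disgust", "ema_surprise", "ema_guilt", "ema_shame",
    # FEEL-style rates (6)
    "feel_positive", "feel_joy", "feel_fear", "feel_sadness", "feel_anger",
    "feel_disgust",
    # valence-weighted happiness score (1)
    "labmt_happiness",
    # polarity / subjectivity from the pluggable scorer (2)
    "textblob_polarity", "textblob_subjectivity",
    # EMPATH-style emotion categories (4)
    "empath_fear", "empath_anger", "empath_sadness", "empath_nervousness",
)

LEXICAL_FEATURES = (
    "model_death", "model_body", "model_physical_sensations", "model_perception",
)

MORPHO_FEATURES = (
    "pron_first_sing", "pron_first_plur", "pron_second", "pron_third",
    "pron_rate", "propn_rate",
    "verb_present", "verb_past", "verb_future", "verb_conditional",
    "past_participle_rate", "auxiliary_rate",
    "present_generic", "present_historical", "present_enunciative",
    "on_we", "on_someone", "on_generic",
)

PASSIVE_FEATURES = (
    "passive_count", "passive_count_norm",
    "passive_agented_count", "passive_agentless_count",
)

DISFLUENCY_FEATURES = (
    "filler_rate", "syllable_repetition_rate", "word_repetition_rate",
    "truncation_rate", "silent_break_after_word_rate",
    "silent_break_between_words_rate", "score_disfluencies",
    "generic_connector_rate", "hesitation_rate",
)

READABILITY_FEATURES = (
    "token_ratio_score", "noun_ratio_score", "adverb_ratio_score",
    "words_per_sentence", "lexical_density",
)

GRAPH_FEATURES = (
    "graph_l1", "graph_l2", "graph_l3", "graph_pe",
    "graph_degree_average", "graph_degree_std",
    "graph_average_clustering", "graph_average_shortest_path",
    "graph_transitivity", "graph_n_nodes", "graph_n_edges",
    "graph_lcc_size",
)


def default_registry() -> "FeatureRegistry":
    defs: list[FeatureDef] = [
        FeatureDef("words_number", "textual"),
        FeatureDef("sentence_number", "textual"),
    ]
    for n in SENTIMENT_FEATURES:
        norm = "none" if n in ("labmt_happiness", "textblob_polarity",
                               "textblob_subjectivity") else "per_token"
        defs.append(FeatureDef(n, "sentiment_emotion", norm,
                               retained_for_ml=n in RETAINED_SENTIMENT))
    defs += [FeatureDef(n, "lexical", "per_token") for n in LEXICAL_FEATURES]
    for n in MORPHO_FEATURES:
        if n.startswith("verb_"):
            norm = "per_verb"
        elif n.startswith("on_"):
            norm = "per_pronoun"
        else:
            norm = "per_token"
        defs.append(FeatureDef(n, "morphosyntactic", norm))
    for n in PASSIVE_FEATURES:
        defs.append(FeatureDef(
            n, "syntactic_passive",
            "per_token" if n == "passive_count_norm" else "none",
            retained_for_ml=(n == "passive_count_norm"),
        ))
    defs += [FeatureDef(n, "disfluency", "per_token") for n in DISFLUENCY_FEATURES]
    defs += [FeatureDef(n, "readability") for n in READABILITY_FEATURES]
    defs += [FeatureDef(n, "graph") for n in GRAPH_FEATURES]
    return FeatureRegistry(defs)


class FeatureRegistry:
    """Ordered collection of feature definitions."""

    def __init__(self, defs: Iterable[FeatureDef]):
        self.defs = list(defs)
        names = [d.name for d in self.defs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        bad = {d.group for d in self.defs} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups {bad}")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    @property
    def retained_names(self) -> list[str]:
        return [d.name for d in self.defs if d.retained_for_ml]

    def group(self, name: str) -> str:
        return self._by_name()[name].group

    def _by_name(self) -> dict:
        return {d.name: d for d in self.defs}

    def group_sizes(self) -> dict:
        sizes: dict = {}
        for d in self.defs:
            sizes[d.group] = sizes.get(d.group, 0) + 1
        return sizes

    def __len__(self) -> int:
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)

    def to_json(self) -> str:
        return json.dumps(
            [d.__dict__ for d in self.defs], ensure_ascii=False, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureRegistry":
        return cls([FeatureDef(**d) for d in json.loads(text)])


class FeatureTable:
    """Document × feature matrix with registry metadata.

    Thin wrapper over a pandas DataFrame (rows indexed by doc_id, columns in
    registry order) keeping the registry alongside the values.
    """

    def __init__(self, doc_ids, values, registry: FeatureRegistry,
                 names: list[str] | None = None):
        self.registry = registry
        self.names = list(names) if names is not None else registry.names
        self.doc_ids = list(doc_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.doc_ids), len(self.names)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.doc_ids)} docs × {len(self.names)} features"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.doc_ids, name="doc_id"),
                            columns=self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, registry: FeatureRegistry):
        return cls(df.index.tolist(), df.to_numpy(dtype=float), registry,
                   names=df.columns.tolist())

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def __len__(self) -> int:
        return len(self.doc_ids)
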