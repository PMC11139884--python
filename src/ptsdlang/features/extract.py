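"""Full feature extraction: one row per document, registry column order."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..registry import FeatureRegistry, FeatureTable, default_registry
from ..tagging import LexiconFieldTagger
from .disfluency import DEFAULT_FILLERS, disfluency_features
from .emotion import emotion_features, lexical_field_rates
from .graph import GraphConfig, speech_graph_features
from .morpho import morphosyntactic_features
from .passive import passive_voice_features
from .readability import readability_features, textual_features


@dataclass
class ExtractionConfig:
    graph: GraphConfig = field(default_factory=GraphConfig)
    fillers: frozenset = DEFAULT_FILLERS


def extract_features(doc, lexicons, field_tagger=None, scorer=None,
                     config: ExtractionConfig | None = None) -> dict:
    """All registered features for one tokenized transcript."""
    config = config or ExtractionConfig()
    if field_tagger is None:
        field_tagger = LexiconFieldTagger(lexicons=list(lexicons))
    row: dict = {}
    row.update(textual_features(doc))
    row.update(emotion_features(doc, lexicons, scorer))
    row.update(lexical_field_rates(doc, field_tagger))
    row.update(morphosyntactic_features(doc, tagger=field_tagger))
    row.update(passive_voice_features(doc))
    row.update(disfluency_features(doc, config.fillers))
    row.update(readability_features(doc))
    row.update(speech_graph_features(doc, config.graph))
    return row


def extract_all(corpus, lexicons, field_tagger=None, scorer=None,
                registry: FeatureRegistry | None = None,
                config: ExtractionConfig | None = None) -> FeatureTable:
    """Extract the full document × feature matrix for a tokenized corpus.

    Raises if a registered feature is not produced by any extractor (e.g. a
    sentiment category with no loaded lexicon would still yield a 0 rate;
    a truly unknown registry entry is an error naming the feature).
    """
    registry = registry or default_registry()
    rows = []
    doc_ids = []
    for doc in corpus:
        row = extract_features(doc, lexicons, field_tagger, scorer, config)
        missing = [n for n in registry.names if n not in row]
        if missing:
            raise ValueError(f"no extractor produced features: {missing}")
        rows.append([row[n] for n in registry.names])
        doc_ids.append(doc.doc_id)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(registry)))
    return FeatureTable(doc_ids, values, registry)


def reduce_features(table: FeatureTable) -> FeatureTable:
    """Drop the features not retained for classification.

    Keeps the six valence-based sentiment scores and the normalised passive
    count; other families pass through untouched. Idempotent; columns not
    known to the registry are kept with a warning.
    """
    registry = table.registry
    retained = set(registry.retained_names)
    known = set(registry.names)
    keep_idx, keep_names = [], []
    for i, name in enumerate(table.names):
        if name not in known:
            warnings.warn(f"unknown feature column kept: {name}")
            keep_idx.append(i)
            keep_names.append(name)
        elif name in retained:
            keep_idx.append(i)
            keep_names.append(name)
    return FeatureTable(table.doc_ids, table.values[:, keep_idx], registry,
                        names=keep_names)
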