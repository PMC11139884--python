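"""Sequence-dataset construction for the CNN branch.

Fixed-length token-id sequences are cut from documents *after* a
document-level split, so no document contributes sequences to more than one
of train/validation/test (leak-freedom by construction). The vocabulary is
built from the training fold only: the top ``vocab_size − 2`` most frequent
forms, plus PAD (id 0) and UNK (id 1).

K, the number of sequences sampled per document, defaults to
``ceil(Q75 / seq_len)`` where Q75 is the document length at the threshold of
the 25% longest documents. Training sequences are cut at random start
offsets (with replacement when the document is shorter than K·seq_len);
documents shorter than ``seq_len`` are right-padded. Inference uses
exhaustive non-overlapping windows instead (see
:func:`ptsdlang.dl.model.infer_document`).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

PAD_ID = 0
UNK_ID = 1

CHANNELS = ("surface", "lemma", "pos")


@dataclass
class SequenceDatasetConfig:
    seq_len: int = 512
    k_per_doc: int | None = None  # None = auto from the Q75 rule
    vocab_size: int = 2000
    channels: tuple = ("surface",)
    val_frac_of_train: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_len <= 0:
            raise ValueError("seq_len must be positive")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {unknown}")


@dataclass
class Sequence:
    doc_id: str
    label: int
    ids: dict  # channel -> int array of length seq_len
    n_real: int  # non-pad token count


@dataclass
class SequenceDataset:
    train: list
    val: list
    test: list
    vocab: dict  # channel -> {form: id}
    config: SequenceDatasetConfig
    k_per_doc: int = 1

    def assert_leak_free(self) -> None:
        sets = [
            {s.doc_id for s in part} for part in (self.train, self.val, self.test)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise AssertionError(
                        f"documents in more than one fold: {sorted(overlap)[:5]}"
                    )


def channel_stream(doc, channel: str) -> list[str]:
    """Token stream for one input channel (word tokens only)."""
    if channel == "surface":
        return [t.surface.lower() for t in doc.tokens if t.is_word]
    if channel == "lemma":
        return [t.lemma.lower() for t in doc.tokens if t.is_word]
    if channel == "pos":
        return [t.pos for t in doc.tokens if t.is_word]
    raise ValueError(f"unknown channel {channel!r}")


def build_vocab(docs, channel: str, vocab_size: int) -> dict:
    counts: Counter = Counter()
    for doc in docs:
        counts.update(channel_stream(doc, channel))
    most = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    vocab = {"<pad>": PAD_ID, "<unk>": UNK_ID}
    for form, _n in most[: max(0, vocab_size - 2)]:
        vocab[form] = len(vocab)
    return vocab


def encode(stream, vocab, seq_len: int, offset: int) -> np.ndarray:
    ids = np.full(seq_len, PAD_ID, dtype=np.int64)
    window = stream[offset : offset + seq_len]
    for i, form in enumerate(window):
        ids[i] = vocab.get(form, UNK_ID)
    return ids


def auto_k(lengths, seq_len: int) -> int:
    """ceil(Q75 / seq_len): Q75 is the length where the 25% longest start."""
    q75 = float(np.percentile(np.asarray(lengths, float), 75,
                              method="higher"))
    return max(1, math.ceil(q75 / seq_len))


def build_sequence_dataset(corpus, labels, cfg: SequenceDatasetConfig,
                           split) -> SequenceDataset:
    """Cut train/val/test sequence sets from a tokenized corpus.

    ``split`` is the document-level (train_ids, test_ids) pair; a further
    validation fold (20% of the training documents by default) is carved
    out here, still at document level.
    """
    train_ids, test_ids = [list(part) for part in split]
    rng = np.random.default_rng(cfg.seed)
    # validation fold carved per label so both classes are represented
    val_ids: list = []
    tr_ids: list = []
    by_label: dict = {}
    for d in sorted(train_ids):
        by_label.setdefault(labels[d], []).append(d)
    for members in by_label.values():
        order = rng.permutation(len(members))
        n_val = max(1, int(round(len(members) * cfg.val_frac_of_train)))
        val_ids.extend(members[i] for i in order[:n_val])
        tr_ids.extend(members[i] for i in order[n_val:])
    val_ids.sort()
    tr_ids.sort()

    by_id = {doc.doc_id: doc for doc in corpus}
    lengths = [len(channel_stream(by_id[d], "surface")) for d in tr_ids]
    k = cfg.k_per_doc or auto_k(lengths, cfg.seq_len)

    vocab = {
        ch: build_vocab([by_id[d] for d in tr_ids], ch, cfg.vocab_size)
        for ch in cfg.channels
    }

    def cut(doc_ids) -> list:
        out = []
        for d in sorted(doc_ids):
            doc = by_id[d]
            streams = {ch: channel_stream(doc, ch) for ch in cfg.channels}
            n = len(streams[cfg.channels[0]])
            if n == 0:
                warnings.warn(f"document {d} empty after tokenization; skipped")
                continue
            max_off = max(0, n - cfg.seq_len)
            offsets = rng.integers(0, max_off + 1, size=k)
            for off in offsets:
                ids = {ch: encode(streams[ch], vocab[ch], cfg.seq_len, int(off))
                       for ch in cfg.channels}
                out.append(Sequence(d, int(labels[d]), ids,
                                    min(cfg.seq_len, n - int(off))))
        return out

    ds = SequenceDataset(cut(tr_ids), cut(val_ids), cut(test_ids), vocab,
                         cfg, k)
    ds.assert_leak_free()
    return ds


def inference_windows(doc, vocab, cfg: SequenceDatasetConfig) -> list:
    """Exhaustive non-overlapping windows of one document (stride = seq_len)."""
    streams = {ch: channel_stream(doc, ch) for ch in cfg.channels}
    n = len(streams[cfg.channels[0]])
    out = []
    for off in range(0, max(1, n), cfg.seq_len):
        ids = {ch: encode(streams[ch], vocab[ch], cfg.seq_len, off)
               for ch in cfg.channels}
        out.append(Sequence(doc.doc_id, -1, ids, min(cfg.seq_len, n - off)))
        if off + cfg.seq_len >= n:
            break
    return out
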