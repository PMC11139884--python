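"""Deconvolution/CAM saliency over token positions (text deconvolution).

Per-token scores are obtained by weighting the post-ReLU convolution
feature maps with the classifier's output weights (class-activation
weighting) and redistributing them back to input positions through the
transposed convolution kernel. The combination across channels is exposed
as a parameter: per-channel kernel slices give one saliency vector per
input channel, or a single summed vector.

Patterns are maximal token spans whose score exceeds the sequence mean plus
one standard deviation; padding positions are masked out of that
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PAD_ID, Sequence


@dataclass
class SaliencyResult:
    sequence: Sequence
    scores: dict  # channel -> float array of length seq_len
    patterns: list  # [(start, end, score), ...] on the combined scores

    @property
    def combined(self) -> np.ndarray:
        return np.sum(list(self.scores.values()), axis=0)


def tds_saliency(model, sequence: Sequence, combine: str = "per_channel"
                 ) -> SaliencyResult:
    """Per-token deconvolution saliency of one sequence.

    Each active convolution unit's pre-activation is decomposed into the
    exact additive contributions ``W[k, d, h] · x[t, d]`` of the input
    tokens, weighted by the classifier weight of its filter, and summed
    back onto token positions (transposed convolution of the class-weighted
    feature maps).
    """
    ids = {ch: sequence.ids[ch][None, :] for ch in model.channels}
    x = model._embed(ids)[0]  # (L, D_total)
    _, pre = model._conv(x[None])
    pre = pre[0]  # (n_pos, H)
    active = (pre > 0).astype(float) * model.w_out[None, :]  # (n_pos, H)
    k = model.cfg.kernel
    d = model.cfg.embedding_dim
    seq_len = x.shape[0]
    n_pos = pre.shape[0]

    scores: dict = {}
    for c_idx, ch in enumerate(model.channels):
        sl = slice(c_idx * d, (c_idx + 1) * d)
        s = np.zeros(seq_len)
        for kk in range(k):
            # contribution of token (j + kk) through kernel offset kk
            piece = x[kk : kk + n_pos, sl] @ model.W[kk, sl, :]  # (n_pos, H)
            s[kk : kk + n_pos] += (piece * active).sum(axis=1)
        scores[ch] = s
    if combine == "sum":
        total = np.sum(list(scores.values()), axis=0)
        scores = {"combined": total}

    mask = sequence.ids[model.channels[0]] != PAD_ID
    combined = np.sum(list(scores.values()), axis=0)
    patterns = extract_pattern_spans(combined, mask)
    return SaliencyResult(sequence, scores, patterns)


def extract_pattern_spans(scores: np.ndarray, mask: np.ndarray) -> list:
    """Maximal spans with score > mean + 1 SD over non-pad positions."""
    if not mask.any():
        return []
    mu = scores[mask].mean()
    sd = scores[mask].std()
    hot = (scores > mu + sd) & mask
    spans = []
    start = None
    for i, h in enumerate(hot):
        if h and start is None:
            start = i
        elif not h and start is not None:
            spans.append((start, i, float(scores[start:i].mean())))
            start = None
    if start is not None:
        spans.append((start, len(hot), float(scores[start:].mean())))
    spans.sort(key=lambda s: -s[2])
    return spans


def most_representative_sequence(model, sequences) -> Sequence:
    """The sequence with the highest predicted positive-class probability."""
    if not sequences:
        raise ValueError("no sequences given")
    p = model.predict_proba(list(sequences))
    return sequences[int(np.argmax(p))]


def extract_top_patterns(model, sequences, vocab: dict, top_n: int = 10,
                         combine: str = "per_channel") -> list:
    """Top saliency patterns from the most representative positive sequence.

    Returns ``[(doc_id, span_tokens, channel, score), ...]`` sorted by
    descending score, with span token text recovered through the inverse
    vocabulary of the first channel.
    """
    seq = most_representative_sequence(model, list(sequences))
    res = tds_saliency(model, seq, combine=combine)
    ch0 = model.channels[0]
    inv = {i: form for form, i in vocab[ch0].items()}
    out = []
    for start, end, score in res.patterns[:top_n]:
        tokens = [inv.get(int(i), "<unk>") for i in seq.ids[ch0][start:end]]
        out.append((seq.doc_id, " ".join(tokens), ch0, score))
    return out
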