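"""CNN branch: dataset construction, focal loss, training, inference."""

import numpy as np
import pytest

from ptsdlang.corpus_io import Transcript, tokenize
from ptsdlang.dl import (
    CNNConfig,
    PAD_ID,
    Sequence,
    SequenceDatasetConfig,
    TextCNN,
    UNK_ID,
    auto_k,
    build_sequence_dataset,
    focal_loss,
    infer_document,
    inference_windows,
    train_cnn,
)
from ptsdlang.dl.model import _focal_grad_logit, load_model, save_model


def _mini_corpus(n=12, length=200, seed=0):
    rng = np.random.default_rng(seed)
    vocab = [f"mot{chr(97 + i // 6)}{chr(97 + i % 6)}" for i in range(40)]
    docs, labels = [], {}
    for i in range(n):
        words = [vocab[rng.integers(40)] for _ in range(length)]
        label = i % 2
        if label:
            for j in rng.integers(length, size=max(8, length // 10)):
                words[j] = "marqueur"
        doc_id = f"d{i:02d}"
        docs.append(tokenize(Transcript(doc_id, " ".join(words) + " .")))
        labels[doc_id] = label
    return docs, labels


class TestDatasetConstruction:
    def test_auto_k_from_upper_quartile(self):
        # documents at the 25%-longest threshold of 1024 tokens, seq_len 512
        lengths = [100] * 75 + [1024] * 25
        assert auto_k(lengths, 512) == 2

    def test_document_level_leak_freedom(self):
        docs, labels = _mini_corpus()
        ids = [d.doc_id for d in docs]
        ds = build_sequence_dataset(
            docs, labels, SequenceDatasetConfig(seq_len=64, vocab_size=100,
                                                seed=1),
            (ids[:9], ids[9:]))
        ds.assert_leak_free()
        assert {s.doc_id for s in ds.test} == set(ids[9:])

    def test_oov_maps_to_unk_and_short_docs_pad(self):
        docs, labels = _mini_corpus(n=6, length=30)
        ids = [d.doc_id for d in docs]
        ds = build_sequence_dataset(
            docs, labels,
            SequenceDatasetConfig(seq_len=64, vocab_size=10, seed=0),
            (ids[:4], ids[4:]))
        seq = ds.train[0]
        assert (seq.ids["surface"] == PAD_ID).sum() > 0  # padded
        assert any((s.ids["surface"] == UNK_ID).any() for s in ds.train)

    def test_every_sequence_inherits_document_label(self):
        docs, labels = _mini_corpus()
        ids = [d.doc_id for d in docs]
        ds = build_sequence_dataset(
            docs, labels, SequenceDatasetConfig(seq_len=64, vocab_size=100,
                                                seed=2),
            (ids[:9], ids[9:]))
        for part in (ds.train, ds.val, ds.test):
            for s in part:
                assert s.label == labels[s.doc_id]


class TestFocalLoss:
    def test_certain_prediction_zero_loss(self):
        assert focal_loss(1.0, 1) == pytest.approx(0.0, abs=1e-10)

    def test_gamma_zero_is_alpha_weighted_cross_entropy(self):
        p = np.linspace(0.01, 0.99, 197)
        for y in (0, 1):
            fl = focal_loss(p, np.full_like(p, y), alpha=0.5, gamma=0.0)
            pt = p if y == 1 else 1 - p
            np.testing.assert_allclose(fl, 0.5 * (-np.log(pt)), rtol=0,
                                       atol=1e-12)

    def test_symbolic_value(self):
        # −α (1−p)^γ ln p at p=0.9, α=0.7, γ=2
        expected = 0.7 * 0.1**2 * -np.log(0.9)
        assert focal_loss(0.9, 1, alpha=0.7, gamma=2.0) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(7.375e-4, rel=1e-3)

    def test_gradient_matches_finite_differences(self):
        logit = np.array([-1.3, 0.2, 2.4])
        y = np.array([1.0, 0.0, 1.0])
        eps = 1e-6

        def loss_at(lo):
            return focal_loss(1 / (1 + np.exp(-lo)), y, 0.7, 2.0)

        num = (loss_at(logit + eps) - loss_at(logit - eps)) / (2 * eps)
        ana = _focal_grad_logit(1 / (1 + np.exp(-logit)), y, 0.7, 2.0)
        np.testing.assert_allclose(ana, num, rtol=1e-5)


class TestInference:
    def _model(self, seed=0):
        return TextCNN({"surface": 30}, CNNConfig(
            embedding_dim=8, hidden=4, kernel=3, dropout=0.0), seed=seed)

    def test_document_probability_is_mean_of_windows(self):
        docs, _ = _mini_corpus(n=1, length=300)
        model = self._model()
        cfg = SequenceDatasetConfig(seq_len=64, vocab_size=30)
        vocab = {"surface": {f"mot{i:02d}": i + 2 for i in range(20)}}
        windows = inference_windows(docs[0], vocab, cfg)
        p = model.predict_proba(windows)
        assert infer_document(model, docs[0], vocab, cfg) == pytest.approx(
            float(np.mean(p)))

    def test_single_window_document_identity(self):
        docs, _ = _mini_corpus(n=1, length=40)
        model = self._model()
        cfg = SequenceDatasetConfig(seq_len=64, vocab_size=30)
        vocab = {"surface": {f"mot{i:02d}": i + 2 for i in range(20)}}
        windows = inference_windows(docs[0], vocab, cfg)
        assert len(windows) == 1
        assert infer_document(model, docs[0], vocab, cfg) == pytest.approx(
            float(model.predict_proba(windows)[0]))

    def test_mean_invariant_to_sequence_order(self):
        rng = np.random.default_rng(1)
        model = self._model()
        seqs = [Sequence(f"s{i}", 1,
                         {"surface": rng.integers(0, 30, size=64)}, 64)
                for i in range(7)]
        p1 = float(np.mean(model.predict_proba(seqs)))
        p2 = float(np.mean(model.predict_proba(seqs[::-1])))
        assert p1 == pytest.approx(p2)


class TestTraining:
    def test_fixed_seed_reproducible_weights(self):
        docs, labels = _mini_corpus(n=10, length=120)
        ids = [d.doc_id for d in docs]
        ds = build_sequence_dataset(
            docs, labels, SequenceDatasetConfig(seq_len=48, vocab_size=60,
                                                seed=3),
            (ids[:8], ids[8:]))
        sizes = {"surface": len(ds.vocab["surface"])}
        cfg = CNNConfig(embedding_dim=16, hidden=8, kernel=3, max_epochs=3)
        m1, _ = train_cnn(ds.train, ds.val, sizes, cfg, seed=9)
        m2, _ = train_cnn(ds.train, ds.val, sizes, cfg, seed=9)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.emb["surface"], m2.emb["surface"])

    def test_multi_channel_with_extra_channels_zeroed_matches_single(self):
        rng = np.random.default_rng(0)
        cfg1 = CNNConfig(embedding_dim=8, hidden=4, kernel=3, dropout=0.0,
                         channels=("surface",))
        cfg3 = CNNConfig(embedding_dim=8, hidden=4, kernel=3, dropout=0.0,
                         channels=("surface", "lemma", "pos"))
        single = TextCNN({"surface": 30}, cfg1, seed=4)
        multi = TextCNN({"surface": 30, "lemma": 20, "pos": 10}, cfg3, seed=4)
        # copy surface weights; zero the extra channels' kernel slices
        multi.emb["surface"][:] = single.emb["surface"]
        multi.W[:] = 0.0
        multi.W[:, :8, :] = single.W
        multi.b[:] = single.b
        multi.w_out[:] = single.w_out
        multi.b_out = single.b_out
        ids1 = {"surface": rng.integers(0, 30, size=(2, 20))}
        ids3 = dict(ids1, lemma=rng.integers(0, 20, size=(2, 20)),
                    pos=rng.integers(0, 10, size=(2, 20)))
        p1, _ = single.forward(ids1)
        p3, _ = multi.forward(ids3)
        np.testing.assert_allclose(p1, p3, rtol=1e-12)

    def test_save_load_round_trip(self, tmp_path):
        model = TextCNN({"surface": 30}, CNNConfig(
            embedding_dim=8, hidden=4, kernel=3), seed=2)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        rng = np.random.default_rng(0)
        ids = {"surface": rng.integers(0, 30, size=(3, 15))}
        np.testing.assert_allclose(model.forward(ids)[0],
                                   back.forward(ids)[0])

    def test_learns_class_exclusive_marker(self):
        from sklearn.metrics import roc_auc_score

        docs, labels = _mini_corpus(n=30, length=200, seed=5)
        ids = [d.doc_id for d in docs]
        ds = build_sequence_dataset(
            docs, labels, SequenceDatasetConfig(seq_len=48, vocab_size=80,
                                                seed=5),
            (ids[:24], ids[24:]))
        model, log = train_cnn(
            ds.train, ds.val, {"surface": len(ds.vocab["surface"])},
            CNNConfig(embedding_dim=32, hidden=8, kernel=5, max_epochs=25),
            seed=5)
        pv = model.predict_proba(ds.val)
        auc = roc_auc_score([s.label for s in ds.val], pv)
        assert auc >= 0.9
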