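"""A small deterministic text CNN with focal loss, in NumPy.

Architecture (the minimal convolutional classifier consistent with
class-activation-map / deconvolution interpretability): per-channel
embedding lookup → concatenation → spatial dropout (whole embedding
dimensions dropped) → one 1-D convolution (valid padding) → ReLU → global
max pooling → dense → sigmoid. Training uses Adam with L2 regularization,
mini-batches, and early stopping on validation loss.

All randomness (initialisation, dropout, batch shuffling) flows from one
seeded generator, and the implementation is single-threaded NumPy, so a
fixed seed and data give bit-identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-7


@dataclass
class CNNConfig:
    embedding_dim: int = 128
    hidden: int = 32
    kernel: int = 9
    dropout: float = 0.1  # spatial dropout probability
    l2_penalty: float = 1e-4
    max_epochs: int = 50
    patience: int = 8
    learning_rate: float = 3e-3
    batch_size: int = 32
    focal_alpha: float = 0.7
    focal_gamma: float = 2.0
    channels: tuple = ("surface",)


def focal_loss(p, y, alpha: float = 0.7, gamma: float = 2.0):
    """Focal loss −α_t (1−p_t)^γ log(p_t) for predicted probability ``p`` of
    the positive class and binary label ``y``.

    α_t is α for the positive class and 1−α for the negative; γ = 0 reduces
    the loss to α-weighted cross-entropy. Probabilities are clipped to
    avoid log(0).
    """
    p = np.clip(np.asarray(p, float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, float)
    pt = np.where(y == 1, p, 1.0 - p)
    alpha_t = np.where(y == 1, alpha, 1.0 - alpha)
    return -alpha_t * (1.0 - pt) ** gamma * np.log(pt)


def _focal_grad_logit(p, y, alpha: float, gamma: float):
    """d(focal loss)/d(logit), with p = sigmoid(logit)."""
    p = np.clip(np.asarray(p, float), _EPS, 1.0 - _EPS)
    y = np.asarray(y, float)
    pt = np.where(y == 1, p, 1.0 - p)
    alpha_t = np.where(y == 1, alpha, 1.0 - alpha)
    # dL/dpt, then dpt/dlogit = ± pt (1 − pt)
    dl_dpt = alpha_t * (
        gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt)
        - (1.0 - pt) ** gamma / pt
    )
    sign = np.where(y == 1, 1.0, -1.0)
    return dl_dpt * sign * pt * (1.0 - pt)


class TextCNN:
    """Binary sequence classifier over one or more token-id channels."""

    def __init__(self, vocab_sizes: dict, cfg: CNNConfig, seed: int = 0):
        self.cfg = cfg
        self.channels = tuple(cfg.channels)
        if set(vocab_sizes) != set(self.channels):
            raise ValueError("vocab_sizes must cover exactly the channels")
        rng = np.random.default_rng(seed)
        d = cfg.embedding_dim
        self.emb = {
            ch: rng.normal(0.0, 0.05, size=(vocab_sizes[ch], d))
            for ch in self.channels
        }
        for e in self.emb.values():
            e[0] = 0.0  # PAD embeds to zero
        d_total = d * len(self.channels)
        limit = np.sqrt(6.0 / (cfg.kernel * d_total + cfg.hidden))
        self.W = rng.uniform(-limit, limit, size=(cfg.kernel, d_total, cfg.hidden))
        self.b = np.zeros(cfg.hidden)
        self.w_out = rng.normal(0.0, 0.05, size=cfg.hidden)
        self.b_out = 0.0
        self._rng = rng
        self._adam: dict = {}
        self._step = 0

    # -- forward -----------------------------------------------------------

    def _embed(self, batch_ids: dict) -> np.ndarray:
        return np.concatenate(
            [self.emb[ch][batch_ids[ch]] for ch in self.channels], axis=2
        )

    def _conv(self, x: np.ndarray):
        k = self.cfg.kernel
        bsz, length, d = x.shape
        n_pos = length - k + 1
        if n_pos < 1:
            raise ValueError(f"sequence length {length} shorter than kernel {k}")
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        # windows: (B, n_pos, D, K) -> (B, n_pos, K*D) matching W layout (K, D, H)
        col = windows.transpose(0, 1, 3, 2).reshape(bsz, n_pos, k * d)
        wflat = self.W.reshape(k * d, self.cfg.hidden)
        return col, col @ wflat + self.b

    def forward(self, batch_ids: dict, train: bool = False):
        x = self._embed(batch_ids)
        cache: dict = {"ids": batch_ids}
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (self._rng.random((x.shape[0], 1, x.shape[2])) < keep) / keep
            x = x * mask
            cache["drop_mask"] = mask
        col, pre = self._conv(x)
        act = np.maximum(pre, 0.0)
        arg = act.argmax(axis=1)  # (B, H)
        pooled = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
        logit = pooled @ self.w_out + self.b_out
        p = 1.0 / (1.0 + np.exp(-logit))
        cache.update(x=x, col=col, pre=pre, act=act, arg=arg, pooled=pooled,
                     logit=logit, p=p)
        return p, cache

    def conv_activations(self, batch_ids: dict) -> np.ndarray:
        """Post-ReLU convolution feature maps (B, positions, hidden)."""
        x = self._embed(batch_ids)
        _, pre = self._conv(x)
        return np.maximum(pre, 0.0)

    # -- backward ----------------------------------------------------------

    def _backward(self, cache: dict, y: np.ndarray) -> dict:
        cfg = self.cfg
        bsz = len(y)
        dlogit = _focal_grad_logit(cache["p"], y, cfg.focal_alpha,
                                   cfg.focal_gamma) / bsz
        grads: dict = {}
        grads["w_out"] = cache["pooled"].T @ dlogit
        grads["b_out"] = dlogit.sum()
        dpooled = dlogit[:, None] * self.w_out[None, :]  # (B, H)
        dact = np.zeros_like(cache["act"])
        np.put_along_axis(dact, cache["arg"][:, None, :], dpooled[:, None, :],
                          axis=1)
        dpre = dact * (cache["pre"] > 0)
        k, h = cfg.kernel, cfg.hidden
        d = cache["x"].shape[2]
        wflat = self.W.reshape(k * d, h)
        col = cache["col"]
        grads["W"] = (
            col.reshape(-1, k * d).T @ dpre.reshape(-1, h)
        ).reshape(k, d, h)
        grads["b"] = dpre.sum(axis=(0, 1))
        dcol = dpre @ wflat.T  # (B, n_pos, K*D)
        dx = np.zeros_like(cache["x"])
        n_pos = dcol.shape[1]
        dcol4 = dcol.reshape(bsz, n_pos, k, d)
        for kk in range(k):
            dx[:, kk : kk + n_pos, :] += dcol4[:, :, kk, :]
        if "drop_mask" in cache:
            dx = dx * cache["drop_mask"]
        grads["emb"] = {}
        offset = 0
        de = cfg.embedding_dim
        for ch in self.channels:
            g = np.zeros_like(self.emb[ch])
            np.add.at(g, cache["ids"][ch], dx[:, :, offset : offset + de])
            g[0] = 0.0  # PAD stays zero
            grads["emb"][ch] = g
            offset += de
        return grads

    def _adam_update(self, name: str, param: np.ndarray, grad: np.ndarray,
                     lr: float) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m, v = self._adam.setdefault(
            name, (np.zeros_like(param), np.zeros_like(param)))
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad**2
        self._adam[name] = (m, v)
        t = self._step
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        param -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, batch_ids: dict, y: np.ndarray) -> float:
        p, cache = self.forward(batch_ids, train=True)
        loss = float(np.mean(focal_loss(p, y, self.cfg.focal_alpha,
                                        self.cfg.focal_gamma)))
        if not np.isfinite(loss):
            raise FloatingPointError("training diverged (non-finite loss)")
        grads = self._backward(cache, y)
        lam = self.cfg.l2_penalty
        self._step += 1
        lr = self.cfg.learning_rate
        self._adam_update("W", self.W, grads["W"] + lam * self.W, lr)
        self._adam_update("b", self.b, grads["b"], lr)
        self._adam_update("w_out", self.w_out,
                          grads["w_out"] + lam * self.w_out, lr)
        b_out = np.array([self.b_out])
        self._adam_update("b_out", b_out, np.array([grads["b_out"]]), lr)
        self.b_out = float(b_out[0])
        for ch in self.channels:
            self._adam_update(f"emb_{ch}", self.emb[ch],
                              grads["emb"][ch] + lam * self.emb[ch], lr)
            self.emb[ch][0] = 0.0
        return loss

    # -- inference ---------------------------------------------------------

    def predict_proba(self, sequences) -> np.ndarray:
        if not sequences:
            return np.empty(0)
        out = []
        for start in range(0, len(sequences), 256):
            chunk = sequences[start : start + 256]
            ids = _stack_ids(chunk, self.channels)
            p, _ = self.forward(ids, train=False)
            out.append(p)
        return np.concatenate(out)


def _stack_ids(sequences, channels) -> dict:
    return {ch: np.stack([s.ids[ch] for s in sequences]) for ch in channels}


@dataclass
class TrainingLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    stopped_epoch: int = 0


def train_cnn(train_seqs, val_seqs, vocab_sizes: dict, cfg: CNNConfig,
              seed: int = 0) -> tuple[TextCNN, TrainingLog]:
    """Train with early stopping on validation focal loss.

    Raises FloatingPointError (with the seed in the message) on divergence.
    """
    model = TextCNN(vocab_sizes, cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    y_train = np.array([s.label for s in train_seqs], dtype=float)
    y_val = np.array([s.label for s in val_seqs], dtype=float)
    log = TrainingLog()
    best_val = np.inf
    best_state = _snapshot(model)
    since_best = 0
    try:
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(train_seqs))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                batch = [train_seqs[i] for i in sel]
                ids = _stack_ids(batch, model.channels)
                losses.append(model.train_step(ids, y_train[sel]))
            log.train_loss.append(float(np.mean(losses)))
            pv = model.predict_proba(val_seqs)
            vloss = float(np.mean(focal_loss(pv, y_val, cfg.focal_alpha,
                                             cfg.focal_gamma)))
            log.val_loss.append(vloss)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = _snapshot(model)
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        log.stopped_epoch = len(log.train_loss)
    except FloatingPointError as e:
        raise FloatingPointError(f"{e} (seed={seed})") from e
    _restore(model, best_state)
    return model, log


def _snapshot(model: TextCNN) -> dict:
    return {
        "emb": {ch: e.copy() for ch, e in model.emb.items()},
        "W": model.W.copy(), "b": model.b.copy(),
        "w_out": model.w_out.copy(), "b_out": model.b_out,
    }


def _restore(model: TextCNN, state: dict) -> None:
    for ch in model.channels:
        model.emb[ch][:] = state["emb"][ch]
    model.W[:] = state["W"]
    model.b[:] = state["b"]
    model.w_out[:] = state["w_out"]
    model.b_out = state["b_out"]


def save_model(model: TextCNN, path) -> None:
    """Persist weights + config to an .npz archive."""
    import dataclasses
    import json
    from pathlib import Path

    arrays = {"W": model.W, "b": model.b, "w_out": model.w_out,
              "b_out": np.array([model.b_out])}
    for ch in model.channels:
        arrays[f"emb_{ch}"] = model.emb[ch]
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(
        json.dumps(dataclasses.asdict(model.cfg)))


def load_model(path) -> TextCNN:
    import json
    from pathlib import Path

    path = Path(path)
    cfg = CNNConfig(**{k: tuple(v) if k == "channels" else v
                       for k, v in
                       json.loads(path.with_suffix(".json").read_text()).items()})
    data = np.load(path.with_suffix(".npz"))
    vocab_sizes = {ch: data[f"emb_{ch}"].shape[0] for ch in cfg.channels}
    model = TextCNN(vocab_sizes, cfg, seed=0)
    model.W[:] = data["W"]
    model.b[:] = data["b"]
    model.w_out[:] = data["w_out"]
    model.b_out = float(data["b_out"][0])
    for ch in cfg.channels:
        model.emb[ch][:] = data[f"emb_{ch}"]
    return model


def infer_document(model: TextCNN, doc, vocab: dict, cfg) -> float:
    """Document probability = arithmetic mean over all contiguous
    non-overlapping sequence windows."""
    from .data import inference_windows

    windows = inference_windows(doc, vocab, cfg)
    return float(np.mean(model.predict_proba(windows)))
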