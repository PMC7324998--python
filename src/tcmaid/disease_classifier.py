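"""Text-convolution disease classifier with ranked top-k output.

Notes are encoded as fixed-length (L) index sequences over an embedding
table (pad row 0 held at zero), convolved by banks of kernels whose width
equals the embedding dimension at several heights (default L-1, L-2, L-3,
yielding feature surfaces of heights 2, 3 and 4), ReLU'd, max-pooled to
one scalar per kernel, concatenated and passed through a fully connected
softmax layer over the disease classes.  Training is cross-entropy with
Adam, early stopping on validation top-1 accuracy, and an optional small
grid search over the learning rate.  Implemented directly in numpy with
exact analytic gradients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TextCnnConfig",
    "TextCnn",
    "DiseasePrediction",
    "encode",
    "conv_output_height",
    "fit",
    "predict_topk",
]

PAD = 0
UNK_ROW = 1


@dataclass
class TextCnnConfig:
    """Architecture and training settings.

    Defaults follow the reference geometry (100-dimensional embeddings,
    256 kernels per height, heights L-1/L-2/L-3); synthetic-corpus runs
    typically shrink ``d`` and ``n_filters``.  ``kernel_heights=None``
    means (L-1, L-2, L-3); the classic small heights (2, 3, 4) are an
    alternative preset via ``small_kernel_preset``.
    """

    L: int = 50
    d: int = 100
    n_filters: int = 256
    kernel_heights: tuple[int, ...] | None = None
    n_classes: int = 2
    seed: int = 0
    lr: float = 0.01
    epochs: int = 20
    batch_size: int = 32
    patience: int = 3
    lr_grid: tuple[float, ...] = ()  # extra candidates, searched descending

    def heights(self) -> tuple[int, ...]:
        hs = self.kernel_heights if self.kernel_heights is not None else (self.L - 1, self.L - 2, self.L - 3)
        for h in hs:
            if not 1 <= h <= self.L:
                raise ValueError(f"kernel height {h} outside [1, L={self.L}]")
        return tuple(hs)

    @staticmethod
    def small_kernel_preset(**kw) -> "TextCnnConfig":
        kw.setdefault("kernel_heights", (2, 3, 4))
        return TextCnnConfig(**kw)


@dataclass
class DiseasePrediction:
    """Ranked (disease, probability) list, descending, ties by class index."""

    ranked: list[tuple[str, float]]


def encode(tokens: list[str], L: int, vocab: dict[str, int]) -> np.ndarray:
    """Map tokens to embedding rows, truncate at L, right-pad with 0.

    Unknown tokens map to the reserved UNK row.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    idx = [vocab.get(t, UNK_ROW) for t in tokens[:L]]
    return np.array(idx + [PAD] * (L - len(idx)), dtype=int)


def conv_output_height(L: int, h: int) -> int:
    """Feature-surface height of a valid stride-1 convolution: L - h + 1.

    The kernel width equals the embedding dimension, so convolution slides
    only along the token axis.
    """
    if not 1 <= h <= L:
        raise ValueError(f"kernel height {h} outside [1, {L}]")
    return L - h + 1


class TextCnn:
    """Numpy text-convolution network; see module docstring."""

    def __init__(self, config: TextCnnConfig, vocab: dict[str, int], classes: list[str]):
        if config.n_classes != len(classes):
            config.n_classes = len(classes)
        if config.n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.config = config
        self.vocab = vocab
        self.classes = list(classes)
        rng = np.random.default_rng(config.seed)
        V = max(vocab.values()) + 1
        d, F = config.d, config.n_filters
        self.params: dict[str, np.ndarray] = {"E": rng.normal(0, 0.1, size=(V, d))}
        self.params["E"][PAD] = 0.0
        self.heights = config.heights()
        for h in self.heights:
            lim = np.sqrt(6.0 / (h * d + F))
            self.params[f"W{h}"] = rng.uniform(-lim, lim, size=(F, h * d))
            self.params[f"c{h}"] = np.zeros(F)
        n_feat = len(self.heights) * F
        lim = np.sqrt(6.0 / (n_feat + config.n_classes))
        self.params["Wf"] = rng.uniform(-lim, lim, size=(n_feat, config.n_classes))
        self.params["bf"] = np.zeros(config.n_classes)

    # -- forward ------------------------------------------------------------

    def _forward(self, idx: np.ndarray, cache: bool = False):
        """Batched forward pass: idx (B, L) -> probabilities (B, C)."""
        p = self.params
        idx = np.atleast_2d(idx)
        B, L = idx.shape
        if L != self.config.L:
            raise ValueError(f"expected sequences of length {self.config.L}, got {L}")
        X = p["E"][idx]  # (B, L, d)
        pooled = []
        caches = []
        for h in self.heights:
            P = conv_output_height(L, h)
            win = np.lib.stride_tricks.sliding_window_view(X, (h,), axis=1)  # (B, P, d, h)
            win = win.transpose(0, 1, 3, 2).reshape(B, P, h * self.config.d)
            Z = win @ p[f"W{h}"].T + p[f"c{h}"]  # (B, P, F)
            R = np.maximum(Z, 0.0)
            am = np.argmax(R, axis=1)  # (B, F)
            pooled.append(np.take_along_axis(R, am[:, None, :], axis=1)[:, 0, :])
            caches.append((win, Z, am))
        U = np.concatenate(pooled, axis=1)  # (B, n_heights * F)
        logits = U @ p["Wf"] + p["bf"]
        logits -= logits.max(axis=1, keepdims=True)
        expL = np.exp(logits)
        probs = expL / expL.sum(axis=1, keepdims=True)
        if cache:
            return probs, (idx, X, caches, U)
        return probs

    def forward(self, idx: np.ndarray) -> np.ndarray:
        """Class distribution for one encoded note (sums to 1)."""
        return self._forward(np.asarray(idx))[0]

    def _backward(self, probs, cache, y_onehot):
        p = self.params
        idx, X, caches, U = cache
        B = len(idx)
        d, F = self.config.d, self.config.n_filters
        dlogits = (probs - y_onehot) / B
        grads = {"Wf": U.T @ dlogits, "bf": dlogits.sum(axis=0)}
        dU = dlogits @ p["Wf"].T
        dX = np.zeros_like(X)
        for j, h in enumerate(self.heights):
            win, Z, am = caches[j]
            dpool = dU[:, j * F : (j + 1) * F]  # (B, F)
            dR = np.zeros_like(Z)
            np.put_along_axis(dR, am[:, None, :], dpool[:, None, :], axis=1)
            dR *= Z > 0
            P = Z.shape[1]
            grads[f"W{h}"] = np.einsum("bpf,bpk->fk", dR, win)
            grads[f"c{h}"] = dR.sum(axis=(0, 1))
            dwin = dR @ p[f"W{h}"]  # (B, P, h*d)
            dwin = dwin.reshape(B, P, h, d)
            for t in range(P):
                dX[:, t : t + h, :] += dwin[:, t]
        dE = np.zeros_like(p["E"])
        np.add.at(dE, idx.ravel(), dX.reshape(-1, d))
        dE[PAD] = 0.0
        grads["E"] = dE
        return grads

    # -- training -----------------------------------------------------------

    def _train(self, Xtr, ytr, Xval, yval, lr, seed):
        rng = np.random.default_rng(seed)
        state: dict = {}
        step = 0
        best_acc = -1.0
        best_params = None
        stale = 0
        trace = []
        cfg = self.config
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(Xtr))
            for s in range(0, len(order), cfg.batch_size):
                sel = order[s : s + cfg.batch_size]
                probs, cache = self._forward(Xtr[sel], cache=True)
                onehot = np.eye(cfg.n_classes)[ytr[sel]]
                grads = self._backward(probs, cache, onehot)
                step += 1
                _adam(self.params, grads, state, lr, step)
                self.params["E"][PAD] = 0.0
            acc = self._top1_acc(Xval, yval) if len(Xval) else 1.0
            trace.append(acc)
            logger.info("cnn lr=%g epoch %d: val top-1 %.4f", lr, epoch, acc)
            if acc > best_acc + 1e-12:
                best_acc = acc
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return best_acc, trace

    def _top1_acc(self, X, y) -> float:
        if len(X) == 0:
            return 0.0
        probs = self._forward(X)
        return float(np.mean(np.argmax(probs, axis=1) == y))

    def save(self, path: str | Path) -> None:
        cfg = self.config
        meta = {
            "format": "tcmaid-cnn-v1",
            "config": {
                "L": cfg.L, "d": cfg.d, "n_filters": cfg.n_filters,
                "kernel_heights": list(self.heights), "n_classes": cfg.n_classes,
                "seed": cfg.seed, "lr": cfg.lr, "epochs": cfg.epochs,
                "batch_size": cfg.batch_size, "patience": cfg.patience,
            },
            "vocab": self.vocab,
            "classes": self.classes,
        }
        np.savez(path, __config__=np.array(json.dumps(meta)), **self.params)

    @staticmethod
    def load(path: str | Path) -> "TextCnn":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__config__"]))
        if meta.get("format") != "tcmaid-cnn-v1":
            raise ValueError("unrecognized classifier archive")
        c = meta["config"]
        c["kernel_heights"] = tuple(c["kernel_heights"])
        model = TextCnn(TextCnnConfig(**c), {k: int(v) for k, v in meta["vocab"].items()}, meta["classes"])
        model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model


def _adam(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for name, g in grads.items():
        m, v = state.setdefault(name, (np.zeros_like(g), np.zeros_like(g)))
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[name] = (m, v)
        params[name] = params[name] - lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)


def build_vocab(token_seqs: list[list[str]]) -> dict[str, int]:
    """Token -> embedding row; rows 0 (pad) and 1 (unk) reserved."""
    vocab: dict[str, int] = {"<pad>": PAD, "<unk>": UNK_ROW}
    for seq in token_seqs:
        for t in seq:
            vocab.setdefault(t, len(vocab))
    return vocab


def fit(
    train: list[tuple[list[str], str]],
    val: list[tuple[list[str], str]],
    config: TextCnnConfig,
) -> TextCnn:
    """Train on (tokens, disease) pairs with a small learning-rate grid.

    Candidates are ``config.lr`` plus ``config.lr_grid``, searched in
    descending order; the model with the best validation top-1 accuracy
    wins.  Raises if a configured class is absent from the training data.
    """
    if not train:
        raise ValueError("empty training set")
    classes = sorted({lab for _, lab in train} | {lab for _, lab in val})
    train_labels = {lab for _, lab in train}
    missing = set(classes) - train_labels
    if missing:
        raise ValueError(f"classes absent from training data: {sorted(missing)}")
    vocab = build_vocab([t for t, _ in train])
    cls_idx = {c: i for i, c in enumerate(classes)}
    config.n_classes = len(classes)
    Xtr = np.stack([encode(t, config.L, vocab) for t, _ in train])
    ytr = np.array([cls_idx[lab] for _, lab in train])
    Xval = (
        np.stack([encode(t, config.L, vocab) for t, _ in val])
        if val else np.zeros((0, config.L), dtype=int)
    )
    yval = np.array([cls_idx[lab] for _, lab in val], dtype=int)

    lrs = sorted({config.lr, *config.lr_grid}, reverse=True)
    best: tuple[float, TextCnn] | None = None
    for lr in lrs:
        model = TextCnn(config, vocab, classes)
        acc, _ = model._train(Xtr, ytr, Xval, yval, lr, config.seed)
        if best is None or acc > best[0]:
            best = (acc, model)
    assert best is not None
    return best[1]


def predict_topk(model: TextCnn, tokens: list[str], k: int) -> DiseasePrediction:
    """First min(k, n_classes) classes ranked by probability, ties by index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = encode(tokens, model.config.L, model.vocab)
    probs = model.forward(idx)
    order = np.argsort(-probs, kind="stable")  # stable: ties keep class order
    ranked = [(model.classes[i], float(probs[i])) for i in order]
    return DiseasePrediction(ranked[: min(k, len(ranked))])
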