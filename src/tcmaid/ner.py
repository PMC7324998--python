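"""Named-entity recognition: bidirectional recurrent encoder + linear-chain CRF.

Tokens are embedded, encoded by a bidirectional tanh recurrent network, and
projected to per-tag emission scores; a linear-chain conditional random
field with learned tag-transition scores (plus virtual START/STOP states)
scores whole tag sequences.  Training minimizes the CRF negative
log-likelihood with exact gradients (forward–backward marginals
backpropagated through the encoder); decoding is exact Viterbi with ties
broken toward the lowest tag index.  Decoded BIO tags become entity spans
that are assembled into structured records, pairing each duration with its
nearest preceding symptom in the same section.

The model is intentionally small: clinical notes here are short token
sequences over a closed lexicon, so a compact encoder trained from scratch
reaches ceiling on the synthetic corpora while keeping the exact-inference
CRF — the part that matters for span quality — fully transparent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .synthetic_corpus import AnnotatedNote, Span, spans_to_tags, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "TagScheme",
    "NerModel",
    "EntityMention",
    "StructuredRecord",
    "path_score",
    "log_partition",
    "viterbi",
    "nll",
    "fit",
    "decode_entities",
    "structure",
    "span_f1",
]

UNK = "<unk>"


@dataclass(frozen=True)
class TagScheme:
    """BIO tag inventory: O plus B-t / I-t per entity type, with START/STOP."""

    entity_types: tuple[str, ...]

    @property
    def tags(self) -> list[str]:
        out = ["O"]
        for t in self.entity_types:
            out.extend((f"B-{t}", f"I-{t}"))
        return out

    @property
    def K(self) -> int:
        return 2 * len(self.entity_types) + 1

    @property
    def START(self) -> int:
        return self.K

    @property
    def STOP(self) -> int:
        return self.K + 1

    def index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise KeyError(f"unknown tag {tag!r}") from None

    def encode(self, tags: list[str]) -> np.ndarray:
        table = {t: i for i, t in enumerate(self.tags)}
        try:
            return np.array([table[t] for t in tags], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown tag {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# linear-chain CRF primitives (emissions e: T x K, transitions A: (K+2) x (K+2))


def _check(e: np.ndarray, A: np.ndarray) -> tuple[int, int]:
    e = np.asarray(e)
    T, K = e.shape
    if A.shape != (K + 2, K + 2):
        raise ValueError(f"transitions must be ({K + 2},{K + 2}), got {A.shape}")
    return T, K


def path_score(e: np.ndarray, A: np.ndarray, y: np.ndarray | list[int]) -> float:
    """Score of one tag path: emissions + START/inner/STOP transitions."""
    T, K = _check(e, A)
    y = np.asarray(y, dtype=int)
    if len(y) != T:
        raise ValueError(f"tag sequence length {len(y)} != {T} tokens")
    if T == 0:
        return 0.0
    START, STOP = K, K + 1
    s = A[START, y[0]] + e[np.arange(T), y].sum() + A[y[-1], STOP]
    if T > 1:
        s += A[y[:-1], y[1:]].sum()
    return float(s)


def log_partition(e: np.ndarray, A: np.ndarray) -> float:
    """log sum over all K^T paths of exp(path_score), by forward recursion."""
    T, K = _check(e, A)
    if T == 0:
        return 0.0
    START, STOP = K, K + 1
    alpha = A[START, :K] + e[0]
    inner = A[:K, :K]
    for t in range(1, T):
        alpha = logsumexp(alpha[:, None] + inner, axis=0) + e[t]
    return float(logsumexp(alpha + A[:K, STOP]))


def viterbi(e: np.ndarray, A: np.ndarray) -> tuple[list[int], float]:
    """Exact MAP decoding; backpointer ties resolve to the lowest tag index."""
    T, K = _check(e, A)
    if T == 0:
        return [], 0.0
    START, STOP = K, K + 1
    inner = A[:K, :K]
    delta = A[START, :K] + e[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + inner  # prev x cur
        back[t] = np.argmax(scores, axis=0)  # first max = lowest index
        delta = scores[back[t], np.arange(K)] + e[t]
    final = delta + A[:K, STOP]
    last = int(np.argmax(final))
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(final[last])


def _forward_backward(e: np.ndarray, A: np.ndarray):
    """Return (log Z, unary marginals T x K, pairwise marginals (T-1) x K x K)."""
    T, K = _check(e, A)
    START, STOP = K, K + 1
    inner = A[:K, :K]
    alphas = np.empty((T, K))
    alphas[0] = A[START, :K] + e[0]
    for t in range(1, T):
        alphas[t] = logsumexp(alphas[t - 1][:, None] + inner, axis=0) + e[t]
    betas = np.empty((T, K))
    betas[T - 1] = A[:K, STOP]
    for t in range(T - 2, -1, -1):
        betas[t] = logsumexp(inner + e[t + 1] + betas[t + 1], axis=1)
    logZ = float(logsumexp(alphas[T - 1] + A[:K, STOP]))
    unary = np.exp(alphas + betas - logZ)
    pair = np.empty((max(T - 1, 0), K, K))
    for t in range(T - 1):
        pair[t] = np.exp(
            alphas[t][:, None] + inner + e[t + 1][None, :] + betas[t + 1][None, :] - logZ
        )
    return logZ, unary, pair


# ---------------------------------------------------------------------------
# model


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    lim = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-lim, lim, size=shape)


@dataclass
class NerModel:
    """Embeddings, bidirectional recurrent encoder, emission projection, CRF."""

    scheme: TagScheme
    vocab: dict[str, int]
    params: dict[str, np.ndarray]
    emb_dim: int
    hidden: int
    seed: int
    char_features: bool = False
    char_vocab: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def init(
        scheme: TagScheme,
        vocab: dict[str, int],
        emb_dim: int = 24,
        hidden: int = 24,
        seed: int = 0,
        char_features: bool = False,
        char_vocab: dict[str, int] | None = None,
    ) -> "NerModel":
        rng = np.random.default_rng(seed)
        K = scheme.K
        V = len(vocab)
        p: dict[str, np.ndarray] = {
            "E": rng.normal(0, 0.1, size=(V, emb_dim)),
            "Wo": _glorot(rng, (2 * hidden, K)),
            "bo": np.zeros(K),
        }
        for d in ("f", "b"):
            p[f"Wx{d}"] = _glorot(rng, (emb_dim, hidden))
            p[f"Wh{d}"] = _glorot(rng, (hidden, hidden))
            p[f"b{d}"] = np.zeros(hidden)
        A = np.zeros((K + 2, K + 2))
        A[:, scheme.START] = -np.inf  # nothing enters START
        A[scheme.STOP, :] = -np.inf  # nothing leaves STOP
        A[scheme.STOP, scheme.STOP] = -np.inf
        p["A"] = A
        cv = char_vocab or {}
        if char_features:
            p["Ec"] = rng.normal(0, 0.1, size=(max(len(cv), 1), emb_dim))
        return NerModel(scheme, vocab, p, emb_dim, hidden, seed, char_features, cv)

    # -- encoding -----------------------------------------------------------

    def token_ids(self, tokens: list[str]) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(t, unk) for t in tokens], dtype=int)

    def _embed(self, tokens: list[str], ids: np.ndarray) -> np.ndarray:
        X = self.params["E"][ids].copy()
        if self.char_features and tokens:
            Ec = self.params["Ec"]
            for i, tok in enumerate(tokens):
                rows = [self.char_vocab[c] for c in tok if c in self.char_vocab]
                if rows:
                    X[i] += Ec[rows].mean(axis=0)
        return X

    def _encode(self, X: np.ndarray):
        """Run both recurrent directions; returns (H, hf, hb) with H = [hf; hb]."""
        p = self.params
        T = len(X)
        h = self.hidden
        hf = np.zeros((T, h))
        hb = np.zeros((T, h))
        prev = np.zeros(h)
        for t in range(T):
            prev = np.tanh(X[t] @ p["Wxf"] + prev @ p["Whf"] + p["bf"])
            hf[t] = prev
        prev = np.zeros(h)
        for t in range(T - 1, -1, -1):
            prev = np.tanh(X[t] @ p["Wxb"] + prev @ p["Whb"] + p["bb"])
            hb[t] = prev
        return np.concatenate([hf, hb], axis=1), hf, hb

    def emissions(self, tokens: list[str]) -> np.ndarray:
        ids = self.token_ids(tokens)
        X = self._embed(tokens, ids)
        H, _, _ = self._encode(X)
        return H @ self.params["Wo"] + self.params["bo"]

    def predict_tags(self, tokens: list[str]) -> list[str]:
        if not tokens:
            return []
        e = self.emissions(tokens)
        path, _ = viterbi(e, self.params["A"])
        tags = self.scheme.tags
        return [tags[i] for i in path]

    # -- training -----------------------------------------------------------

    def _seq_grads(self, tokens: list[str], gold: np.ndarray):
        """NLL of one sequence and exact gradients for all parameters."""
        p = self.params
        scheme = self.scheme
        K = scheme.K
        ids = self.token_ids(tokens)
        X = self._embed(tokens, ids)
        H, hf, hb = self._encode(X)
        e = H @ p["Wo"] + p["bo"]
        A = p["A"]
        T = len(tokens)

        logZ, unary, pair = _forward_backward(e, A)
        loss = logZ - path_score(e, A, gold)

        de = unary.copy()
        de[np.arange(T), gold] -= 1.0

        dA = np.zeros_like(A)
        dA[scheme.START, :K] += unary[0]
        dA[scheme.START, gold[0]] -= 1.0
        dA[:K, scheme.STOP] += unary[T - 1]
        dA[gold[T - 1], scheme.STOP] -= 1.0
        if T > 1:
            dA[:K, :K] += pair.sum(axis=0)
            np.add.at(dA[:K, :K], (gold[:-1], gold[1:]), -1.0)

        grads: dict[str, np.ndarray] = {"A": dA}
        grads["Wo"] = H.T @ de
        grads["bo"] = de.sum(axis=0)
        dH = de @ p["Wo"].T
        h = self.hidden
        dHf, dHb = dH[:, :h], dH[:, h:]

        dX = np.zeros_like(X)
        for d, hs, dHd, order in (
            ("f", hf, dHf, range(T - 1, -1, -1)),
            ("b", hb, dHb, range(T)),
        ):
            Wx, Wh = p[f"Wx{d}"], p[f"Wh{d}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(h)
            carry = np.zeros(h)
            for t in order:
                dh = dHd[t] + carry
                dpre = dh * (1.0 - hs[t] ** 2)
                prev_h = (
                    hs[t - 1] if (d == "f" and t > 0) else hs[t + 1] if (d == "b" and t < T - 1) else None
                )
                if prev_h is not None:
                    dWh += np.outer(prev_h, dpre)
                dWx += np.outer(X[t], dpre)
                db += dpre
                dX[t] += dpre @ Wx.T
                carry = dpre @ Wh.T
            grads[f"Wx{d}"] = dWx
            grads[f"Wh{d}"] = dWh
            grads[f"b{d}"] = db

        dE = np.zeros_like(p["E"])
        np.add.at(dE, ids, dX)
        grads["E"] = dE
        if self.char_features:
            dEc = np.zeros_like(p["Ec"])
            for i, tok in enumerate(tokens):
                rows = [self.char_vocab[c] for c in tok if c in self.char_vocab]
                if rows:
                    g = dX[i] / len(rows)
                    for r in rows:
                        dEc[r] += g
            grads["Ec"] = dEc
        return loss, grads

    def save(self, path: str | Path) -> None:
        """Single versioned archive with config embedded."""
        cfg = {
            "format": "tcmaid-ner-v1",
            "entity_types": list(self.scheme.entity_types),
            "vocab": self.vocab,
            "emb_dim": self.emb_dim,
            "hidden": self.hidden,
            "seed": self.seed,
            "char_features": self.char_features,
            "char_vocab": self.char_vocab,
        }
        np.savez(path, __config__=np.array(json.dumps(cfg)), **self.params)

    @staticmethod
    def load(path: str | Path) -> "NerModel":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        if cfg.get("format") != "tcmaid-ner-v1":
            raise ValueError("unrecognized NER model archive")
        params = {k: data[k] for k in data.files if k != "__config__"}
        return NerModel(
            TagScheme(tuple(cfg["entity_types"])),
            {k: int(v) for k, v in cfg["vocab"].items()},
            params,
            cfg["emb_dim"],
            cfg["hidden"],
            cfg["seed"],
            cfg["char_features"],
            {k: int(v) for k, v in cfg["char_vocab"].items()},
        )


def nll(model: NerModel, batch: list[tuple[list[str], list[str]]]) -> float:
    """Summed CRF negative log-likelihood of gold tag sequences; always >= 0."""
    total = 0.0
    for tokens, tags in batch:
        if not tokens:
            continue
        gold = model.scheme.encode(list(tags))
        e = model.emissions(tokens)
        total += log_partition(e, model.params["A"]) - path_score(e, model.params["A"], gold)
    return float(total)


# ---------------------------------------------------------------------------
# training


def _note_sequences(note: AnnotatedNote) -> list[tuple[list[str], list[str]]]:
    out = []
    for section, text in note.sections.items():
        if section in ("admission", "discharge") or not text:
            continue
        toks, tags = spans_to_tags(text, [s for s in note.spans if s.section == section])
        if toks:
            out.append((toks, tags))
    return out


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for name, g in grads.items():
        p = params[name]
        if name == "A":
            mask = np.isfinite(p)
            g = np.where(mask, g, 0.0)
        m, v = state.setdefault(name, (np.zeros_like(g), np.zeros_like(g)))
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[name] = (m, v)
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        upd = lr * mhat / (np.sqrt(vhat) + eps)
        if name == "A":
            upd = np.where(np.isfinite(p), upd, 0.0)
        params[name] = p - upd


def span_f1(model: NerModel, notes: list[AnnotatedNote]) -> float:
    """Exact-match span F1 (start, end, type) over all annotated sections."""
    tp = fp = fn = 0
    for note in notes:
        for section, text in note.sections.items():
            if section in ("admission", "discharge") or not text:
                continue
            gold = {
                (s.start, s.end, s.etype) for s in note.spans if s.section == section
            }
            toks = tokenize(text)
            tags = model.predict_tags([t[0] for t in toks])
            pred = set()
            for st, en, ty in decode_entities([t[0] for t in toks], tags):
                pred.add((toks[st][1], toks[en - 1][2], ty))
            tp += len(gold & pred)
            fp += len(pred - gold)
            fn += len(gold - pred)
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def fit(
    train_notes: list[AnnotatedNote],
    val_notes: list[AnnotatedNote],
    hyperparams: dict | None = None,
    seed: int = 0,
) -> tuple[NerModel, list[float]]:
    """Train the tagger on annotated notes; early-stop on validation span F1.

    Returns the model (best validation weights restored) and the per-epoch
    validation F1 trace.  ``hyperparams``: ``emb_dim`` (24), ``hidden``
    (24), ``lr`` (0.02), ``epochs`` (5), ``patience`` (2),
    ``char_features`` (False).
    """
    if not train_notes:
        raise ValueError("empty training set")
    hp = {"emb_dim": 24, "hidden": 24, "lr": 0.02, "epochs": 5, "patience": 2, "char_features": False}
    hp.update(hyperparams or {})

    etypes = sorted({s.etype for n in train_notes for s in n.spans})
    scheme = TagScheme(tuple(etypes))
    seqs = [sq for n in train_notes for sq in _note_sequences(n)]
    vocab: dict[str, int] = {UNK: 0}
    for toks, _ in seqs:
        for t in toks:
            vocab.setdefault(t, len(vocab))
    char_vocab: dict[str, int] = {}
    if hp["char_features"]:
        for tok in vocab:
            for c in tok:
                char_vocab.setdefault(c, len(char_vocab))

    model = NerModel.init(
        scheme, vocab, hp["emb_dim"], hp["hidden"], seed,
        char_features=hp["char_features"], char_vocab=char_vocab,
    )
    if hp["epochs"] <= 0:
        return model, []

    rng = np.random.default_rng(seed)
    state: dict = {}
    step = 0
    best_f1 = -1.0
    best_params: dict[str, np.ndarray] | None = None
    trace: list[float] = []
    stale = 0
    for epoch in range(hp["epochs"]):
        order = rng.permutation(len(seqs))
        for idx in order:
            toks, tags = seqs[idx]
            gold = scheme.encode(tags)
            _, grads = model._seq_grads(toks, gold)
            step += 1
            _adam_step(model.params, grads, state, hp["lr"], step)
        f1 = span_f1(model, val_notes) if val_notes else 1.0
        trace.append(f1)
        logger.info("ner epoch %d: val span-F1 %.4f", epoch, f1)
        if f1 > best_f1 + 1e-12:
            best_f1 = f1
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= hp["patience"]:
                break
    if best_params is not None:
        model.params = best_params
    return model, trace


# ---------------------------------------------------------------------------
# span decoding and structuring


def decode_entities(tokens: list[str], tags: list[str]) -> list[tuple[int, int, str]]:
    """BIO tags -> token-index spans (start, end half-open, type).

    Maximal ``B-t (I-t)*`` runs become spans; a dangling ``I-t`` (no
    preceding ``B-t``/``I-t`` of the same type) is repaired to ``B-t``.
    """
    if len(tags) != len(tokens):
        raise ValueError("tokens and tags must align")
    spans: list[tuple[int, int, str]] = []
    start = None
    cur_type = None
    for i, tag in enumerate(tags):
        if tag == "O":
            prefix, etype = "O", None
        elif tag.startswith(("B-", "I-")) and len(tag) > 2:
            prefix, etype = tag[0], tag[2:]
        else:
            raise ValueError(f"unknown tag {tag!r}")
        if prefix == "O":
            if start is not None:
                spans.append((start, i, cur_type))
                start = None
        elif prefix == "B" or (prefix == "I" and etype != cur_type):
            if start is not None:
                spans.append((start, i, cur_type))
            start, cur_type = i, etype
        # else: I- continuing the current span
    if start is not None:
        spans.append((start, len(tags), cur_type))
    return spans


@dataclass
class EntityMention:
    section: str
    etype: str
    surface: str
    start: int
    end: int
    duration: str | None = None  # surface of the paired duration entity


@dataclass
class StructuredRecord:
    """Per-section canonical entities with symptom-duration relationships."""

    note_id: str
    entities: list[EntityMention]
    unpaired_durations: list[EntityMention] = field(default_factory=list)


def predict_spans(model: NerModel, note: AnnotatedNote) -> list[Span]:
    """Tag every annotated-text section and return character-offset spans."""
    spans: list[Span] = []
    for section, text in note.sections.items():
        if section in ("admission", "discharge") or not text:
            continue
        toks = tokenize(text)
        tags = model.predict_tags([t[0] for t in toks])
        for st, en, ty in decode_entities([t[0] for t in toks], tags):
            spans.append(Span(section, toks[st][1], toks[en - 1][2], ty, text[toks[st][1] : toks[en - 1][2]]))
    return spans


def structure(note: AnnotatedNote, spans: list[Span]) -> StructuredRecord:
    """Group entities by section and pair durations with symptoms.

    Each duration attaches to the nearest preceding symptom in the same
    section; durations with no preceding symptom are kept aside and logged.
    """
    entities: list[EntityMention] = []
    unpaired: list[EntityMention] = []
    by_section: dict[str, list[Span]] = {}
    for s in spans:
        by_section.setdefault(s.section, []).append(s)
    for section in note.sections:
        sec_spans = sorted(by_section.get(section, []), key=lambda s: s.start)
        text = note.sections[section]
        last_symptom: EntityMention | None = None
        for s in sec_spans:
            surface = text[s.start : s.end]
            m = EntityMention(section, s.etype, surface, s.start, s.end)
            if s.etype == "duration":
                if last_symptom is not None and last_symptom.duration is None:
                    last_symptom.duration = surface
                else:
                    logger.info("unpaired duration %r in %s of %s", surface, section, note.note_id)
                    unpaired.append(m)
                continue
            entities.append(m)
            if s.etype == "symptom":
                last_symptom = m
    return StructuredRecord(note.note_id, entities, unpaired)
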