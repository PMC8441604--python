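"""Multi-label ICD code classifier: embedding -> BiGRU -> FC -> FC.

The full model is a 4-layer network: a word-embedding layer, a
bidirectional GRU whose final forward and backward states are
concatenated, a fully connected layer with PReLU activation and
dropout, and a final fully connected layer of size L (one logit per
code) under an elementwise sigmoid.  The baseline model drops the
recurrent and hidden layers entirely: mean-pooled embeddings feed a
single fully connected output layer.  Training minimizes mean
per-label binary cross-entropy with Adam and keeps the parameters of
the epoch with the best validation micro-F1.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from icdcoder import nn
from icdcoder.embeddings import EmbeddingMatrix
from icdcoder.text_pipeline import (
    LabeledNote,
    LabelSpace,
    PAD_INDEX,
    Vocabulary,
    encode,
)


@dataclass
class ClassifierConfig:
    """Hyperparameters; sizes default to the production configuration
    (256 GRU units per direction, 700 hidden units, dropout 0.2)."""

    label_count: int
    embedding_dim: int
    gru_hidden: int = 256
    fc1_size: int = 700
    dropout: float = 0.2
    max_len: int = 256
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.label_count, self.embedding_dim, self.gru_hidden,
               self.fc1_size, self.max_len, self.epochs, self.batch_size) < 1:
            if self.label_count < 1:
                raise ValueError("empty label space")
            raise ValueError("all sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class PredictionResult:
    note_id: str
    probabilities: np.ndarray
    ranked_codes: list[str]


class ClassifierModel:
    """Parameterized network plus its configuration and label space."""

    def __init__(
        self,
        config: ClassifierConfig,
        provider,
        vocab: Vocabulary,
        label_space: LabelSpace,
        mode: str = "full",
    ):
        if mode not in ("full", "baseline"):
            raise ValueError("mode must be 'full' or 'baseline'")
        self.config = config
        self.vocab = vocab
        self.label_space = label_space
        self.mode = mode
        rng = np.random.default_rng(config.seed)

        if isinstance(provider, EmbeddingMatrix):
            self.embedding = nn.Embedding(
                provider.matrix, pad_index=PAD_INDEX, trainable=provider.trainable
            )
            self.contextual = None
        else:  # contextual provider: frozen callable, vectors computed per note
            self.embedding = None
            self.contextual = provider
        d = config.embedding_dim

        layers: list[tuple[str, object]] = []
        if self.embedding is not None:
            layers.append(("embedding", self.embedding))
        if mode == "full":
            self.gru_f = nn.GRU(d, config.gru_hidden, rng)
            self.gru_b = nn.GRU(d, config.gru_hidden, rng)
            self.fc1 = nn.Dense(2 * config.gru_hidden, config.fc1_size, rng)
            self.prelu = nn.PReLU()
            self.drop = nn.Dropout(config.dropout)
            self.fc2 = nn.Dense(config.fc1_size, config.label_count, rng)
            layers += [
                ("gru_f", self.gru_f),
                ("gru_b", self.gru_b),
                ("fc1", self.fc1),
                ("prelu", self.prelu),
                ("fc2", self.fc2),
            ]
        else:
            self.fc2 = nn.Dense(d, config.label_count, rng)
            layers.append(("fc2", self.fc2))
        self.params = nn.collect_params(layers)

    # -- encoding -----------------------------------------------------------

    def encode_notes(
        self, notes: Sequence[LabeledNote]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index matrix (N, max_len), true lengths, multi-hot targets."""
        T = self.config.max_len
        idx = np.zeros((len(notes), T), dtype=np.int64)
        lengths = np.zeros(len(notes), dtype=np.int64)
        Y = np.zeros((len(notes), self.config.label_count), dtype=np.float32)
        for i, note in enumerate(notes):
            if not note.tokens:
                raise ValueError(f"empty input: note {note.note_id} has no tokens")
            idx[i], lengths[i] = encode(note.tokens, self.vocab, T)
            Y[i] = self.label_space.binarize(note.gold_codes)
        return idx, lengths, Y

    def _embed(self, idx: np.ndarray):
        if self.embedding is not None:
            return self.embedding.forward(idx)
        X = np.stack([self.contextual(row) for row in idx]).astype(np.float32)
        return X, None

    # -- forward / backward -------------------------------------------------

    def forward_batch(
        self, idx: np.ndarray, lengths: np.ndarray, train_rng=None
    ):
        """Logits (B, L) and the cache needed for the backward pass."""
        mask = (np.arange(idx.shape[1])[None, :] < lengths[:, None]).astype(np.float32)
        X, emb_cache = self._embed(idx)
        if self.mode == "baseline":
            denom = np.maximum(lengths[:, None], 1).astype(np.float32)
            pooled = (X * mask[:, :, None]).sum(axis=1) / denom
            logits, fc2_cache = self.fc2.forward(pooled)
            return logits, ("baseline", emb_cache, mask, denom, fc2_cache, X.shape)
        x_rev = nn.reverse_padded(X, lengths)
        sf, cf = self.gru_f.forward(X, mask)
        sb, cb = self.gru_b.forward(x_rev, mask)
        summary = np.concatenate([sf[:, -1], sb[:, -1]], axis=1)
        h1, c1 = self.fc1.forward(summary)
        a1, ca = self.prelu.forward(h1)
        d1, cd = self.drop.forward(a1, train_rng)
        logits, c2 = self.fc2.forward(d1)
        return logits, ("full", emb_cache, mask, lengths, cf, cb, c1, ca, cd, c2)

    def backward_batch(self, cache, d_logits: np.ndarray) -> None:
        if cache[0] == "baseline":
            _, emb_cache, mask, denom, fc2_cache, xshape = cache
            d_pooled = self.fc2.backward(fc2_cache, d_logits)
            dX = (d_pooled[:, None, :] / denom[:, None]) * mask[:, :, None]
            if self.embedding is not None:
                self.embedding.backward(emb_cache, dX)
            return
        _, emb_cache, mask, lengths, cf, cb, c1, ca, cd, c2 = cache
        H = self.config.gru_hidden
        d_d1 = self.fc2.backward(c2, d_logits)
        d_a1 = self.drop.backward(cd, d_d1)
        d_h1 = self.prelu.backward(ca, d_a1)
        d_summary = self.fc1.backward(c1, d_h1)
        B, T = mask.shape
        d_sf = np.zeros((B, T, H), dtype=np.float32)
        d_sb = np.zeros((B, T, H), dtype=np.float32)
        d_sf[:, -1] = d_summary[:, :H]
        d_sb[:, -1] = d_summary[:, H:]
        dX = self.gru_f.backward(cf, d_sf)
        dX_rev = self.gru_b.backward(cb, d_sb)
        dX += nn.reverse_padded(dX_rev, lengths)
        if self.embedding is not None:
            self.embedding.backward(emb_cache, dX)

    def predict_proba(self, notes: Sequence[LabeledNote]) -> np.ndarray:
        """Deterministic evaluation-mode forward pass, batched."""
        idx, lengths, _ = self.encode_notes(notes)
        out = np.empty((len(notes), self.config.label_count), dtype=np.float32)
        bs = max(self.config.batch_size, 1)
        for s in range(0, len(notes), bs):
            logits, _ = self.forward_batch(idx[s : s + bs], lengths[s : s + bs])
            out[s : s + bs] = nn._sigmoid(logits)
        return out

    def predict(self, notes: Sequence[LabeledNote], k: int = 20) -> list[PredictionResult]:
        probs = self.predict_proba(notes)
        return [
            PredictionResult(n.note_id, p, rank_top_k(p, self.label_space, k))
            for n, p in zip(notes, probs)
        ]

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.value[...] = state[k]

    def save(self, path: str | Path) -> None:
        """Self-describing JSON checkpoint: config + vocab + labels + weights."""
        payload = {
            "config": asdict(self.config),
            "mode": self.mode,
            "vocab": self.vocab.to_dict(),
            "vocab_min_count": self.vocab.min_count,
            "labels": {c: self.label_space.definition(c) for c in self.label_space.codes},
            "params": {k: v.tolist() for k, v in self.state_dict().items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        config = ClassifierConfig(**payload["config"])
        vocab = Vocabulary.from_dict(payload["vocab"], payload["vocab_min_count"])
        space = LabelSpace(payload["labels"])
        mat = np.zeros((len(vocab), config.embedding_dim), dtype=np.float32)
        model = cls(config, EmbeddingMatrix(mat, vocab), vocab, space, payload["mode"])
        model.load_state_dict(
            {k: np.asarray(v, dtype=np.float32) for k, v in payload["params"].items()}
        )
        return model


def build_classifier(
    config: ClassifierConfig,
    provider,
    vocab: Vocabulary,
    label_space: LabelSpace,
    mode: str = "full",
) -> ClassifierModel:
    """Construct a seeded classifier in ``full`` or ``baseline`` mode."""
    if len(label_space) == 0:
        raise ValueError("empty label space")
    return ClassifierModel(config, provider, vocab, label_space, mode)


def forward(model: ClassifierModel, note: LabeledNote) -> np.ndarray:
    """Probability vector in [0,1]^L for one note (evaluation mode)."""
    return model.predict_proba([note])[0]


def train_classifier(
    model: ClassifierModel,
    train_notes: Sequence[LabeledNote],
    valid_notes: Sequence[LabeledNote] | None = None,
    tau: float = 0.5,
) -> tuple[ClassifierModel, list[dict]]:
    """Train with per-label binary cross-entropy + Adam.

    Returns the model with the parameters of the best validation
    micro-F1 epoch restored, and a per-epoch log of train loss and
    train/valid micro-F1.  Fully seeded: identical inputs give an
    identical epoch log.
    """
    from icdcoder.evaluation import micro_scores

    cfg = model.config
    if not train_notes:
        raise ValueError("train set is empty")
    idx, lengths, Y = model.encode_notes(train_notes)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(train_notes)
    log: list[dict] = []
    best_f1, best_state = -1.0, None

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for s in range(0, n, cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            logits, cache = model.forward_batch(idx[b], lengths[b], train_rng=rng)
            loss, d_logits = nn.bce_with_logits(logits, Y[b])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {s // cfg.batch_size}"
                )
            opt.zero_grad()
            model.backward_batch(cache, d_logits)
            opt.step()
            total_loss += loss * len(b)
        entry = {"epoch": epoch, "train_loss": total_loss / n}
        if valid_notes:
            gold = [v.gold_codes for v in valid_notes]
            probs = model.predict_proba(valid_notes)
            pred = [threshold_decode(p, model.label_space, tau) for p in probs]
            f1 = micro_scores(pred, gold).micro_f1
            entry["valid_micro_f1"] = f1
            if f1 > best_f1:
                best_f1, best_state = f1, model.state_dict()
        log.append(entry)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def rank_top_k(
    probabilities: np.ndarray, label_space: LabelSpace, k: int = 20
) -> list[str]:
    """Top-K codes by descending probability; ties broken by ascending
    label index. K beyond L returns all L codes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(probabilities, dtype=np.float64)
    order = np.lexsort((np.arange(p.size), -p))
    return [label_space.code(i) for i in order[: min(k, p.size)]]


def threshold_decode(
    probabilities: np.ndarray, label_space: LabelSpace, tau: float = 0.5
) -> set[str]:
    """Codes whose probability strictly exceeds tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    p = np.asarray(probabilities)
    return {label_space.code(i) for i in np.flatnonzero(p > tau)}
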