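"""Note/code-definition matching with additive attention highlighting.

The matcher is trained on (note, ICD-definition) pairs: one positive
pair per gold code of a note plus negatives sampled from the remaining
codes, up to a per-note budget (default 40 pairs in total).  The note
is encoded with an embedding layer and a BiGRU; the code definition is
encoded as the mean of its embedded tokens and used as the query of a
Bahdanau-style additive attention over the note states
(``score_i = v . tanh(W1 h_i + W2 q)``).  The attended context feeds a
single logistic output: the probability that the note matches the
code.  The attention weights themselves are the explanation — tokens
whose weight exceeds a threshold (default 1.5/n, i.e. one-and-a-half
times the uniform weight) are highlighted as the keywords supporting
the code, the view shown to trainee coders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
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
    clean_text,
    encode,
)


@dataclass
class AttentionPair:
    """One training example for the matcher; label 1 iff the code is gold."""

    note: LabeledNote
    code: str
    definition_tokens: list[str]
    label: int


@dataclass
class AttentionMap:
    """Per-token attention weights for one (note, code) pair; sums to 1."""

    note_id: str
    code: str
    tokens: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.tokens):
            raise ValueError("one weight per note token required")


@dataclass
class Highlight:
    positions: list[int]
    threshold: float


def build_pair_dataset(
    notes: Sequence[LabeledNote],
    label_space: LabelSpace,
    cap: int = 40,
    seed: int = 0,
    stopwords=None,
) -> list[AttentionPair]:
    """Positive pairs for every gold code plus sampled negatives.

    Per note the pair count is ``|gold| + min(cap - |gold|, L - |gold|)``;
    negatives are drawn uniformly without replacement from the non-gold
    codes.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    def_tokens = {
        c: clean_text(label_space.definition(c), stopwords) for c in label_space.codes
    }
    pairs: list[AttentionPair] = []
    all_codes = label_space.codes
    for note in notes:
        gold = sorted(c for c in note.gold_codes if c in label_space)
        if cap < len(gold):
            raise ValueError(
                f"cap={cap} smaller than gold-set size {len(gold)} for note {note.note_id}"
            )
        for c in gold:
            pairs.append(AttentionPair(note, c, def_tokens[c], 1))
        negatives = [c for c in all_codes if c not in note.gold_codes]
        n_neg = min(cap - len(gold), len(negatives))
        if n_neg > 0:
            chosen = rng.choice(len(negatives), size=n_neg, replace=False)
            for j in sorted(chosen):
                c = negatives[j]
                pairs.append(AttentionPair(note, c, def_tokens[c], 0))
    return pairs


def additive_attention(
    note_states: np.ndarray,
    query: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
    v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-example additive attention.

    ``score_i = v . tanh(W1 h_i + W2 q)``; weights are the softmax of
    the scores; the context is the weight-averaged state sequence.
    Returns ``(context, weights)``.
    """
    states = np.asarray(note_states, dtype=np.float64)
    if states.ndim != 2 or states.shape[0] == 0:
        raise ValueError("note_states must be a nonempty (n, d) sequence")
    scores = np.tanh(states @ w1 + np.asarray(query) @ w2) @ v
    e = np.exp(scores - scores.max())
    weights = e / e.sum()
    context = weights @ states
    return context, weights


@dataclass
class MatcherConfig:
    """Hyperparameters of the attention matcher."""

    embedding_dim: int = 48
    gru_hidden: int = 48
    attn_size: int = 64
    max_len: int = 64
    def_max_len: int = 16
    learning_rate: float = 1e-3
    epochs: int = 5
    batch_size: int = 64
    seed: int = 0


class MatcherModel:
    """Embedding + BiGRU note encoder, mean-embedded definition query,
    additive attention, logistic match output."""

    def __init__(
        self,
        config: MatcherConfig,
        vocab: Vocabulary,
        label_space: LabelSpace,
        embedding: EmbeddingMatrix | None = None,
    ):
        self.config = config
        self.vocab = vocab
        self.label_space = label_space
        rng = np.random.default_rng(config.seed)
        d, H = config.embedding_dim, config.gru_hidden
        if embedding is None:
            mat = rng.uniform(-0.05, 0.05, size=(len(vocab), d)).astype(np.float32)
            mat[PAD_INDEX] = 0.0
        else:
            mat = embedding.matrix
        self.embedding = nn.Embedding(mat, pad_index=PAD_INDEX)
        self.gru_f = nn.GRU(d, H, rng)
        self.gru_b = nn.GRU(d, H, rng)
        self.attn = nn.AdditiveAttention(2 * H, d, config.attn_size, rng)
        # logit from [context, query]: the concatenation keeps a direct
        # gradient path into the definition embedding while the note/code
        # interaction itself can only come through the attended context
        self.out = nn.Dense(2 * H + d, 1, rng)
        self.params = nn.collect_params(
            [
                ("embedding", self.embedding),
                ("gru_f", self.gru_f),
                ("gru_b", self.gru_b),
                ("attn", self.attn),
                ("out", self.out),
            ]
        )
        self._def_cache: dict[str, tuple[np.ndarray, int]] = {}

    # -- encoding -----------------------------------------------------------

    def encode_pairs(self, pairs: Sequence[AttentionPair]):
        cfg = self.config
        B = len(pairs)
        nidx = np.zeros((B, cfg.max_len), dtype=np.int64)
        nlen = np.zeros(B, dtype=np.int64)
        didx = np.zeros((B, cfg.def_max_len), dtype=np.int64)
        dlen = np.zeros(B, dtype=np.int64)
        y = np.zeros((B, 1), dtype=np.float32)
        for i, pair in enumerate(pairs):
            if not pair.note.tokens:
                raise ValueError(f"empty input: note {pair.note.note_id}")
            nidx[i], nlen[i] = encode(pair.note.tokens, self.vocab, cfg.max_len)
            didx[i], dlen[i] = encode(pair.definition_tokens, self.vocab, cfg.def_max_len)
            y[i, 0] = pair.label
        return nidx, nlen, didx, dlen, y

    # -- forward / backward -------------------------------------------------

    def forward_batch(self, nidx, nlen, didx, dlen):
        T = nidx.shape[1]
        nmask = (np.arange(T)[None, :] < nlen[:, None]).astype(np.float32)
        dmask = (np.arange(didx.shape[1])[None, :] < dlen[:, None]).astype(np.float32)
        X, ecx = self.embedding.forward(nidx)
        D, ecd = self.embedding.forward(didx)
        ddenom = np.maximum(dlen[:, None], 1).astype(np.float32)
        query = (D * dmask[:, :, None]).sum(axis=1) / ddenom
        x_rev = nn.reverse_padded(X, nlen)
        sf, cf = self.gru_f.forward(X, nmask)
        sb_rev, cb = self.gru_b.forward(x_rev, nmask)
        sb = nn.reverse_padded(sb_rev, nlen)  # align backward states to positions
        states = np.concatenate([sf, sb], axis=2)
        context, weights, ca = self.attn.forward(states, query, nmask)
        logits, co = self.out.forward(np.concatenate([context, query], axis=1))
        cache = (ecx, ecd, dmask, ddenom, nlen, cf, cb, ca, co)
        return logits, weights, cache

    def backward_batch(self, cache, d_logits):
        ecx, ecd, dmask, ddenom, nlen, cf, cb, ca, co = cache
        H2 = 2 * self.config.gru_hidden
        H = self.config.gru_hidden
        d_concat = self.out.backward(co, d_logits)
        d_context = d_concat[:, :H2]
        d_states, d_query = self.attn.backward(ca, d_context)
        d_query = d_query + d_concat[:, H2:]
        d_sf = d_states[:, :, :H]
        d_sb = d_states[:, :, H:]
        dX = self.gru_f.backward(cf, np.ascontiguousarray(d_sf))
        d_sb_rev = nn.reverse_padded(np.ascontiguousarray(d_sb), nlen)
        dX += nn.reverse_padded(self.gru_b.backward(cb, d_sb_rev), nlen)
        self.embedding.backward(ecx, dX)
        dD = (d_query[:, None, :] / ddenom[:, None]) * dmask[:, :, None]
        self.embedding.backward(ecd, dD.astype(np.float32))

    def predict_proba(self, pairs: Sequence[AttentionPair]) -> np.ndarray:
        nidx, nlen, didx, dlen, _ = self.encode_pairs(pairs)
        out = np.empty(len(pairs), dtype=np.float32)
        bs = self.config.batch_size
        for s in range(0, len(pairs), bs):
            logits, _, _ = self.forward_batch(
                nidx[s : s + bs], nlen[s : s + bs], didx[s : s + bs], dlen[s : s + bs]
            )
            out[s : s + bs] = nn._sigmoid(logits[:, 0])
        return out

    def attention_map(self, pair: AttentionPair) -> AttentionMap:
        nidx, nlen, didx, dlen, _ = self.encode_pairs([pair])
        _, weights, _ = self.forward_batch(nidx, nlen, didx, dlen)
        n = int(nlen[0])
        return AttentionMap(
            note_id=pair.note.note_id,
            code=pair.code,
            tokens=pair.note.tokens[:n],
            weights=weights[0, :n],
        )


def train_matcher(
    pairs: Sequence[AttentionPair],
    vocab: Vocabulary,
    label_space: LabelSpace,
    config: MatcherConfig | None = None,
    embedding: EmbeddingMatrix | None = None,
) -> tuple[MatcherModel, list[dict]]:
    """Train the matcher with binary cross-entropy + Adam; seeded.

    Raises on a single-class pair set (nothing to discriminate).
    """
    if config is None:
        config = MatcherConfig()
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValueError("degenerate labels: pairs must contain both classes")
    model = MatcherModel(config, vocab, label_space, embedding)
    nidx, nlen, didx, dlen, y = model.encode_pairs(pairs)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(pairs)
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, config.batch_size):
            b = order[s : s + config.batch_size]
            logits, _, cache = model.forward_batch(nidx[b], nlen[b], didx[b], dlen[b])
            loss, d_logits = nn.bce_with_logits(logits, y[b])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward_batch(cache, d_logits)
            opt.step()
            total += loss * len(b)
        log.append({"epoch": epoch, "train_loss": total / n})
    return model, log


def pair_f1(model: MatcherModel, pairs: Sequence[AttentionPair], tau: float = 0.5) -> float:
    """Per-pair binary F1 of match probabilities thresholded at tau."""
    probs = model.predict_proba(pairs)
    pred = probs > tau
    gold = np.array([p.label for p in pairs], dtype=bool)
    tp = int((pred & gold).sum())
    fp = int((pred & ~gold).sum())
    fn = int((~pred & gold).sum())
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def highlight_positions(weights: Sequence[float], threshold: float) -> list[int]:
    """Positions whose attention weight strictly exceeds the threshold."""
    return [i for i, w in enumerate(weights) if w > threshold]


def extract_highlights(
    matcher: MatcherModel,
    note: LabeledNote,
    code: str,
    threshold: float | None = None,
    stopwords=None,
) -> tuple[AttentionMap, Highlight]:
    """Attention map plus positions whose weight exceeds the threshold.

    The default threshold is length-adaptive, 1.5/n: one-and-a-half
    times the uniform weight over the note's n tokens.
    """
    if not note.tokens:
        raise ValueError("empty input: note has no tokens")
    if code not in matcher.label_space:
        raise KeyError(f"code {code!r} not in label space")
    pair = AttentionPair(
        note, code, clean_text(matcher.label_space.definition(code), stopwords), 0
    )
    amap = matcher.attention_map(pair)
    n = len(amap.tokens)
    if threshold is None:
        threshold = 1.5 / n
    positions = highlight_positions(amap.weights, threshold)
    return amap, Highlight(positions=positions, threshold=float(threshold))


def write_highlight_json(
    amap: AttentionMap, highlight: Highlight, path: str | Path
) -> None:
    payload = {
        "note_id": amap.note_id,
        "code": amap.code,
        "threshold": highlight.threshold,
        "tokens": [
            {
                "token": t,
                "weight": float(w),
                "highlighted": i in set(highlight.positions),
            }
            for i, (t, w) in enumerate(zip(amap.tokens, amap.weights))
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_highlight_html(
    amap: AttentionMap, highlight: Highlight, path: str | Path
) -> None:
    """Standalone heat-map page for visual inspection."""
    wmax = float(max(amap.weights.max(), 1e-9))
    spans = []
    hl = set(highlight.positions)
    for i, (tok, w) in enumerate(zip(amap.tokens, amap.weights)):
        alpha = float(w) / wmax
        border = "border:1px solid #c00;" if i in hl else ""
        spans.append(
            f'<span title="{float(w):.4f}" style="background:rgba(255,160,0,{alpha:.3f});{border}'
            f'padding:1px 2px;margin:1px;border-radius:2px">{tok}</span>'
        )
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{amap.note_id} / {amap.code}</title></head>"
        f"<body><h3>{amap.note_id} &rarr; {amap.code}</h3><p>"
        + " ".join(spans)
        + "</p></body></html>"
    )
    Path(path).write_text(html)
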