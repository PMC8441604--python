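"""Word-vector providers for the classifier and matcher.

Static vectors live in an :class:`EmbeddingMatrix` aligned with a
vocabulary (PAD row pinned to zero); they can be randomly initialized
and trained, or loaded from the de-facto standard whitespace-delimited
word-vector text format (one line per word, optional ``V d`` header).

Contextual embedders are not bundled: any callable mapping an index
sequence to a ``(length, d)`` array satisfies the provider contract, so
externally computed contextual vectors can be plugged in unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from icdcoder.text_pipeline import PAD_INDEX, Vocabulary

logger = logging.getLogger(__name__)


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Maps a token-index sequence to one d-vector per position."""

    dim: int

    def __call__(self, indices: Sequence[int]) -> np.ndarray: ...


@dataclass
class EmbeddingMatrix:
    """Vocabulary-aligned |V| x d matrix of word vectors.

    Position-independent: row i is the vector of vocabulary index i,
    wherever it occurs.  The PAD row is all zeros.
    """

    matrix: np.ndarray
    vocab: Vocabulary
    trainable: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.vocab):
            raise ValueError("row count must equal vocabulary size")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __call__(self, indices: Sequence[int]) -> np.ndarray:
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.matrix.shape[0]):
            raise IndexError("token index out of range for embedding matrix")
        return self.matrix[idx]


def init_random_embeddings(vocab: Vocabulary, d: int, seed: int = 0) -> EmbeddingMatrix:
    """Uniform[-0.05, 0.05] init, PAD row zeroed, trainable."""
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    mat = rng.uniform(-0.05, 0.05, size=(len(vocab), d)).astype(np.float32)
    mat[PAD_INDEX] = 0.0
    return EmbeddingMatrix(mat, vocab, trainable=True)


def load_vector_file(
    path: str | Path, vocab: Vocabulary, seed: int = 0
) -> EmbeddingMatrix:
    """Load pretrained static vectors for a vocabulary.

    In-vocabulary words take their file vector; vocabulary words absent
    from the file keep a random-initialized row (so training can still
    specialize them); PAD is zeroed.  An optional first header line
    ``V d`` is tolerated.  Inconsistent vector lengths raise.
    """
    vectors: dict[str, np.ndarray] = {}
    d: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:  # header "V d"
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            word, vals = parts[0], parts[1:]
            vec = np.array([float(v) for v in vals], dtype=np.float32)
            if d is None:
                d = vec.size
                if d == 0:
                    raise ValueError(f"line {lineno}: no vector components")
            elif vec.size != d:
                raise ValueError(
                    f"dimension mismatch at line {lineno}: got {vec.size}, expected {d}"
                )
            vectors[word] = vec
    if d is None:
        raise ValueError("vector file contains no vectors")

    emb = init_random_embeddings(vocab, d, seed=seed)
    hits = 0
    for tok in vocab.tokens():
        if tok in vectors:
            emb.matrix[vocab[tok]] = vectors[tok]
            hits += 1
    emb.matrix[PAD_INDEX] = 0.0
    logger.info(
        "loaded vectors for %d/%d vocabulary words (%.1f%% coverage)",
        hits, len(vocab), 100.0 * hits / max(len(vocab), 1),
    )
    return emb


def save_vector_file(emb: EmbeddingMatrix, path: str | Path, header: bool = False) -> None:
    """Write the matrix in the word-vector text format, losslessly.

    Values are written with ``repr`` of the exact float so a reload
    reproduces the matrix bit for bit.
    """
    toks = emb.vocab.tokens()
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(toks)} {emb.dim}\n")
        for i, tok in enumerate(toks):
            vals = " ".join(repr(float(v)) for v in emb.matrix[i])
            fh.write(f"{tok} {vals}\n")


def lookup_sequence(provider: EmbeddingProvider, indices: Sequence[int]) -> np.ndarray:
    """One d-vector per position, via any provider honoring the contract."""
    out = np.asarray(provider(indices), dtype=np.float32)
    if out.shape != (len(indices), provider.dim):
        raise ValueError(
            f"provider returned shape {out.shape}, expected ({len(indices)}, {provider.dim})"
        )
    return out


def hashed_contextual_provider(vocab: Vocabulary, d: int) -> Callable:
    """Deterministic dummy *contextual* provider for tests and demos.

    Each position's vector is a hash of the token index and its
    immediate neighbors, so the same token gets different vectors in
    different contexts — enough to prove downstream models are
    provider-agnostic without shipping a language model.
    """

    def provide(indices: Sequence[int]) -> np.ndarray:
        idx = np.asarray(indices, dtype=np.int64)
        n = idx.size
        out = np.empty((n, d), dtype=np.float32)
        left = np.concatenate(([-1], idx[:-1]))
        right = np.concatenate((idx[1:], [-1]))
        for i in range(n):
            h = (idx[i] * 1_000_003 + left[i] * 10_007 + right[i] * 101) % (2**31)
            rng = np.random.default_rng(h)
            out[i] = rng.standard_normal(d, dtype=np.float32) * 0.1
        out[idx == PAD_INDEX] = 0.0
        return out

    provide.dim = d
    return provide
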