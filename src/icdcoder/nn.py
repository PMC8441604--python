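"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly the pieces the coding models need — trainable
embedding lookup, a masked (variable-length) GRU run forward or over
reversed sequences to form a BiGRU, dense layers, PReLU, inverted
dropout, additive attention, sigmoid binary cross-entropy, and Adam.
Layers follow the usual convention: ``forward`` returns outputs plus an
opaque cache, ``backward`` consumes the cache and upstream gradients,
accumulates parameter gradients in-place, and returns input gradients.
All gradients are exact (they are verified against finite differences
in the test-suite).

Arrays are float32; shapes are written as B=batch, T=time, D=input
dim, H=hidden dim.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

F = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape).astype(F)


class Embedding:
    """Trainable lookup table; row ``pad_index`` is pinned to zero."""

    def __init__(self, matrix: np.ndarray, pad_index: int = 0, trainable: bool = True):
        self.weight = Param(matrix)
        self.pad_index = pad_index
        self.trainable = trainable

    def forward(self, idx: np.ndarray):
        return self.weight.value[idx], idx

    def backward(self, cache, d_out: np.ndarray) -> None:
        if not self.trainable:
            return
        idx = cache
        d = self.weight.value.shape[1]
        np.add.at(self.weight.grad, idx.ravel(), d_out.reshape(-1, d))
        self.weight.grad[self.pad_index] = 0.0

    def params(self) -> dict[str, Param]:
        return {"weight": self.weight} if self.trainable else {}


class Dense:
    """Affine layer y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in)
        self.W = Param(_uniform(rng, (d_in, d_out), scale))
        self.b = Param(np.zeros(d_out, dtype=F))

    def forward(self, x: np.ndarray):
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, d_out: np.ndarray) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ d_out
        self.b.grad += d_out.sum(axis=0)
        return d_out @ self.W.value.T

    def params(self) -> dict[str, Param]:
        return {"W": self.W, "b": self.b}


class PReLU:
    """Parametric ReLU with a single learnable slope (init 0.25)."""

    def __init__(self, init: float = 0.25):
        self.a = Param(np.array([init], dtype=F))

    def forward(self, x: np.ndarray):
        a = self.a.value[0]
        return np.where(x > 0, x, a * x), x

    def backward(self, cache, d_out: np.ndarray) -> np.ndarray:
        x = cache
        neg = x <= 0
        self.a.grad += np.array([(d_out * np.where(neg, x, 0.0)).sum()], dtype=F)
        return d_out * np.where(neg, self.a.value[0], 1.0)

    def params(self) -> dict[str, Param]:
        return {"a": self.a}


class Dropout:
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None):
        if rng is None or self.rate == 0.0:
            return x, None
        keep = (rng.random(x.shape) >= self.rate).astype(F) / F(1.0 - self.rate)
        return x * keep, keep

    def backward(self, cache, d_out: np.ndarray) -> np.ndarray:
        if cache is None:
            return d_out
        return d_out * cache


class GRU:
    """Single-direction GRU over padded sequences with a validity mask.

    Gate equations (PyTorch convention, with the reset gate applied to
    the hidden contribution of the candidate state)::

        z = sigmoid(x Wz + h Uz + bz)
        r = sigmoid(x Wr + h Ur + br)
        n = tanh(x Wn + bn + r * (h Un + cn))
        h' = (1 - z) * n + z * h

    At padded positions (mask 0) the state is carried through
    unchanged, so the output at the last time step equals the state at
    each sequence's true length regardless of padding.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_in, self.d_hidden = d_in, d_hidden
        s = 1.0 / np.sqrt(d_hidden)
        p = {}
        for g in ("z", "r", "n"):
            p["W" + g] = Param(_uniform(rng, (d_in, d_hidden), s))
            p["U" + g] = Param(_uniform(rng, (d_hidden, d_hidden), s))
            p["b" + g] = Param(np.zeros(d_hidden, dtype=F))
        p["cn"] = Param(np.zeros(d_hidden, dtype=F))  # hidden-side bias of n
        self._p = p

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x: (B,T,D); mask: (B,T) in {0,1}. Returns states (B,T,H) + cache."""
        p = self._p
        B, T, _ = x.shape
        H = self.d_hidden
        h = np.zeros((B, H), dtype=F)
        states = np.empty((B, T, H), dtype=F)
        steps = []
        for t in range(T):
            xt = x[:, t]
            m = mask[:, t, None].astype(F)
            z = _sigmoid(xt @ p["Wz"].value + h @ p["Uz"].value + p["bz"].value)
            r = _sigmoid(xt @ p["Wr"].value + h @ p["Ur"].value + p["br"].value)
            hh = h @ p["Un"].value + p["cn"].value
            n = np.tanh(xt @ p["Wn"].value + p["bn"].value + r * hh)
            h_new = (1.0 - z) * n + z * h
            h_out = m * h_new + (1.0 - m) * h
            steps.append((xt, h, z, r, n, hh, m))
            h = h_out
            states[:, t] = h
        return states, steps

    def backward(self, cache, d_states: np.ndarray) -> np.ndarray:
        """d_states: (B,T,H) gradient wrt every output state."""
        p = self._p
        steps = cache
        B, T, _ = d_states.shape
        dx = np.zeros((B, T, self.d_in), dtype=F)
        dh = np.zeros((B, self.d_hidden), dtype=F)
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, n, hh, m = steps[t]
            dh = dh + d_states[:, t]
            dhi = dh * m  # through the update branch
            dh_prev = dh * (1.0 - m)  # pad positions copy the state
            dz = dhi * (h_prev - n)
            dn = dhi * (1.0 - z)
            dh_prev += dhi * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * hh
            dhh = dn_pre * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            p["Wn"].grad += xt.T @ dn_pre
            p["bn"].grad += dn_pre.sum(axis=0)
            p["Un"].grad += h_prev.T @ dhh
            p["cn"].grad += dhh.sum(axis=0)
            p["Wz"].grad += xt.T @ dz_pre
            p["Uz"].grad += h_prev.T @ dz_pre
            p["bz"].grad += dz_pre.sum(axis=0)
            p["Wr"].grad += xt.T @ dr_pre
            p["Ur"].grad += h_prev.T @ dr_pre
            p["br"].grad += dr_pre.sum(axis=0)
            dh_prev += dhh @ p["Un"].value.T
            dh_prev += dz_pre @ p["Uz"].value.T + dr_pre @ p["Ur"].value.T
            dx[:, t] = (
                dz_pre @ p["Wz"].value.T
                + dr_pre @ p["Wr"].value.T
                + dn_pre @ p["Wn"].value.T
            )
            dh = dh_prev
        return dx

    def params(self) -> dict[str, Param]:
        return dict(self._p)


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length; padding stays at the end.

    Works on (B,T) index arrays and (B,T,D) feature arrays alike, and is
    an involution, so it also un-reverses backward-direction states.
    """
    out = x.copy()
    for i, L in enumerate(lengths):
        out[i, :L] = x[i, :L][::-1]
    return out


class AdditiveAttention:
    """Bahdanau-style attention: score_i = v . tanh(W1 h_i + W2 q).

    Weights are a masked softmax over valid positions; the context is
    the weight-averaged state sequence.
    """

    def __init__(self, d_state: int, d_query: int, d_attn: int, rng: np.random.Generator):
        s1 = 1.0 / np.sqrt(d_state)
        s2 = 1.0 / np.sqrt(d_query)
        sv = 1.0 / np.sqrt(d_attn)
        self.W1 = Param(_uniform(rng, (d_state, d_attn), s1))
        self.W2 = Param(_uniform(rng, (d_query, d_attn), s2))
        self.v = Param(_uniform(rng, (d_attn,), sv))

    def forward(self, states: np.ndarray, query: np.ndarray, mask: np.ndarray):
        """states: (B,T,H); query: (B,Q); mask: (B,T). Returns
        (context (B,H), weights (B,T), cache)."""
        u = np.tanh(states @ self.W1.value + (query @ self.W2.value)[:, None, :])
        scores = u @ self.v.value  # (B,T)
        neg = np.finfo(F).min / 4
        scores = np.where(mask > 0, scores, neg)
        smax = scores.max(axis=1, keepdims=True)
        e = np.exp(scores - smax) * (mask > 0)
        weights = (e / e.sum(axis=1, keepdims=True)).astype(F)
        context = np.einsum("bt,bth->bh", weights, states).astype(F)
        return context, weights, (states, query, u, weights, mask)

    def backward(self, cache, d_context: np.ndarray):
        states, query, u, w, mask = cache
        d_states = w[:, :, None] * d_context[:, None, :]
        d_alpha = np.einsum("bh,bth->bt", d_context, states)
        # softmax Jacobian
        d_scores = w * (d_alpha - (w * d_alpha).sum(axis=1, keepdims=True))
        d_scores = d_scores * (mask > 0)
        self.v.grad += np.einsum("bta,bt->a", u, d_scores)
        du = d_scores[:, :, None] * self.v.value
        du_pre = du * (1.0 - u * u)
        self.W1.grad += np.einsum("bth,bta->ha", states, du_pre)
        d_states += du_pre @ self.W1.value.T
        du_sum = du_pre.sum(axis=1)  # query is broadcast over time
        self.W2.grad += query.T @ du_sum
        d_query = du_sum @ self.W2.value.T
        return d_states.astype(F), d_query.astype(F)

    def params(self) -> dict[str, Param]:
        return {"W1": self.W1, "W2": self.W2, "v": self.v}


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean elementwise sigmoid binary cross-entropy.

    Returns (loss, d_logits); numerically stable for large |logits|.
    """
    x, y = logits, targets
    loss = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))
    d = (_sigmoid(x) - y) / x.size
    return float(loss.mean()), d.astype(F)


class Adam:
    """Adam optimizer over a flat dict of Params."""

    def __init__(
        self,
        params: dict[str, Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def collect_params(named_layers: Iterable[tuple[str, object]]) -> dict[str, Param]:
    """Flatten layer parameter dicts into '<layer>.<name>' keys."""
    flat: dict[str, Param] = {}
    for prefix, layer in named_layers:
        for name, p in layer.params().items():
            flat[f"{prefix}.{name}"] = p
    return flat
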