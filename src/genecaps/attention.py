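"""Multi-head scaled dot-product self-attention over capsule outputs.

The J routed capsules form a length-J "sequence" of d_c-dimensional
tokens.  Each head projects them to queries, keys and values with
full-width d_c x d_c maps (Q = W_q V', K = W_k V', V = W_v V'), applies
softmax(Q K^T / sqrt(d_k)) V row-wise, and the head outputs are
concatenated and flattened into a single feature vector for the dense
sigmoid head.  No positional encoding, feed-forward block or layer norm:
capsules are an unordered set mixed purely by learned relevance.
"""

from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np

from .autodiff import Tensor, softmax

ACTIVATIONS = ("sigmoid", "relu", "tanh")
ArrayLike = Union[np.ndarray, Tensor]


@dataclasses.dataclass
class AttentionParams:
    """Per-head projections stacked as (n_heads, d_c, d_c)."""

    W_q: Tensor
    W_k: Tensor
    W_v: Tensor
    d_k: int = 16

    def __post_init__(self):
        shapes = {t.shape for t in (self.W_q, self.W_k, self.W_v)}
        if len(shapes) != 1 or self.W_q.ndim != 3:
            raise ValueError("W_q/W_k/W_v must share shape (n_heads, d_c, d_c)")
        if self.d_k <= 0:
            raise ValueError("d_k must be positive")

    @property
    def n_heads(self) -> int:
        return self.W_q.shape[0]

    @property
    def d_c(self) -> int:
        return self.W_q.shape[1]

    @classmethod
    def initialize(cls, rng: np.random.Generator, d_c: int = 16,
                   n_heads: int = 4, d_k: int | None = None
                   ) -> "AttentionParams":
        if n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        lim = 1.0 / np.sqrt(d_c)

        def draw():
            return Tensor(rng.uniform(-lim, lim, (n_heads, d_c, d_c)),
                          requires_grad=True)

        return cls(draw(), draw(), draw(), d_k=d_k if d_k else d_c)

    def tensors(self) -> list[Tensor]:
        return [self.W_q, self.W_k, self.W_v]

    def copy(self) -> "AttentionParams":
        return AttentionParams(*(Tensor(t.data.copy(), requires_grad=True)
                                 for t in self.tensors()), d_k=self.d_k)


@dataclasses.dataclass
class ClassifierHeadParams:
    """Dense hidden layer (default 150 neurons) plus a logistic output unit."""

    hidden_weights: Tensor   # (n_hidden, n_in)
    hidden_bias: Tensor      # (n_hidden,)
    output_weights: Tensor   # (1, n_hidden)
    output_bias: Tensor      # (1,)

    def __post_init__(self):
        h, n_in = self.hidden_weights.shape
        if self.hidden_bias.shape != (h,) or \
                self.output_weights.shape != (1, h) or \
                self.output_bias.shape != (1,):
            raise ValueError("inconsistent head shapes")

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @classmethod
    def initialize(cls, rng: np.random.Generator, n_inputs: int,
                   n_hidden: int = 150) -> "ClassifierHeadParams":
        lim1 = 1.0 / np.sqrt(n_inputs)
        lim2 = 1.0 / np.sqrt(n_hidden)
        return cls(
            Tensor(rng.uniform(-lim1, lim1, (n_hidden, n_inputs)),
                   requires_grad=True),
            Tensor(np.zeros(n_hidden), requires_grad=True),
            Tensor(rng.uniform(-lim2, lim2, (1, n_hidden)),
                   requires_grad=True),
            Tensor(np.zeros(1), requires_grad=True))

    def tensors(self) -> list[Tensor]:
        return [self.hidden_weights, self.hidden_bias,
                self.output_weights, self.output_bias]

    def copy(self) -> "ClassifierHeadParams":
        return ClassifierHeadParams(*(Tensor(t.data.copy(),
                                             requires_grad=True)
                                      for t in self.tensors()))


def scaled_dot_attention(Q: ArrayLike, K: ArrayLike, V: ArrayLike,
                         d_k: int) -> ArrayLike:
    """softmax(Q K^T / sqrt(d_k)) V, softmax applied row-wise.

    Accepts plain arrays (returns an array) or tensors (stays on the
    autodiff graph).  Leading batch/head axes broadcast.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    is_tensor = any(isinstance(a, Tensor) for a in (Q, K, V))
    Qt, Kt, Vt = (a if isinstance(a, Tensor) else Tensor(np.atleast_2d(a))
                  for a in (Q, K, V))
    scores = (Qt @ Kt.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    out = softmax(scores, axis=-1) @ Vt
    return out if is_tensor else out.data


def attention_weights(Q: np.ndarray, K: np.ndarray, d_k: int) -> np.ndarray:
    """The row-stochastic attention matrix softmax(Q K^T / sqrt(d_k))."""
    scores = (np.atleast_2d(Q) @ np.atleast_2d(K).swapaxes(-1, -2)) \
        / np.sqrt(d_k)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def multi_head(v_prime: ArrayLike, params: AttentionParams) -> Tensor:
    """All heads on (batch, J, d_c) capsules -> (batch, n_heads*J*d_c).

    Heads are concatenated in index order and each head's (J, d_c) block
    is flattened row-major.
    """
    vt = v_prime if isinstance(v_prime, Tensor) else Tensor(v_prime)
    if vt.ndim == 2:
        vt = vt.reshape(1, *vt.shape)
    B, J, d_c = vt.shape
    if d_c != params.d_c:
        raise ValueError(f"capsule dim {d_c} != attention d_c {params.d_c}")
    H = params.n_heads
    v4 = vt.reshape(B, 1, J, d_c)
    Q = v4 @ params.W_q.swapaxes(-1, -2)  # (B, H, J, d_c)
    K = v4 @ params.W_k.swapaxes(-1, -2)
    V = v4 @ params.W_v.swapaxes(-1, -2)
    Z = scaled_dot_attention(Q, K, V, params.d_k)  # (B, H, J, d_c)
    return Z.reshape(B, H * J * d_c)


def classify(z: ArrayLike, head: ClassifierHeadParams,
             activation: str = "sigmoid") -> Tensor:
    """Dense hidden layer + logistic output; probabilities in (0, 1)."""
    if activation not in ACTIVATIONS:
        raise ValueError(f"activation must be one of {ACTIVATIONS}")
    zt = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(z))
    if zt.ndim == 1:
        zt = zt.reshape(1, -1)
    if zt.shape[-1] != head.n_inputs:
        raise ValueError(f"feature length {zt.shape[-1]} != head input "
                         f"dim {head.n_inputs}")
    pre = zt @ head.hidden_weights.swapaxes(0, 1) + head.hidden_bias
    hidden = getattr(pre, activation)()
    logits = hidden @ head.output_weights.swapaxes(0, 1) + head.output_bias
    # keep probabilities strictly inside (0, 1) even at float saturation
    return logits.sigmoid().clip(1e-12, 1.0 - 1e-12).reshape(zt.shape[0])
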