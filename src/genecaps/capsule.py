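"""Two-layer capsule encoder with dynamic routing-by-agreement.

A gene-expression vector ``x`` (length ``n``) is projected by ``P``
independent weight matrices into primary capsules ``u_i = W_i x``.
Prediction vectors ``uhat_{j|i} = w_ij u_i`` vote for ``J`` output
capsules; dynamic routing sets coupling coefficients
``c_ij = softmax(b_ij)`` by iterated agreement (dot products between
votes and squashed outputs), starting from ``b = 0``.  The squashing
nonlinearity bounds each capsule norm in [0, 1) while preserving its
direction, so a capsule's length reads as the activity of the gene
program it detects.

Coupling coefficients are recomputed on every forward pass and are *not*
part of the trainable parameter set: gradients flow through the final
weighted sum into the votes, never through the routing logits.  The
softmax axis is configurable — ``input_capsules`` normalizes over i
(the printed form of the coupling coefficient), ``output_capsules`` over
j (the original routing-by-agreement convention).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .autodiff import Tensor

SQUASH_EPS = 1e-8
SOFTMAX_AXES = ("input_capsules", "output_capsules")


@dataclasses.dataclass
class CapsuleEncoderParams:
    """Primary projections ``W_i`` and routing transforms ``w_ij``.

    ``primary_weights`` is stacked (P, d_p, n_genes); ``routing_weights``
    is (P, J, d_c, d_p).  Defaults follow the reference architecture:
    8 primary capsules routed into 20 output capsules of 16 dimensions.
    """

    primary_weights: Tensor
    routing_weights: Tensor

    def __post_init__(self):
        if self.primary_weights.ndim != 3 or self.routing_weights.ndim != 4:
            raise ValueError("primary_weights must be (P, d_p, n_genes) and "
                             "routing_weights (P, J, d_c, d_p)")
        P, d_p, _ = self.primary_weights.shape
        Pw, J, d_c, d_pw = self.routing_weights.shape
        if Pw != P or d_pw != d_p:
            raise ValueError(
                f"routing_weights {self.routing_weights.shape} inconsistent "
                f"with primary_weights {self.primary_weights.shape}")
        if P < 1 or J < 1:
            raise ValueError("need at least one capsule per layer")
        for t in (self.primary_weights, self.routing_weights):
            if not np.all(np.isfinite(t.data)):
                raise ValueError("encoder weights contain NaN/Inf")

    @property
    def n_primary(self) -> int:
        return self.primary_weights.shape[0]

    @property
    def n_capsules(self) -> int:
        return self.routing_weights.shape[1]

    @property
    def d_primary(self) -> int:
        return self.primary_weights.shape[1]

    @property
    def d_capsule(self) -> int:
        return self.routing_weights.shape[2]

    @property
    def n_genes(self) -> int:
        return self.primary_weights.shape[2]

    @classmethod
    def initialize(cls, n_genes: int, rng: np.random.Generator,
                   n_primary: int = 8, n_capsules: int = 20,
                   d_primary: int = 16, d_capsule: int = 16
                   ) -> "CapsuleEncoderParams":
        """Fan-in scaled uniform initialization under ``rng``."""
        lim_w = 1.0 / np.sqrt(n_genes)
        lim_r = 1.0 / np.sqrt(d_primary)
        W = rng.uniform(-lim_w, lim_w, (n_primary, d_primary, n_genes))
        w = rng.uniform(-lim_r, lim_r,
                        (n_primary, n_capsules, d_capsule, d_primary))
        return cls(Tensor(W, requires_grad=True),
                   Tensor(w, requires_grad=True))

    def tensors(self) -> list[Tensor]:
        return [self.primary_weights, self.routing_weights]

    def copy(self) -> "CapsuleEncoderParams":
        return CapsuleEncoderParams(
            Tensor(self.primary_weights.data.copy(), requires_grad=True),
            Tensor(self.routing_weights.data.copy(), requires_grad=True))


@dataclasses.dataclass
class RoutingState:
    """Snapshot of one routing iteration (plain arrays, detached)."""

    b: np.ndarray
    c: np.ndarray
    s: np.ndarray
    v: np.ndarray
    iteration: int


ArrayLike = Union[np.ndarray, Tensor]


def squash(s: ArrayLike, axis: int = -1) -> ArrayLike:
    """``v = (|s|^2 / (1 + |s|^2)) * s / |s|`` along ``axis``.

    The output norm is |s|^2/(1+|s|^2), strictly inside [0, 1), and the
    direction of ``s`` is preserved.  An epsilon in the norm denominator
    maps the zero vector to the zero vector.
    """
    if isinstance(s, Tensor):
        if not np.all(np.isfinite(s.data)):
            raise ValueError("squash input contains NaN/Inf")
        n2 = (s * s).sum(axis=axis, keepdims=True)
        norm = n2.sqrt()
        return s * (n2 / (1.0 + n2) / (norm + SQUASH_EPS))
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("squash input contains NaN/Inf")
    n2 = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(n2)
    return s * (n2 / (1.0 + n2) / (norm + SQUASH_EPS))


def primary_capsules(x: ArrayLike, params: CapsuleEncoderParams) -> Tensor:
    """``u_i = W_i x`` for every primary capsule; batched.

    ``x`` is (n_genes,) or (batch, n_genes); the result is
    (batch, P, d_p).
    """
    xt = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
    if xt.ndim == 1:
        xt = xt.reshape(1, -1)
    n = params.n_genes
    if xt.shape[-1] != n:
        raise ValueError(f"expected gene vectors of length {n}, "
                         f"got {xt.shape[-1]}")
    P, d_p = params.n_primary, params.d_primary
    W_flat = params.primary_weights.reshape(P * d_p, n)  # (P*d_p, n)
    u = xt @ W_flat.swapaxes(0, 1)                       # (B, P*d_p)
    return u.reshape(xt.shape[0], P, d_p)


def prediction_vectors(u: ArrayLike, params: CapsuleEncoderParams) -> Tensor:
    """Votes ``uhat_{j|i} = w_ij u_i``; result (batch, P, J, d_c)."""
    ut = u if isinstance(u, Tensor) else Tensor(u)
    if ut.ndim == 2:  # (P, d_p) single sample
        ut = ut.reshape(1, *ut.shape)
    B, P, d_p = ut.shape
    if (P, d_p) != (params.n_primary, params.d_primary):
        raise ValueError(f"primary capsules {(P, d_p)} do not match params "
                         f"{(params.n_primary, params.d_primary)}")
    # (P,J,d_c,d_p) @ (B,P,1,d_p,1) -> (B,P,J,d_c,1)
    uhat = params.routing_weights @ ut.reshape(B, P, 1, d_p, 1)
    return uhat.reshape(B, P, params.n_capsules, params.d_capsule)


def _softmax_np(b: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(b - b.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def dynamic_routing(uhat: ArrayLike, n_iterations: int = 3,
                    softmax_axis: str = "input_capsules",
                    collect_trace: bool = False
                    ) -> tuple[ArrayLike, list[RoutingState]]:
    """Routing-by-agreement from zero logits.

    Each iteration computes ``c = softmax(b)`` along the configured axis,
    the weighted vote sum ``s_j = sum_i c_ij uhat_{j|i}``, the squashed
    output ``v_j``, and the agreement update ``b_ij += uhat_{j|i} . v_j``.
    The output after the final iteration is returned together with a
    per-iteration trace of detached (b, c, s, v) snapshots when requested.

    Coupling coefficients are treated as constants by autodiff: gradients
    reach ``uhat`` only through the final weighted sum and squash.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if softmax_axis not in SOFTMAX_AXES:
        raise ValueError(f"softmax_axis must be one of {SOFTMAX_AXES}")
    is_tensor = isinstance(uhat, Tensor)
    ut = uhat if is_tensor else Tensor(np.asarray(uhat, dtype=np.float64))
    squeeze = ut.ndim == 3
    if squeeze:  # single sample (P, J, d_c)
        ut = ut.reshape(1, *ut.shape)
    B, P, J, d_c = ut.shape
    axis = 1 if softmax_axis == "input_capsules" else 2
    uh = ut.data  # detached view for the routing loop
    b = np.zeros((B, P, J))
    trace: list[RoutingState] = []
    v_np = None
    for t in range(1, n_iterations + 1):
        c = _softmax_np(b, axis=axis)  # (B, P, J)
        s_np = np.einsum("bpj,bpjc->bjc", c, uh)
        v_np = squash(s_np)
        if not np.all(np.isfinite(v_np)):
            raise FloatingPointError(
                f"non-finite capsule output at routing iteration {t}")
        b = b + np.einsum("bpjc,bjc->bpj", uh, v_np)
        if collect_trace:
            trace.append(RoutingState(b=b.copy(), c=c.copy(), s=s_np.copy(),
                                      v=np.asarray(v_np).copy(), iteration=t))
        if t == n_iterations:
            # final iteration again, on the graph, with c as a constant
            s = (ut * Tensor(c[..., None])).sum(axis=1)
            v = squash(s)
    out: ArrayLike = v if is_tensor else np.asarray(v_np)
    if squeeze:
        out = out.reshape(J, d_c) if is_tensor else out.reshape(J, d_c)
    if squeeze and collect_trace:
        trace = [RoutingState(r.b[0], r.c[0], r.s[0], r.v[0], r.iteration)
                 for r in trace]
    return out, trace


def encode(x: ArrayLike, params: CapsuleEncoderParams,
           n_iterations: int = 3, softmax_axis: str = "input_capsules"
           ) -> Tensor:
    """Full encoder: genes -> primary capsules -> routed capsules.

    ``x`` is (batch, n_genes); the result is (batch, J, d_c).  Batch
    processing is elementwise identical to per-sample processing because
    every step is per-sample.
    """
    u = primary_capsules(x, params)
    uhat = prediction_vectors(u, params)
    v, _ = dynamic_routing(uhat, n_iterations=n_iterations,
                           softmax_axis=softmax_axis)
    return v


def capsule_norms(v: ArrayLike) -> np.ndarray:
    """Per-capsule activity lengths ||v_j|| as a plain array."""
    arr = v.data if isinstance(v, Tensor) else np.asarray(v)
    return np.linalg.norm(arr, axis=-1)


# ---------------------------------------------------------------------------
# checkpoint serialization helpers (one .npy per tensor + JSON manifest)
# ---------------------------------------------------------------------------

def save_tensors(directory, tensors: dict[str, Tensor],
                 manifest_extra: dict) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"tensors": {}, **manifest_extra}
    for name, t in tensors.items():
        np.save(directory / f"{name}.npy", t.data)
        manifest["tensors"][name] = list(t.shape)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_tensors(directory, names: Sequence[str]) -> dict[str, Tensor]:
    directory = Path(directory)
    return {name: Tensor(np.load(directory / f"{name}.npy"),
                         requires_grad=True) for name in names}
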