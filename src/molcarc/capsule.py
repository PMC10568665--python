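"""Capsule layer with non-iterative self-attention routing and margin loss.

Input capsules u_i (16 capsules of dimension 8) are linearly transformed by
per-pair weight matrices into vote vectors

    u_hat[i, j] = u_i^T W[i, j]                     (votes, one per output j)

Self-attention routing then computes, in a single pass per output capsule j,
a vote-similarity matrix A_j = U_j U_j^T / D (D = 128 stabilises the scale
against the learnable log-priors B), row-sums it, and softmax-normalises
across output capsules to obtain coupling coefficients C. The output
capsule pre-activation is the (C + B)-weighted vote sum,

    s_j = sum_i (C[i, j] + B[i, j]) u_hat[i, j],     v_j = squash(s_j),

with the bounded activation squash(s) = (1 - e^{-||s||}) s / ||s||, whose
length 1 - e^{-||s||} plays the role of a class probability. Training
minimises the per-class margin loss

    L_k = T_k max(0, m+ - ||v_k||)^2 + lambda (1 - T_k) max(0, ||v_k|| - m-)^2

with m+ = 0.9, m- = 0.1, lambda = 0.5. Iterative dynamic routing (3 rounds)
is kept as the no-attention ablation path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["CapsuleLayerParams", "LossConfig", "squash", "capsule_lengths",
           "compute_votes", "self_attention_routing", "dynamic_routing",
           "margin_loss", "CapsuleLayer"]

_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        assert 0 < self.m_minus < self.m_plus < 1 and self.lam > 0


@dataclass(frozen=True)
class CapsuleLayerParams:
    """Architecture constants of the capsule head."""

    n_in: int = 16
    d_in: int = 8
    n_out: int = 2
    d_out: int = 2
    attention_stabilizer: float = 128.0   # the divisor D of the similarity matrix
    sqrt_stabilizer: bool = False         # divide by sqrt(D) instead of D

    def __post_init__(self):
        assert self.attention_stabilizer > 0


def squash(s: Tensor | np.ndarray, axis: int = -1) -> Tensor:
    """Bounded activation: same direction, length 1 - e^{-||s||} in [0, 1).

    The zero vector maps to the zero vector (the continuous limit).
    """
    s = s if isinstance(s, Tensor) else Tensor(s)
    norm = ((s * s).sum(axis=axis, keepdims=True) + _EPS).sqrt()
    scale = (1.0 - (-norm).exp()) / norm
    return s * scale


def capsule_lengths(v: Tensor, axis: int = -1) -> Tensor:
    return ((v * v).sum(axis=axis) + _EPS).sqrt()


def compute_votes(u: Tensor, W: Tensor) -> Tensor:
    """Votes u_hat[..., i, j, :] = u[..., i, :] @ W[i, j].

    ``u``: (batch, n_in, d_in); ``W``: (n_in, n_out, d_in, d_out).
    Returns (batch, n_in, n_out, d_out).
    """
    if u.shape[-1] != W.shape[2]:
        raise ValueError(f"capsule dim {u.shape[-1]} != weight d_in {W.shape[2]}")
    b, n_in, d_in = u.shape
    # (b, n_in, 1, 1, d_in) @ (n_in, n_out, d_in, d_out) -> broadcast matmul
    u5 = u.reshape(b, n_in, 1, 1, d_in)
    out = u5 @ W
    return out.reshape(b, n_in, W.shape[1], W.shape[3])


def self_attention_routing(u_hat: Tensor, B: Tensor,
                           D: float = 128.0) -> tuple[Tensor, dict]:
    """Single-pass routing from vote similarities; no iteration.

    ``u_hat``: (batch, n_in, n_out, d_out); ``B``: (n_in, n_out) log-priors.
    Returns the squashed output capsules (batch, n_out, d_out) and a dict of
    intermediate quantities (coupling coefficients etc.) for inspection.
    """
    b, n_in, n_out, d_out = u_hat.shape
    # row-sums of A_j = U_j U_j^T / D without materialising A:
    # R[b,i,j] = sum_k <u_hat[b,i,j], u_hat[b,k,j]> / D
    tot = u_hat.sum(axis=1, keepdims=True)            # (b, 1, n_out, d_out)
    rowsum = (u_hat * tot).sum(axis=-1) * (1.0 / D)   # (b, n_in, n_out)
    C = rowsum.softmax(axis=2)                        # softmax over output capsules
    weights = C + B.reshape(1, n_in, n_out)
    s = (u_hat * weights.reshape(b, n_in, n_out, 1)).sum(axis=1)
    v = squash(s)
    return v, {"coupling": C, "pre_activation": s, "attention_rowsum": rowsum}


def dynamic_routing(u_hat: Tensor, n_iters: int = 3) -> tuple[Tensor, dict]:
    """Classic iterative routing-by-agreement (the no-attention ablation)."""
    b, n_in, n_out, d_out = u_hat.shape
    logits = np.zeros((b, n_in, n_out))
    C = v = None
    for it in range(n_iters):
        C = Tensor(logits).softmax(axis=2)
        s = (u_hat * C.reshape(b, n_in, n_out, 1)).sum(axis=1)
        v = squash(s)
        if it < n_iters - 1:
            # agreement update uses current values only (no grad through logits)
            agree = (u_hat.data * v.data.reshape(b, 1, n_out, d_out)).sum(axis=-1)
            logits = logits + agree
    return v, {"coupling": C}


def margin_loss(v_norms: Tensor, labels_onehot: np.ndarray,
                config: LossConfig = LossConfig()) -> Tensor:
    """Batch-averaged per-class margin loss on capsule lengths in [0, 1]."""
    if np.any(v_norms.data < -1e-9) or np.any(v_norms.data > 1 + 1e-9):
        raise ValueError("capsule lengths outside [0, 1]")
    T = np.asarray(labels_onehot, dtype=np.float64)
    present = (config.m_plus - v_norms).relu()
    absent = (v_norms - config.m_minus).relu()
    per_class = T * present * present + config.lam * (1.0 - T) * absent * absent
    return per_class.sum(axis=-1).mean()


class CapsuleLayer:
    """Learnable capsule head: votes + routing + squash."""

    def __init__(self, params: CapsuleLayerParams, rng: np.random.Generator,
                 routing: str = "self_attention", n_routing_iters: int = 3):
        assert routing in ("self_attention", "dynamic")
        self.hp = params
        self.routing = routing
        self.n_routing_iters = n_routing_iters
        scale = 0.1
        self.W = Parameter(scale * rng.standard_normal(
            (params.n_in, params.n_out, params.d_in, params.d_out)))
        self.B = Parameter(np.zeros((params.n_in, params.n_out)))

    @property
    def params(self) -> list[Parameter]:
        return [self.W, self.B] if self.routing == "self_attention" else [self.W]

    def __call__(self, u: Tensor) -> tuple[Tensor, dict]:
        """Input capsules (batch, n_in, d_in) -> squashed outputs + state."""
        u_hat = compute_votes(u, self.W)
        if self.routing == "self_attention":
            D = self.hp.attention_stabilizer
            if self.hp.sqrt_stabilizer:
                D = float(np.sqrt(D))
            return self_attention_routing(u_hat, self.B, D)
        return dynamic_routing(u_hat, self.n_routing_iters)
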