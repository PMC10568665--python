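"""Two-layer multi-head graph attention encoder with max-pool readout.

Each layer computes, per attention head, for every node i with neighbourhood
N(i) (self-loop included):

    z_i = W h_i
    e_ij = LeakyReLU(a^T [z_i || z_j])          (slope 0.2)
    alpha_ij = softmax_{j in N(i)} e_ij
    h'_i = sigma( sum_j alpha_ij z_j )

The shared attention vector a is stored split as (a_dst, a_src) so the edge
score is the equivalent a_dst.z_i + a_src.z_j. Layer 1 concatenates its four
heads (ELU activation); layer 2 averages them (identity activation) and an
elementwise max over each molecule's nodes yields the 50-d graph embedding.
Feature and attention dropout (rate 0.2) are active only in training mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (Parameter, Tensor, concat, dropout_mask, gather,
                       segment_max, segment_softmax, segment_sum)
from .molgraph import ATOM_FEATURE_DIM, GraphBatch, MolecularGraph, batch_graphs

__all__ = ["GATLayer", "GATEncoder"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


class GATLayer:
    """One multi-head graph attention layer on a batched graph."""

    def __init__(self, d_in: int, d_hidden: int, num_heads: int,
                 rng: np.random.Generator, *, leaky_slope: float = 0.2,
                 feat_drop: float = 0.2, attn_drop: float = 0.2,
                 combine: str = "concat", activation: str | None = "elu"):
        assert combine in ("concat", "mean")
        self.d_in, self.d_hidden, self.num_heads = d_in, d_hidden, num_heads
        self.leaky_slope = leaky_slope
        self.feat_drop, self.attn_drop = feat_drop, attn_drop
        self.combine, self.activation = combine, activation
        self.W = Parameter(_glorot(rng, (d_in, num_heads * d_hidden)))
        self.a_dst = Parameter(_glorot(rng, (num_heads, d_hidden)))
        self.a_src = Parameter(_glorot(rng, (num_heads, d_hidden)))

    @property
    def params(self) -> list[Parameter]:
        return [self.W, self.a_dst, self.a_src]

    @property
    def d_out(self) -> int:
        return (self.num_heads * self.d_hidden if self.combine == "concat"
                else self.d_hidden)

    def __call__(self, h: Tensor, batch: GraphBatch, *,
                 training: bool = False,
                 rng: np.random.Generator | None = None,
                 return_attention: bool = False):
        if h.shape[0] != batch.n_nodes:
            raise ValueError(f"feature rows {h.shape[0]} != nodes {batch.n_nodes}")
        if training and self.feat_drop > 0:
            h = h * dropout_mask(rng, h.shape, self.feat_drop)
        z = (h @ self.W).reshape(batch.n_nodes, self.num_heads, self.d_hidden)
        s_dst = (z * self.a_dst).sum(axis=-1)          # (N, heads)
        s_src = (z * self.a_src).sum(axis=-1)
        e = (gather(s_dst, batch.dst) + gather(s_src, batch.src)
             ).leaky_relu(self.leaky_slope)            # (E, heads)
        alpha = segment_softmax(e, batch.dst, batch.n_nodes)
        if training and self.attn_drop > 0:
            alpha = alpha * dropout_mask(rng, alpha.shape, self.attn_drop)
        msgs = alpha.reshape(-1, self.num_heads, 1) * gather(z, batch.src)
        out = segment_sum(msgs, batch.dst, batch.n_nodes)  # (N, heads, d_hidden)
        if self.combine == "concat":
            out = out.reshape(batch.n_nodes, self.num_heads * self.d_hidden)
        else:
            out = out.mean(axis=1)
        if self.activation == "elu":
            out = out.elu()
        if return_attention:
            return out, alpha.data
        return out


@dataclass
class GATEncoder:
    """Stacked two-layer GAT with per-molecule max-pool readout (50-d)."""

    d_in: int = ATOM_FEATURE_DIM
    d_hidden: int = 50
    num_heads: int = 4
    feat_drop: float = 0.2
    attn_drop: float = 0.2
    layers: list = field(default_factory=list)

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int = ATOM_FEATURE_DIM,
             d_hidden: int = 50, num_heads: int = 4,
             feat_drop: float = 0.2, attn_drop: float = 0.2) -> "GATEncoder":
        enc = cls(d_in, d_hidden, num_heads, feat_drop, attn_drop)
        l1 = GATLayer(d_in, d_hidden, num_heads, rng, combine="concat",
                      activation="elu", feat_drop=feat_drop, attn_drop=attn_drop)
        l2 = GATLayer(l1.d_out, d_hidden, num_heads, rng, combine="mean",
                      activation=None, feat_drop=feat_drop, attn_drop=attn_drop)
        enc.layers = [l1, l2]
        return enc

    @property
    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def d_out(self) -> int:
        return self.d_hidden

    def __call__(self, batch: GraphBatch, *, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = Tensor(batch.node_features)
        for layer in self.layers:
            h = layer(h, batch, training=training, rng=rng)
        return segment_max(h, batch.graph_ids, batch.n_graphs)

    def encode_graph(self, graph: MolecularGraph) -> np.ndarray:
        """Deterministic (eval-mode) embedding of a single molecule."""
        if graph.n_nodes == 0:
            raise ValueError("cannot encode an empty graph")
        return self(batch_graphs([graph])).data[0]
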