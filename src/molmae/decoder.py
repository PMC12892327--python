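"""Graph-Transformer decoder for masked-node reconstruction.

Pipeline per the architecture: dynamic message passing (DMPN, several
hops per layer with shared weights) -> multi-head attention over the
nodes of each molecule -> Agg2Node / Agg2Edge neighborhood aggregation
-> a single long-range residual carrying the decoder's *input* node and
edge features to the last layer (replacing the usual short-range
residuals of a Transformer) -> layer normalization -> feed-forward
network -> per-node reconstruction Z. Node and edge states are pooled
order-free per molecule and fused by an MLP into one graph-level vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, gather_rows, relu, spmm
from .batching import GraphBatch
from .encoder import BondEmbedding, LatentGraph
from .exceptions import ConfigurationError, ContractError, GraphIntegrityError

__all__ = ["DecoderState", "GraphTransformerDecoder", "dmpn_step",
           "agg2node_agg2edge"]


@dataclass
class DecoderState:
    """Node/edge hidden states at hop ``k`` of layer ``l``."""

    node_h: Tensor
    edge_h: Tensor
    layer: int = 0
    hop: int = 0


def dmpn_step(state: DecoderState, batch: GraphBatch,
              msg_proj: nn.Linear, upd: nn.Linear,
              activation=relu) -> DecoderState:
    """One DMPN hop.

    For every directed edge (u -> v) the triple (h_v, h_u, H_uv) is
    concatenated, linearly projected and sum-aggregated at v:
    m_v = Σ_u proj([h_v ; h_u ; H_uv]); then h_v <- σ(W m_v + b) with W, b
    shared across hops of the same layer.
    """
    if state.node_h is None or state.edge_h is None:
        raise ContractError("decoder state not initialized from encoder latents")
    h, e = state.node_h, state.edge_h
    if batch.n_edges:
        if batch.edge_index.max(initial=-1) >= batch.n_nodes:
            raise GraphIntegrityError("edge references a missing node")
        src, dst = batch.edge_index
        triple = concat([gather_rows(h, dst), gather_rows(h, src), e], axis=1)
        m = spmm(batch.incoming, msg_proj(triple))
    else:
        m = Tensor(np.zeros((batch.n_nodes, upd.in_dim)))
    new_h = activation(upd(m))
    return DecoderState(new_h, e, state.layer, state.hop + 1)


def agg2node_agg2edge(node_h: Tensor, batch: GraphBatch
                      ) -> tuple[Tensor, Tensor]:
    """Neighborhood sums of the attention-updated node states.

    Agg2Node: m_v = Σ_{u ∈ N(v)} h̄_u. Agg2Edge: m_vw = h̄_v + h̄_w (sum
    over the endpoint set of each directed edge).
    """
    if batch.n_edges:
        src, dst = batch.edge_index
        if max(src.max(initial=-1), dst.max(initial=-1)) >= batch.n_nodes:
            raise GraphIntegrityError("edge references a missing node")
        m_node = spmm(batch.incoming, gather_rows(node_h, src))
        m_edge = gather_rows(node_h, src) + gather_rows(node_h, dst)
    else:
        dim = node_h.shape[1]
        m_node = Tensor(np.zeros((batch.n_nodes, dim)))
        m_edge = Tensor(np.zeros((0, dim)))
    return m_node, m_edge


class _DecoderLayer(nn.Module):
    def __init__(self, dim: int, n_heads: int, dmpn_hops: int,
                 rng: np.random.Generator):
        self.dmpn_hops = dmpn_hops
        self.msg_proj = nn.Linear(3 * dim, dim, rng)
        self.upd = nn.Linear(dim, dim, rng)
        self.attn = nn.MultiHeadAttention(dim, n_heads, rng)

    def __call__(self, state: DecoderState, batch: GraphBatch) -> DecoderState:
        for _ in range(self.dmpn_hops):
            state = dmpn_step(state, batch, self.msg_proj, self.upd)
        attended = self.attn(state.node_h, mask=batch.attention_mask)
        return DecoderState(attended, state.edge_h, state.layer + 1, 0)


class GraphTransformerDecoder(nn.Module):
    """Decode latent node states into per-node reconstructions.

    ``out_dim`` is the width of the reconstruction target (the tokenizer's
    ``hops * dim`` by default). The remask token used by the multi-view
    objective lives here, on the decoder side.
    """

    def __init__(self, latent_dim: int, out_dim: int, hidden_dim: int = 64,
                 n_heads: int = 2, n_layers: int = 1, dmpn_hops: int = 2,
                 seed: int = 0, long_range_residual: bool = True):
        if hidden_dim % n_heads != 0:
            raise ConfigurationError(
                f"attention heads ({n_heads}) must divide hidden dim ({hidden_dim})")
        if n_layers < 1 or dmpn_hops < 1:
            raise ConfigurationError("decoder layers and dmpn hops must be >= 1")
        rng = np.random.default_rng(seed)
        self.hidden_dim = hidden_dim
        self.long_range_residual = long_range_residual
        self.in_proj = nn.Linear(latent_dim, hidden_dim, rng)
        self.edge_embed = BondEmbedding(hidden_dim, rng)
        self.layers = [_DecoderLayer(hidden_dim, n_heads, dmpn_hops, rng)
                       for _ in range(n_layers)]
        self.node_res = nn.Linear(latent_dim, hidden_dim, rng)
        self.edge_res = nn.Linear(hidden_dim, hidden_dim, rng)
        self.node_norm = nn.LayerNorm(hidden_dim)
        self.edge_norm = nn.LayerNorm(hidden_dim)
        self.node_ffn = nn.FeedForward(hidden_dim, 2 * hidden_dim, rng)
        self.edge_ffn = nn.FeedForward(hidden_dim, 2 * hidden_dim, rng)
        self.out_proj = nn.Linear(hidden_dim, out_dim, rng)
        self.fusion = nn.MLP([2 * hidden_dim, hidden_dim, hidden_dim], rng)
        self.remask_token = nn.parameter(rng.normal(0.0, 0.1, (1, latent_dim)))

    def decode(self, latent_nodes: Tensor, batch: GraphBatch
               ) -> tuple[Tensor, Tensor]:
        """Return per-node reconstruction Z and the fused graph vector."""
        edge_h = self.edge_embed(batch.edge_attrs)
        state = DecoderState(self.in_proj(latent_nodes), edge_h)
        for layer in self.layers:
            state = layer(state, batch)
        m_node, m_edge = agg2node_agg2edge(state.node_h, batch)
        if self.long_range_residual:
            m_node = m_node + self.node_res(latent_nodes)
            if batch.n_edges:
                m_edge = m_edge + self.edge_res(edge_h)
        node_states = self.node_ffn(self.node_norm(m_node))
        edge_states = self.edge_ffn(self.edge_norm(m_edge)) if batch.n_edges \
            else Tensor(np.zeros((0, self.hidden_dim)))
        z = self.out_proj(node_states)
        node_pool = spmm(batch.pool_matrix("mean", "nodes"), node_states)
        if batch.n_edges:
            edge_pool = spmm(batch.pool_matrix("mean", "edges"), edge_states)
        else:
            edge_pool = Tensor(np.zeros((batch.n_mols, self.hidden_dim)))
        graph_vec = self.fusion(concat([node_pool, edge_pool], axis=1))
        return z, graph_vec

    def __call__(self, latent: LatentGraph) -> tuple[Tensor, Tensor]:
        return self.decode(latent.node_h, latent.batch)
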