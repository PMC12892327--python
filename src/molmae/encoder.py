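"""Input masking and the graph encoder (GIN default, GCN/GAT variants).

Masking replaces the attribute embedding of selected nodes with a single
learnable [MASK] vector; edges are never masked. The encoder then runs
standard message passing over the masked graph and returns latent states
for every node, masked ones included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autodiff import Tensor, gather_rows, leaky_relu, relu, spmm
from .batching import GraphBatch
from .exceptions import ConfigurationError
from .molio import (
    MolecularGraph,
    N_ATOM_TYPES,
    N_BOND_DIRS,
    N_BOND_TYPES,
    N_CHIRALITY_TAGS,
)

logger = logging.getLogger(__name__)

__all__ = ["MaskPlan", "LatentGraph", "NodeEmbedding", "BondEmbedding",
           "GraphEncoder", "mask_graph", "masked_node_count"]


@dataclass
class MaskPlan:
    """Which nodes of one molecule were input-masked."""

    masked_idx: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self):
        self.masked_idx = np.unique(np.asarray(self.masked_idx, dtype=np.int64))


@dataclass
class LatentGraph:
    """Encoder output: latent node states over a (batched) graph."""

    node_h: Tensor
    batch: GraphBatch
    edge_h: Tensor | None = None
    plans: list[MaskPlan] = field(default_factory=list)

    @property
    def masked_idx(self) -> np.ndarray:
        """Batch-level indices of the originally masked nodes."""
        return np.flatnonzero(self.batch.mask_flags)


def masked_node_count(n_nodes: int, ratio: float) -> int:
    """round(ratio * n), but at least one node for non-empty graphs."""
    if n_nodes == 0:
        return 0
    # Banker's rounding in ``round`` would make 0.45*20 ambiguous; use
    # half-up rounding, the convention throughout.
    return max(1, int(np.floor(ratio * n_nodes + 0.5)))


def mask_graph(graph: MolecularGraph, ratio: float, seed: int
               ) -> tuple[MolecularGraph, MaskPlan]:
    """Draw the input mask for one molecule.

    Returns the (unchanged) graph and a :class:`MaskPlan`; the learnable
    [MASK] embedding is substituted inside the encoder, which is the
    graph-side equivalent of replacing the masked attribute rows.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError(f"mask ratio must be in (0, 1), got {ratio}")
    n_mask = masked_node_count(graph.n_nodes, ratio)
    rng = np.random.default_rng(seed)
    idx = rng.choice(graph.n_nodes, size=n_mask, replace=False)
    return graph, MaskPlan(np.sort(idx), ratio, seed)


def batch_with_masks(graphs: list[MolecularGraph], plans: list[MaskPlan]
                     ) -> GraphBatch:
    flags = np.zeros(sum(g.n_nodes for g in graphs), dtype=bool)
    offset = 0
    for g, plan in zip(graphs, plans):
        flags[offset + plan.masked_idx] = True
        offset += g.n_nodes
    return GraphBatch(graphs, mask_flags=flags)


class NodeEmbedding(nn.Module):
    """Sum of atomic-number and chirality embeddings, plus a [MASK] row."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.atom = nn.Embedding(N_ATOM_TYPES, dim, rng)
        self.chirality = nn.Embedding(N_CHIRALITY_TAGS, dim, rng)
        self.mask_token = nn.parameter(rng.normal(0.0, 0.1, size=(1, dim)))

    def __call__(self, node_attrs: np.ndarray,
                 mask_flags: np.ndarray | None = None) -> Tensor:
        h = self.atom(node_attrs[:, 0]) + self.chirality(node_attrs[:, 1])
        if mask_flags is not None and mask_flags.any():
            f = mask_flags.astype(np.float64)[:, None]
            h = h * (1.0 - f) + self.mask_token * f
        return h

    def embed_numpy(self, node_attrs: np.ndarray) -> np.ndarray:
        """Unmasked embedding as a plain array (tokenizer entry point)."""
        return (self.atom.table.data[node_attrs[:, 0]]
                + self.chirality.table.data[node_attrs[:, 1]])


class BondEmbedding(nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.bond_type = nn.Embedding(N_BOND_TYPES, dim, rng)
        self.bond_dir = nn.Embedding(N_BOND_DIRS, dim, rng)

    def __call__(self, edge_attrs: np.ndarray) -> Tensor:
        return self.bond_type(edge_attrs[:, 0]) + self.bond_dir(edge_attrs[:, 1])


class _GINLayer(nn.Module):
    """GIN convolution with bond features: MLP((1+eps) h + Σ (h_u + e_uv))."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.mlp = nn.MLP([dim, 2 * dim, dim], rng)
        self.eps = nn.parameter(np.zeros(1))
        self.edge = BondEmbedding(dim, rng)
        self.norm = nn.LayerNorm(dim)

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        if batch.n_edges:
            msgs = gather_rows(h, batch.edge_index[0]) + self.edge(batch.edge_attrs)
            agg = spmm(batch.incoming, msgs)
            out = self.mlp(h * (1.0 + self.eps) + agg)
        else:
            out = self.mlp(h * (1.0 + self.eps))
        return self.norm(out)


class _GCNLayer(nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.lin = nn.Linear(dim, dim, rng)
        self.norm = nn.LayerNorm(dim)

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        return self.norm(self.lin(spmm(batch.propagation("sym"), h)))


class _GATLayer(nn.Module):
    """Single-head additive attention over incoming edges (with self-loop)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.lin = nn.Linear(dim, dim, rng)
        self.att_src = nn.parameter(nn.glorot(rng, dim, 1, (dim, 1)))
        self.att_dst = nn.parameter(nn.glorot(rng, dim, 1, (dim, 1)))
        self.edge = BondEmbedding(dim, rng)
        self.norm = nn.LayerNorm(dim)

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        from ._autodiff import exp

        hw = self.lin(h)
        alpha_dst = (hw @ self.att_dst)        # (n, 1)
        if batch.n_edges:
            src, dst = batch.edge_index
            msg = gather_rows(hw, src) + self.edge(batch.edge_attrs)
            score = leaky_relu(gather_rows(alpha_dst, dst)
                               + (msg @ self.att_src))
            # Numerically-stable softmax over incoming edges per node,
            # including a self-loop term.
            score_self = leaky_relu(alpha_dst + (hw @ self.att_src))
            m = np.zeros((batch.n_nodes, 1))
            np.maximum.at(m, dst, score.data)
            m = np.maximum(m, score_self.data)
            e_edge = exp(score - Tensor(m[dst]))
            e_self = exp(score_self - Tensor(m))
            denom = spmm(batch.incoming, e_edge) + e_self
            out = (spmm(batch.incoming, e_edge * msg) + e_self * hw) / denom
        else:
            out = hw
        return self.norm(out)


_LAYERS = {"gin": _GINLayer, "gcn": _GCNLayer, "gat": _GATLayer}


class GraphEncoder(nn.Module):
    """Configurable message-passing encoder over (masked) molecular graphs.

    Defaults follow the ablation optimum: GIN layers at depth 3. Each
    layer applies normalization and (between layers) a ReLU nonlinearity.
    """

    def __init__(self, hidden_dim: int = 64, arch: str = "gin", depth: int = 3,
                 seed: int = 0):
        arch = arch.lower()
        if arch not in _LAYERS:
            raise ConfigurationError(
                f"unknown encoder arch {arch!r}; expected one of {sorted(_LAYERS)}")
        if depth < 1:
            raise ConfigurationError(f"encoder depth must be >= 1, got {depth}")
        rng = np.random.default_rng(seed)
        self.arch, self.depth, self.hidden_dim = arch, depth, hidden_dim
        self.embedding = NodeEmbedding(hidden_dim, rng)
        self.layers = [_LAYERS[arch](hidden_dim, rng) for _ in range(depth)]

    def __call__(self, batch: GraphBatch) -> Tensor:
        h = self.embedding(batch.node_attrs, batch.mask_flags)
        for i, layer in enumerate(self.layers):
            h = layer(h, batch)
            if i < len(self.layers) - 1:
                h = relu(h)
        return h

    def encode(self, batch: GraphBatch,
               plans: list[MaskPlan] | None = None) -> LatentGraph:
        return LatentGraph(self(batch), batch, plans=plans or [])

    def pooled(self, batch: GraphBatch, mode: str = "mean") -> Tensor:
        """Graph-level vectors by order-free pooling of node latents."""
        return spmm(batch.pool_matrix(mode, "nodes"), self(batch))
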