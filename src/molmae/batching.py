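"""Batching of molecular graphs into one disjoint-union graph.

A :class:`GraphBatch` concatenates node/edge arrays of several molecules
with offset node indices and keeps per-node molecule ids. Sparse
operators used by the models (incoming-edge scatter, normalized
propagation, pooling, the intra-molecule attention mask) are built once
and cached on the batch.
"""

from __future__ import annotations

from functools import cached_property
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .exceptions import ConfigurationError
from .molio import MolecularGraph

NEG_INF = -1e9


def propagation_matrix(n_nodes: int, edge_index: np.ndarray,
                       norm: str = "sym") -> sp.csr_matrix:
    """Adjacency-with-self-loops propagation operator.

    ``sym``  — D̃^(-1/2) (A + I) D̃^(-1/2), the simplified-GCN operator;
    ``row``  — D̃^(-1) (A + I), random-walk normalization;
    ``raw``  — A + I, unnormalized sum aggregation.
    """
    rows = np.concatenate([edge_index[1], np.arange(n_nodes)])
    cols = np.concatenate([edge_index[0], np.arange(n_nodes)])
    data = np.ones(rows.shape[0])
    a_tilde = sp.csr_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))
    if norm == "raw":
        return a_tilde
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    if norm == "sym":
        d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
        return (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()
    if norm == "row":
        return (sp.diags(1.0 / deg) @ a_tilde).tocsr()
    raise ConfigurationError(f"unknown propagation norm: {norm!r}")


class GraphBatch:
    """Disjoint union of molecular graphs with cached sparse operators."""

    def __init__(self, graphs: Sequence[MolecularGraph],
                 mask_flags: np.ndarray | None = None):
        if not graphs:
            raise ConfigurationError("cannot batch zero graphs")
        self.graphs = list(graphs)
        sizes = np.array([g.n_nodes for g in graphs], dtype=np.int64)
        self.sizes = sizes
        self.node_offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.n_nodes = int(sizes.sum())
        self.n_mols = len(graphs)
        self.node_attrs = np.concatenate([g.node_attrs for g in graphs], axis=0)
        parts = [g.edge_index + off for g, off in zip(graphs, self.node_offsets)]
        self.edge_index = np.concatenate(parts, axis=1) if parts else \
            np.zeros((2, 0), dtype=np.int64)
        self.edge_attrs = np.concatenate([g.edge_attrs for g in graphs], axis=0)
        self.n_edges = int(self.edge_index.shape[1])
        self.mol_id = np.repeat(np.arange(self.n_mols), sizes)
        if mask_flags is None:
            mask_flags = np.zeros(self.n_nodes, dtype=bool)
        self.mask_flags = np.asarray(mask_flags, dtype=bool)
        if self.mask_flags.shape[0] != self.n_nodes:
            raise ConfigurationError("mask_flags length must equal total node count")

    @classmethod
    def single(cls, graph: MolecularGraph) -> "GraphBatch":
        return cls([graph])

    def node_slice(self, mol: int) -> slice:
        return slice(int(self.node_offsets[mol]), int(self.node_offsets[mol + 1]))

    # -- cached sparse operators ---------------------------------------
    @cached_property
    def incoming(self) -> sp.csr_matrix:
        """(n_nodes, n_edges) scatter matrix: sums per-edge messages at dst."""
        rows = self.edge_index[1]
        cols = np.arange(self.n_edges)
        return sp.csr_matrix((np.ones(self.n_edges), (rows, cols)),
                             shape=(self.n_nodes, self.n_edges))

    def propagation(self, norm: str = "sym") -> sp.csr_matrix:
        key = f"_prop_{norm}"
        if not hasattr(self, key):
            setattr(self, key, propagation_matrix(self.n_nodes, self.edge_index, norm))
        return getattr(self, key)

    def pool_matrix(self, mode: str = "mean", over: str = "nodes") -> sp.csr_matrix:
        """(n_mols, n_items) pooling operator over nodes or edges."""
        if over == "nodes":
            owner, n_items = self.mol_id, self.n_nodes
        elif over == "edges":
            owner = self.mol_id[self.edge_index[0]] if self.n_edges else \
                np.zeros(0, dtype=np.int64)
            n_items = self.n_edges
        else:
            raise ConfigurationError(f"unknown pooling target: {over!r}")
        mat = sp.csr_matrix((np.ones(n_items), (owner, np.arange(n_items))),
                            shape=(self.n_mols, n_items))
        if mode == "sum":
            return mat
        if mode == "mean":
            counts = np.maximum(np.asarray(mat.sum(axis=1)).ravel(), 1.0)
            return (sp.diags(1.0 / counts) @ mat).tocsr()
        raise ConfigurationError(f"unknown pooling mode: {mode!r}")

    @cached_property
    def attention_mask(self) -> np.ndarray:
        """Additive (n_nodes, n_nodes) mask confining attention per molecule."""
        same = self.mol_id[:, None] == self.mol_id[None, :]
        return np.where(same, 0.0, NEG_INF)
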