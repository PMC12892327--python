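"""Parameter-free graph tokenizer producing multi-hop reconstruction targets.

The tokenizer embeds node attributes with the *encoder's own* embedding
table (shared weights), then applies K rounds of linear neighborhood
propagation H^l = ω(A) H^(l-1) — no nonlinearity, no learned weights of
its own — and concatenates the per-node states of hops 1..K. The result
is the reconstruction target of the masked autoencoder and is always
detached from the autodiff tape (stop-gradient), so no loss can train
the tokenizer through its targets.

ω(A) defaults to the symmetric-normalized adjacency with self-loops,
D̃^(-1/2)(A+I)D̃^(-1/2); row-normalized and raw-sum variants are offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .batching import GraphBatch, propagation_matrix
from .exceptions import ConfigurationError
from .molio import MolecularGraph

__all__ = ["GraphTokenizer", "TokenTarget", "propagate"]


@dataclass
class TokenTarget:
    """Per-node concatenated multi-hop tokens: ``(n_nodes, hops * dim)``."""

    tokens: np.ndarray
    hops: int
    embed_dim: int

    def __post_init__(self):
        if self.tokens.shape[1] != self.hops * self.embed_dim and not (
                self.tokens.shape[1] == (self.hops + 1) * self.embed_dim):
            raise ConfigurationError("token width inconsistent with hops * dim")


def propagate(h_prev: np.ndarray, graph: MolecularGraph | GraphBatch,
              norm: str = "sym") -> np.ndarray:
    """One linear propagation step ``ω(A) @ H``."""
    n = graph.n_nodes
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if h_prev.shape[0] != n:
        raise ValueError(
            f"H has {h_prev.shape[0]} rows but the graph has {n} nodes")
    if isinstance(graph, GraphBatch):
        omega = graph.propagation(norm)
    else:
        omega = propagation_matrix(n, graph.edge_index, norm)
    return np.asarray(omega @ h_prev)


class GraphTokenizer:
    """Multi-hop linear-propagation tokenizer; zero trainable parameters."""

    def __init__(self, hops: int = 3, norm: str = "sym",
                 include_h0: bool = False):
        if hops < 1:
            raise ConfigurationError(f"tokenizer hops must be >= 1, got {hops}")
        self.hops = hops
        self.norm = norm
        self.include_h0 = include_h0

    def tokenize(self, graph: MolecularGraph | GraphBatch,
                 embed) -> TokenTarget:
        """Compute per-node tokens from the shared embedding.

        ``embed`` is any object exposing ``embed_numpy(node_attrs)`` — in
        the full model, the encoder's node-embedding module. The result is
        a plain array, outside the autodiff tape by construction.
        """
        h = np.asarray(embed.embed_numpy(graph.node_attrs), dtype=np.float64)
        dim = h.shape[1]
        states = [h] if self.include_h0 else []
        for _ in range(self.hops):
            h = propagate(h, graph, self.norm)
            states.append(h)
        return TokenTarget(np.concatenate(states, axis=1), self.hops, dim)

    @property
    def out_multiplier(self) -> int:
        """Token width as a multiple of the embedding dim."""
        return self.hops + (1 if self.include_h0 else 0)

    def n_trainable_parameters(self) -> int:
        """The tokenizer owns no weights; the shared embedding is the
        encoder's and is counted there."""
        return 0
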