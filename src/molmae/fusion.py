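"""Graph-sequence fusion: SMILES Transformer and three alignment losses.

The sequence side tokenizes SMILES with the standard chemistry regex
(two-letter elements and bracket atoms are single tokens), embeds tokens
with learned positional embeddings, and pools a prepended [CLS] token
from a Transformer encoder.

Three fusion strategies align the graph and sequence views of the same
molecule:

* dual-tower — symmetric InfoNCE on pooled vectors with in-batch
  negatives and temperature τ (default 0.5);
* Q-Former — T learnable queries (default 16) read the graph's node
  latents via cross-attention; similarity of a molecule pair is the best
  match over query tokens, max_k cos(m_ik, t_j), inside the same
  symmetric InfoNCE (default τ = 0.1);
* dual-view consistency — negative-free: each modality's predictor
  matches the other's stop-gradient projection,
  L = -cos(q_s, SG(p_g)) - cos(q_g, SG(p_s)) ∈ [-2, 2].
"""

from __future__ import annotations

import logging
import re

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, matmul
from .exceptions import ConfigurationError, SmilesLengthError, SmilesParseError
from .molio import MAX_SMILES_LEN
from .nn import cosine_rows, log_softmax, normalize_rows

logger = logging.getLogger(__name__)

__all__ = [
    "SMILES_TOKEN_RE", "tokenize_smiles", "SmilesVocab", "SequenceEncoder",
    "dual_tower_loss", "QFormer", "qformer_loss",
    "DualViewHeads", "dual_view_loss", "ProjectionHead",
]

# Standard SMILES tokenization regex: bracket atoms, two-letter elements
# and ring-bond escapes are single tokens.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|@|%\d{2}|=|#|\+|-|\\|/|\(|\)|\.|:|~|\*|\$|[A-Za-z]|\d)"
)


def tokenize_smiles(smiles: str) -> list[str]:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens = SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise SmilesParseError(f"untokenizable SMILES: {smiles!r}")
    return tokens


class SmilesVocab:
    """Fixed token vocabulary with [PAD]/[CLS]/[OOV] specials."""

    _BASE = (
        ["[PAD]", "[CLS]", "[OOV]"]
        + list("BCNOPSFIbcnops")
        + ["Br", "Cl", "Si", "Se", "se"]
        + list("0123456789")
        + ["=", "#", "+", "-", "(", ")", "/", "\\", ".", ":", "~", "*", "$", "@", "@@"]
        + ["[nH]", "[NH+]", "[NH2+]", "[NH3+]", "[O-]", "[N+]", "[n+]", "[S+]",
           "[C@H]", "[C@@H]", "[C@]", "[C@@]"]
    )

    def __init__(self):
        self.index = {tok: i for i, tok in enumerate(self._BASE)}

    def __len__(self) -> int:
        return len(self._BASE)

    @property
    def pad(self) -> int:
        return 0

    @property
    def cls(self) -> int:
        return 1

    def encode(self, smiles: str) -> list[int]:
        """[CLS]-prefixed token ids; unknown tokens map to [OOV]."""
        ids = [self.cls]
        oov = self.index["[OOV]"]
        for tok in tokenize_smiles(smiles):
            ids.append(self.index.get(tok, oov))
        return ids


class SequenceEncoder(nn.Module):
    """Transformer encoder over SMILES token streams, pooled at [CLS]."""

    def __init__(self, dim: int = 64, n_layers: int = 2, n_heads: int = 2,
                 max_len: int = MAX_SMILES_LEN, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.vocab = SmilesVocab()
        self.max_len = max_len
        self.dim = dim
        self.token_embed = nn.Embedding(len(self.vocab), dim, rng)
        self.pos_embed = nn.Embedding(max_len + 1, dim, rng)  # +1 for [CLS]
        self.blocks = [nn.TransformerBlock(dim, n_heads, rng)
                       for _ in range(n_layers)]

    def encode(self, smiles: str) -> Tensor:
        """Pooled [CLS] vector for one SMILES string."""
        if len(smiles) > self.max_len:
            raise SmilesLengthError(
                f"SMILES longer than {self.max_len} characters")
        ids = np.asarray(self.vocab.encode(smiles), dtype=np.int64)
        x = self.token_embed(ids) + self.pos_embed(np.arange(len(ids)))
        for block in self.blocks:
            x = block(x)
        from ._autodiff import gather_rows
        return gather_rows(x, np.array([0]))  # (1, dim)

    def encode_batch(self, smiles_list: list[str]) -> Tensor:
        return concat([self.encode(s) for s in smiles_list], axis=0)

    def encode_masked(self, smiles: str, ratio: float,
                      rng: np.random.Generator) -> Tensor:
        """Pooled vector of a token-masked view of the SMILES.

        A fraction ``ratio`` of the (non-[CLS]) tokens is replaced by the
        [OOV] token — the sequence-side analogue of node masking, used by
        the dual-view consistency strategy.
        """
        if len(smiles) > self.max_len:
            raise SmilesLengthError(
                f"SMILES longer than {self.max_len} characters")
        ids = np.asarray(self.vocab.encode(smiles), dtype=np.int64)
        n_tok = len(ids) - 1
        if n_tok > 0 and ratio > 0:
            k = max(1, int(np.floor(ratio * n_tok + 0.5)))
            hit = 1 + rng.choice(n_tok, size=k, replace=False)
            ids[hit] = self.vocab.index["[OOV]"]
        x = self.token_embed(ids) + self.pos_embed(np.arange(len(ids)))
        for block in self.blocks:
            x = block(x)
        from ._autodiff import gather_rows
        return gather_rows(x, np.array([0]))


def _info_nce(sim: Tensor, tau: float) -> Tensor:
    """Symmetric InfoNCE over a (K, K) similarity matrix, diagonal positive."""
    k = sim.shape[0]
    logits = sim * (1.0 / tau)
    diag = np.eye(k)
    l1 = (log_softmax(logits, axis=1) * diag).sum() * (1.0 / k)
    l2 = (log_softmax(logits.transpose(1, 0), axis=1) * diag).sum() * (1.0 / k)
    return -l1 - l2


def dual_tower_loss(x: Tensor, y: Tensor, tau: float = 0.5) -> Tensor:
    """Symmetric InfoNCE between pooled graph (x) and sequence (y) vectors.

    Matched rows are positives; all other in-batch pairs are negatives.
    """
    if tau <= 0:
        raise ConfigurationError(f"temperature must be > 0, got {tau}")
    if x.shape != y.shape:
        raise ConfigurationError("paired representations must share a shape")
    if x.shape[0] == 1:
        logger.warning("dual-tower batch of size 1 has no negatives")
    sim = matmul(normalize_rows(x), normalize_rows(y).transpose(1, 0))
    return _info_nce(sim, tau)


class QFormer(nn.Module):
    """Learnable query tokens reading graph node latents via cross-attention.

    Each block: self-attention among the T queries, cross-attention from
    queries to the molecule's node latents, FFN. Dimension alignment
    between modalities happens inside the cross-attention projections.
    """

    def __init__(self, dim: int = 64, n_tokens: int = 16, n_layers: int = 2,
                 n_heads: int = 2, graph_dim: int | None = None, seed: int = 0):
        if n_tokens < 1:
            raise ConfigurationError(f"query count must be >= 1, got {n_tokens}")
        rng = np.random.default_rng(seed)
        self.n_tokens, self.dim = n_tokens, dim
        self.queries = nn.parameter(rng.normal(0.0, 0.1, (n_tokens, dim)))
        self.self_attn = [nn.MultiHeadAttention(dim, n_heads, rng)
                          for _ in range(n_layers)]
        self.cross_attn = [
            nn.MultiHeadAttention(dim, n_heads, rng, kv_dim=graph_dim or dim)
            for _ in range(n_layers)]
        self.ffn = [nn.FeedForward(dim, 2 * dim, rng) for _ in range(n_layers)]
        self.norms = [nn.LayerNorm(dim) for _ in range(2 * n_layers)]

    def embed(self, node_latents: Tensor) -> Tensor:
        """Query tokens ``(T, dim)`` for one molecule's node latents."""
        q = self.queries
        for i, (sa, ca, ff) in enumerate(zip(self.self_attn, self.cross_attn,
                                             self.ffn)):
            q = self.norms[2 * i](q + sa(q))
            q = q + ca(q, node_latents)
            q = self.norms[2 * i + 1](ff(q))
        return q

    def embed_batch(self, per_mol_latents: list[Tensor]) -> list[Tensor]:
        return [self.embed(h) for h in per_mol_latents]


def qformer_loss(query_tokens: list[Tensor], seq_vecs: Tensor,
                 tau: float = 0.1) -> Tensor:
    """Symmetric InfoNCE with best-query-match similarity.

    ``sim(i, j) = max_k cos(m_ik, t_j)`` over the T query tokens of
    molecule i against the sequence vector of molecule j.
    """
    if tau <= 0:
        raise ConfigurationError(f"temperature must be > 0, got {tau}")
    k = len(query_tokens)
    if k != seq_vecs.shape[0]:
        raise ConfigurationError("query tokens and sequence batch sizes differ")
    t_norm = normalize_rows(seq_vecs)            # (K, d)
    rows = []
    for m in query_tokens:
        cos_all = matmul(normalize_rows(m), t_norm.transpose(1, 0))  # (T, K)
        rows.append(cos_all.max(axis=0).reshape(1, -1))
    sim = concat(rows, axis=0)                   # (K, K)
    return _info_nce(sim, tau)


class ProjectionHead(nn.Module):
    """Per-modality MLP mapping a representation into the shared space.

    The default (linear -> ReLU -> linear) matches the dual-tower
    dimension-alignment head; ``n_layers``/``dim`` span the ablation grid
    (2-5 layers, widths 64-512).
    """

    def __init__(self, in_dim: int, dim: int = 256, n_layers: int = 2,
                 seed: int = 0):
        if n_layers < 1:
            raise ConfigurationError("projection needs at least one layer")
        rng = np.random.default_rng(seed)
        self.mlp = nn.MLP([in_dim] + [dim] * n_layers, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.mlp(x)


def project_align(graph_vec: Tensor, seq_vec: Tensor,
                  graph_head: ProjectionHead, seq_head: ProjectionHead
                  ) -> tuple[Tensor, Tensor]:
    """Map both modalities into one shared dimension."""
    return graph_head(graph_vec), seq_head(seq_vec)


class DualViewHeads(nn.Module):
    """Projection (3-layer MLP) + prediction (2-layer MLP) per modality."""

    def __init__(self, graph_dim: int, seq_dim: int, proj_dim: int = 256,
                 proj_layers: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.proj_g = nn.MLP([graph_dim] + [proj_dim] * proj_layers, rng)
        self.proj_s = nn.MLP([seq_dim] + [proj_dim] * proj_layers, rng)
        self.pred_g = nn.MLP([proj_dim, proj_dim, proj_dim], rng)
        self.pred_s = nn.MLP([proj_dim, proj_dim, proj_dim], rng)

    def forward_graph(self, f_g: Tensor) -> tuple[Tensor, Tensor]:
        p_g = self.proj_g(f_g)
        return p_g, self.pred_g(p_g)

    def forward_seq(self, f_s: Tensor) -> tuple[Tensor, Tensor]:
        p_s = self.proj_s(f_s)
        return p_s, self.pred_s(p_s)


def dual_view_loss(heads: DualViewHeads, f_g: Tensor, f_s: Tensor) -> Tensor:
    """Negative-free consistency loss with stop-gradient targets.

    L = -cos(q_s, SG(p_g)) - cos(q_g, SG(p_s)); the stop-gradient branch
    receives exactly zero gradient.
    """
    p_g, q_g = heads.forward_graph(f_g)
    p_s, q_s = heads.forward_seq(f_s)
    term1 = cosine_rows(q_s, p_g.detach()).mean()
    term2 = cosine_rows(q_g, p_s.detach()).mean()
    return -term1 - term2
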