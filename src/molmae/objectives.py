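"""Multi-view remasking and the Scaled Cosine Error pretraining loss.

After encoding, K independent "remask" sets are drawn and the latent
rows of each set are replaced by a learnable decoder-side remask token,
giving K views of the same latent graph. Each view is decoded and scored
against the (stop-gradient) tokenizer targets with the Scaled Cosine
Error, SCE = mean_i (1 - cos(x_i, z_i))^γ with γ > 1; the total loss
averages the per-view SCEs. K = 0 is the "no remask" autoencoder
baseline, K = 1 single remask, K >= 2 multi-view masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor
from .batching import GraphBatch
from .encoder import LatentGraph, masked_node_count
from .exceptions import ConfigurationError, ContractError
from .nn import cosine_rows

__all__ = ["SCEConfig", "ViewBatch", "remask_views", "sce", "multiview_loss"]


@dataclass
class SCEConfig:
    gamma: float = 2.0

    def __post_init__(self):
        if self.gamma <= 1.0:
            raise ConfigurationError(f"SCE gamma must be > 1, got {self.gamma}")


@dataclass
class ViewBatch:
    """K independently remasked copies of one latent graph."""

    views: list[Tensor]
    remask_sets: list[np.ndarray]
    remask_ratio: float
    K: int
    target_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))


def _draw_remask(batch: GraphBatch, ratio: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-molecule remask indices (batch-level), round(ratio * n) each."""
    picked = []
    for m in range(batch.n_mols):
        sl = batch.node_slice(m)
        n = sl.stop - sl.start
        k = masked_node_count(n, ratio)
        picked.append(sl.start + rng.choice(n, size=k, replace=False))
    return np.sort(np.concatenate(picked)) if picked else np.zeros(0, np.int64)


def remask_views(latent: LatentGraph, K: int, ratio: float,
                 remask_token: Tensor, seed: int = 0) -> ViewBatch:
    """Draw K independent remask sets and build the corresponding views.

    Each view replaces the latent rows of its remask set with the
    learnable decoder-side ``remask_token``. ``K = 0`` returns the latent
    unchanged (passthrough, the "no remask" baseline).
    """
    if K < 0:
        raise ConfigurationError(f"number of views must be >= 0, got {K}")
    target_idx = latent.masked_idx
    if K == 0:
        return ViewBatch([latent.node_h], [np.zeros(0, np.int64)],
                         ratio, 0, target_idx)
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError(f"remask ratio must be in (0, 1), got {ratio}")
    views, sets = [], []
    for j in range(K):
        rng = np.random.default_rng((seed, j))
        idx = _draw_remask(latent.batch, ratio, rng)
        flags = np.zeros((latent.batch.n_nodes, 1))
        flags[idx] = 1.0
        views.append(latent.node_h * (1.0 - flags) + remask_token * flags)
        sets.append(idx)
    return ViewBatch(views, sets, ratio, K, target_idx)


def sce(x, z, gamma: float = 2.0, eps: float = 1e-8) -> Tensor:
    """Scaled Cosine Error: mean over rows of (1 - cos(x_i, z_i))^γ."""
    if gamma <= 1.0:
        raise ConfigurationError(f"SCE gamma must be > 1, got {gamma}")
    x, z = as_tensor(x), as_tensor(z)
    if x.shape != z.shape:
        raise ContractError(f"shape mismatch in SCE: {x.shape} vs {z.shape}")
    if x.ndim == 1:
        x, z = x.reshape(1, -1), z.reshape(1, -1)
    cos = cosine_rows(x, z, eps=eps)
    return ((1.0 - cos) ** gamma).mean()


def multiview_loss(targets: np.ndarray, reconstructions: list[Tensor],
                   target_idx: np.ndarray, gamma: float = 2.0) -> Tensor:
    """Average SCE over views, evaluated on the originally masked nodes.

    ``targets`` are the tokenizer output (already outside the autodiff
    tape); ``target_idx`` is normally the input MaskPlan's masked set, so
    the loss scores exactly the nodes the encoder never saw.
    """
    if not reconstructions:
        raise ConfigurationError("multiview loss needs at least one view")
    target_idx = np.asarray(target_idx, dtype=np.int64)
    if target_idx.size == 0:
        raise ContractError("empty target index set for the reconstruction loss")
    targets = np.asarray(targets, dtype=np.float64)[target_idx]
    total = None
    for z in reconstructions:
        from ._autodiff import gather_rows
        term = sce(Tensor(targets), gather_rows(z, target_idx), gamma=gamma)
        total = term if total is None else total + term
    return total * (1.0 / len(reconstructions))
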