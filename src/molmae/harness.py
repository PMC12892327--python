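"""Training harness: masked-autoencoder pretraining, fusion pretraining,
fine-tuning with ROC-AUC / RMSE reporting, checkpointing and ablations.

Every loop is CPU-deterministic given the config seed: parameter
initialization, batch order, input masks and remask draws all derive
from it, so a repeated run reproduces the loss trajectory bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from ._autodiff import Tensor, log, sigmoid, spmm
from .batching import GraphBatch
from .config import RunConfig, config_hash
from .decoder import GraphTransformerDecoder
from .encoder import GraphEncoder, batch_with_masks, mask_graph
from .exceptions import ConfigurationError, DatasetError
from .fusion import (
    DualViewHeads,
    ProjectionHead,
    QFormer,
    SequenceEncoder,
    dual_tower_loss,
    dual_view_loss,
    qformer_loss,
)
from .molio import MolecularGraph, N_ATOM_TYPES, N_CHIRALITY_TAGS, TaskDataset
from .objectives import multiview_loss, remask_views
from .tokenizer import GraphTokenizer

logger = logging.getLogger(__name__)

__all__ = ["PretrainModel", "MetricReport", "Checkpoint", "pretrain",
           "fuse_pretrain", "finetune", "evaluate_ablation"]

RAW_FEATURE_DIM = N_ATOM_TYPES + N_CHIRALITY_TAGS


@dataclass
class Checkpoint:
    """Serialized weights + config hash, round-trippable through one file."""

    state: dict[str, np.ndarray]
    config: dict
    hash: str

    def save(self, path: str | Path) -> None:
        np.savez(Path(path), __meta__=np.array(
            json.dumps({"config": self.config, "hash": self.hash})),
            **self.state)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(state, meta["config"], meta["hash"])


@dataclass
class MetricReport:
    metric: str                      # "roc_auc" | "rmse"
    per_seed: list[float]
    mean: float
    split_sizes: dict[str, int]
    config_hash: str

    def __post_init__(self):
        if self.metric == "roc_auc" and not all(0 <= v <= 1 for v in self.per_seed):
            raise ValueError("ROC-AUC values must lie in [0, 1]")
        if self.metric == "rmse" and any(v < 0 for v in self.per_seed):
            raise ValueError("RMSE must be non-negative")


class PretrainModel(nn.Module):
    """Encoder + parameter-free tokenizer + Graph-Transformer decoder."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.encoder = GraphEncoder(
            hidden_dim=config.encoder.hidden_dim, arch=config.encoder.arch,
            depth=config.encoder.depth, seed=config.train.seed)
        self.graph_tokenizer = GraphTokenizer(
            hops=config.tokenizer.hops, norm=config.tokenizer.norm,
            include_h0=config.tokenizer.include_h0)
        if config.objective.target == "tokens":
            out_dim = self.graph_tokenizer.out_multiplier * config.encoder.hidden_dim
        else:
            out_dim = RAW_FEATURE_DIM
        self.decoder = GraphTransformerDecoder(
            latent_dim=config.encoder.hidden_dim, out_dim=out_dim,
            hidden_dim=config.decoder.hidden_dim, n_heads=config.decoder.heads,
            n_layers=config.decoder.layers, dmpn_hops=config.decoder.dmpn_hops,
            seed=config.train.seed + 1,
            long_range_residual=config.decoder.long_range_residual)

    def targets(self, batch: GraphBatch) -> np.ndarray:
        if self.config.objective.target == "tokens":
            return self.graph_tokenizer.tokenize(batch, self.encoder.embedding).tokens
        onehot = np.zeros((batch.n_nodes, RAW_FEATURE_DIM))
        onehot[np.arange(batch.n_nodes), batch.node_attrs[:, 0]] = 1.0
        onehot[np.arange(batch.n_nodes),
               N_ATOM_TYPES + batch.node_attrs[:, 1]] = 1.0
        return onehot

    def batch_loss(self, graphs: list[MolecularGraph], mask_seed: int,
                   remask_seed: int) -> Tensor:
        cfg = self.config
        plans = [mask_graph(g, cfg.mask.ratio, mask_seed + i)[1]
                 for i, g in enumerate(graphs)]
        batch = batch_with_masks(graphs, plans)
        targets = self.targets(batch)
        latent = self.encoder.encode(batch, plans)
        ratio = cfg.objective.remask_ratio or cfg.mask.ratio
        views = remask_views(latent, cfg.objective.views, ratio,
                             self.decoder.remask_token, seed=remask_seed)
        recons = [self.decoder.decode(v, batch)[0] for v in views.views]
        if cfg.objective.support == "all":
            target_idx = np.arange(batch.n_nodes)
        else:
            target_idx = views.target_idx
        return multiview_loss(targets, recons, target_idx,
                              gamma=cfg.objective.gamma)


def _graphs_of(corpus) -> list[MolecularGraph]:
    if isinstance(corpus, TaskDataset):
        return corpus.graphs
    return list(corpus)


def pretrain(corpus, config: RunConfig
             ) -> tuple[PretrainModel, Checkpoint, list[float]]:
    """Masked-autoencoder pretraining loop.

    Per batch: mask -> tokenize (stop-gradient targets) -> encode ->
    remask K views -> decode each -> averaged SCE -> Adam step. Returns
    the trained model, a checkpoint, and the per-epoch mean loss.
    """
    graphs = _graphs_of(corpus)
    if not graphs:
        raise DatasetError("pretraining corpus is empty")
    model = PretrainModel(config)
    opt = nn.Adam(model.parameters(), lr=config.train.lr)
    rng = np.random.default_rng(config.train.seed)
    bs = config.train.batch_size
    epoch_losses: list[float] = []
    for epoch in range(config.train.epochs):
        order = rng.permutation(len(graphs))
        losses = []
        for start in range(0, len(graphs), bs):
            chunk = [graphs[i] for i in order[start:start + bs]]
            mask_seed = int(rng.integers(2 ** 31 - len(chunk)))
            remask_seed = int(rng.integers(2 ** 31))
            loss = model.batch_loss(chunk, mask_seed, remask_seed)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start} "
                    f"(molecules {[g.smiles for g in chunk[:3]]}...)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_losses.append(float(np.mean(losses)))
        if epoch % 20 == 0 or epoch == config.train.epochs - 1:
            logger.info("pretrain epoch %d loss %.5f", epoch, epoch_losses[-1])
    ckpt = Checkpoint(model.state_dict(), config.model_dump(),
                      config_hash(config))
    return model, ckpt, epoch_losses


def _default_tau(strategy: str) -> float:
    return 0.1 if strategy == "qformer" else 0.5


def fuse_pretrain(pairs: list[tuple[MolecularGraph, str]], strategy: str,
                  config: RunConfig, encoder: GraphEncoder | None = None
                  ) -> tuple[dict, list[float]]:
    """Joint graph-sequence pretraining under one fusion strategy.

    Returns the trained modules (dict with ``encoder``, ``seq_encoder``
    and strategy heads) and the per-epoch mean loss.
    """
    if strategy not in ("dual_tower", "qformer", "dual_view"):
        raise ConfigurationError(f"unknown fusion strategy: {strategy!r}")
    if not pairs:
        raise DatasetError("fusion corpus is empty")
    cfg = config
    tau = cfg.fusion.tau if cfg.fusion.tau is not None else _default_tau(strategy)
    if encoder is None:
        encoder = GraphEncoder(hidden_dim=cfg.encoder.hidden_dim,
                               arch=cfg.encoder.arch, depth=cfg.encoder.depth,
                               seed=cfg.train.seed)
    seq_encoder = SequenceEncoder(dim=cfg.fusion.seq_dim,
                                  n_layers=cfg.fusion.seq_layers,
                                  n_heads=cfg.fusion.seq_heads,
                                  seed=cfg.train.seed + 10)
    modules: dict = {"encoder": encoder, "seq_encoder": seq_encoder}
    d_g, d_s = cfg.encoder.hidden_dim, cfg.fusion.seq_dim
    if strategy == "dual_tower":
        modules["proj_g"] = ProjectionHead(d_g, cfg.fusion.proj_dim, 2,
                                           seed=cfg.train.seed + 20)
        modules["proj_s"] = ProjectionHead(d_s, cfg.fusion.proj_dim, 2,
                                           seed=cfg.train.seed + 21)
    elif strategy == "qformer":
        modules["qformer"] = QFormer(dim=cfg.fusion.proj_dim,
                                     n_tokens=cfg.fusion.qformer_tokens,
                                     n_layers=cfg.fusion.qformer_layers,
                                     graph_dim=d_g, seed=cfg.train.seed + 20)
        modules["proj_s"] = ProjectionHead(d_s, cfg.fusion.proj_dim, 2,
                                           seed=cfg.train.seed + 21)
    else:
        modules["heads"] = DualViewHeads(d_g, d_s, cfg.fusion.proj_dim,
                                         cfg.fusion.proj_layers,
                                         seed=cfg.train.seed + 20)

    params: list = []
    for mod in modules.values():
        params.extend(mod.parameters())
    opt = nn.Adam(params, lr=cfg.train.lr)
    rng = np.random.default_rng(cfg.train.seed)
    bs = cfg.train.batch_size
    epoch_losses: list[float] = []
    for epoch in range(cfg.train.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), bs):
            chunk = [pairs[i] for i in order[start:start + bs]]
            if len(chunk) == 1 and strategy in ("dual_tower", "qformer"):
                logger.warning("contrastive batch of size 1 has no negatives")
            graphs = [g for g, _ in chunk]
            smiles = [s for _, s in chunk]
            if strategy == "dual_view":
                # Masked views of both modalities, per the consistency loss.
                plans = [mask_graph(g, cfg.mask.ratio,
                                    int(rng.integers(2 ** 31)))[1]
                         for g in graphs]
                batch = batch_with_masks(graphs, plans)
                f_g = spmm(batch.pool_matrix("mean", "nodes"), encoder(batch))
                f_s = nn.mean_rows(
                    [seq_encoder.encode_masked(s, cfg.mask.ratio, rng).reshape(-1)
                     for s in smiles])
                loss = dual_view_loss(modules["heads"], f_g, f_s)
            else:
                batch = GraphBatch(graphs)
                g_vec = spmm(batch.pool_matrix("mean", "nodes"), encoder(batch))
                s_vec = seq_encoder.encode_batch(smiles)
                if strategy == "dual_tower":
                    x = modules["proj_g"](g_vec)
                    y = modules["proj_s"](s_vec)
                    loss = dual_tower_loss(x, y, tau)
                else:
                    node_h = encoder(batch)
                    from ._autodiff import gather_rows
                    per_mol = [gather_rows(node_h, np.arange(
                        batch.node_offsets[m], batch.node_offsets[m + 1]))
                        for m in range(batch.n_mols)]
                    tokens = modules["qformer"].embed_batch(per_mol)
                    t = modules["proj_s"](s_vec)
                    loss = qformer_loss(tokens, t, tau)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite fusion loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_losses.append(float(np.mean(losses)))
        if epoch % 20 == 0 or epoch == cfg.train.epochs - 1:
            logger.info("fusion(%s) epoch %d loss %.5f", strategy, epoch,
                        epoch_losses[-1])
    return modules, epoch_losses


# -- fine-tuning ---------------------------------------------------------

def _bce_masked(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Binary cross-entropy averaged over observed (non-NaN) entries."""
    observed = np.isfinite(labels)
    y = np.where(observed, labels, 0.0)
    w = observed.astype(np.float64)
    p = sigmoid(logits)
    eps = 1e-12
    nll = -(y * log(p + eps) + (1.0 - y) * log(1.0 - p + eps))
    return (nll * w).sum() * (1.0 / max(w.sum(), 1.0))


def _mse(pred: Tensor, labels: np.ndarray) -> Tensor:
    diff = pred - labels
    return (diff * diff).mean()


def _predict(encoder: GraphEncoder, head: nn.Linear,
             graphs: list[MolecularGraph], readout: str,
             batch_size: int = 128) -> np.ndarray:
    outs = []
    for start in range(0, len(graphs), batch_size):
        batch = GraphBatch(graphs[start:start + batch_size])
        outs.append(head(encoder.pooled(batch, readout)).data)
    return np.vstack(outs)


def _auc_over_tasks(scores: np.ndarray, labels: np.ndarray) -> float:
    aucs = []
    for t in range(labels.shape[1]):
        observed = np.isfinite(labels[:, t])
        y = labels[observed, t]
        if len(np.unique(y)) < 2:
            logger.info("task %d has a single class in the test split; "
                        "excluded from the AUC mean", t)
            continue
        aucs.append(roc_auc_score(y, scores[observed, t]))
    if not aucs:
        raise DatasetError("no task with both classes in the test split")
    return float(np.mean(aucs))


def finetune(encoder_source, dataset: TaskDataset, config: RunConfig
             ) -> MetricReport:
    """Fine-tune (or probe) the encoder with a linear task head.

    Classification reports per-task ROC-AUC averaged over tasks (missing
    labels excluded, single-class tasks dropped with a log line);
    regression reports RMSE. Repeats over ``config.train.seeds`` and
    reports the mean.
    """
    dataset.validate_split()
    cfg = config
    train_idx = dataset.split["train"]
    if cfg.finetune.eval_split == "heldout":
        test_idx = sorted(dataset.split["valid"] + dataset.split["test"])
    else:
        test_idx = dataset.split[cfg.finetune.eval_split] \
            or dataset.split["test"] or dataset.split["valid"]
    train_graphs = [dataset.graphs[i] for i in train_idx]
    y_train = dataset.labels[np.asarray(train_idx, dtype=int)]
    test_graphs = [dataset.graphs[i] for i in test_idx]
    y_test = dataset.labels[np.asarray(test_idx, dtype=int)]
    is_clf = dataset.task_type == "classification"

    per_seed: list[float] = []
    for seed in cfg.train.seeds:
        encoder = GraphEncoder(hidden_dim=cfg.encoder.hidden_dim,
                               arch=cfg.encoder.arch, depth=cfg.encoder.depth,
                               seed=seed)
        if isinstance(encoder_source, PretrainModel):
            encoder.load_state_dict(encoder_source.encoder.state_dict())
        elif isinstance(encoder_source, GraphEncoder):
            encoder.load_state_dict(encoder_source.state_dict())
        elif isinstance(encoder_source, Checkpoint):
            state = {k[len("encoder."):]: v
                     for k, v in encoder_source.state.items()
                     if k.startswith("encoder.")}
            encoder.load_state_dict(state)
        elif encoder_source is not None:
            raise ConfigurationError(
                f"cannot fine-tune from {type(encoder_source).__name__}")
        rng = np.random.default_rng(seed)
        head = nn.Linear(cfg.encoder.hidden_dim, dataset.n_tasks, rng)
        params = head.parameters()
        if cfg.finetune.tune_encoder:
            params = params + encoder.parameters()
        opt = nn.Adam(params, lr=cfg.finetune.lr)
        bs = cfg.finetune.batch_size
        for _ in range(cfg.finetune.epochs):
            order = rng.permutation(len(train_graphs))
            for start in range(0, len(train_graphs), bs):
                idx = order[start:start + bs]
                batch = GraphBatch([train_graphs[i] for i in idx])
                out = head(encoder.pooled(batch, cfg.finetune.readout))
                loss = _bce_masked(out, y_train[idx]) if is_clf \
                    else _mse(out, y_train[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        scores = _predict(encoder, head, test_graphs, cfg.finetune.readout)
        if is_clf:
            per_seed.append(_auc_over_tasks(scores, y_test))
        else:
            per_seed.append(float(np.sqrt(np.nanmean((scores - y_test) ** 2))))
    return MetricReport(
        metric="roc_auc" if is_clf else "rmse",
        per_seed=per_seed, mean=float(np.mean(per_seed)),
        split_sizes={k: len(v) for k, v in dataset.split.items()},
        config_hash=config_hash(config))


def evaluate_ablation(base_config: RunConfig, grid: dict[str, dict],
                      corpus, dataset: TaskDataset) -> list[dict]:
    """Run pretrain + finetune for each named config delta.

    Returns one row per grid cell (JSON-serializable), with the delta
    name, the applied overrides and the resulting MetricReport fields.
    An empty grid returns an empty table.
    """
    from .config import apply_deltas

    rows: list[dict] = []
    for name, deltas in grid.items():
        cfg = apply_deltas(base_config, deltas)
        model, _, _ = pretrain(corpus, cfg)
        report = finetune(model, dataset, cfg)
        rows.append({"name": name, "deltas": deltas, "metric": report.metric,
                     "per_seed": report.per_seed, "mean": report.mean,
                     "config_hash": report.config_hash})
    return rows
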