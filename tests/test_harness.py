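"""Training harness: metrics, determinism, checkpoints, config, ablation."""

import numpy as np
import pytest

from molmae.batching import GraphBatch
from molmae.config import apply_deltas, config_hash, make_config
from molmae.exceptions import ConfigurationError, DatasetError
from molmae.harness import (
    Checkpoint,
    MetricReport,
    PretrainModel,
    _auc_over_tasks,
    evaluate_ablation,
    finetune,
    fuse_pretrain,
    pretrain,
)
from molmae.molio import random_split, scaffold_split
from molmae.synthdata import FixtureSpec, generate_corpus, make_pairs


def tiny_config(**over):
    base = {"encoder": {"hidden_dim": 16}, "decoder": {"hidden_dim": 16},
            "train": {"epochs": 3, "batch_size": 8, "seed": 0, "seeds": [0]},
            "finetune": {"epochs": 5, "batch_size": 32}}
    for k, v in over.items():
        base.setdefault(k, {}).update(v)
    return make_config(base)


class TestMetrics:
    def test_perfect_ranking_gives_auc_one(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = np.array([[1.0], [1.0], [0.0], [0.0]])
        assert _auc_over_tasks(scores, labels) == 1.0

    def test_half_concordant_ranking_gives_auc_half(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = np.array([[1.0], [0.0], [0.0], [1.0]])
        assert _auc_over_tasks(scores, labels) == 0.5

    def test_single_class_task_excluded(self):
        scores = np.random.default_rng(0).normal(size=(4, 2))
        labels = np.column_stack([[1.0, 1.0, 1.0, 1.0], [1.0, 0.0, 1.0, 0.0]])
        _auc_over_tasks(scores, labels)  # only task 2 counted, no error
        with pytest.raises(DatasetError):
            _auc_over_tasks(scores[:, :1], labels[:, :1])

    def test_metric_report_validates_ranges(self):
        with pytest.raises(ValueError):
            MetricReport("roc_auc", [1.2], 1.2, {}, "x")
        with pytest.raises(ValueError):
            MetricReport("rmse", [-0.1], -0.1, {}, "x")


class TestConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            make_config({"encoder": {"hidden": 32}})
        with pytest.raises(ConfigurationError):
            make_config({"encoderr": {}})

    def test_hash_changes_iff_config_changes(self):
        a = make_config({})
        b = make_config({})
        c = make_config({"mask": {"ratio": 0.3}})
        assert config_hash(a) == config_hash(b)
        assert config_hash(a) != config_hash(c)

    def test_apply_deltas_validates(self):
        cfg = make_config({})
        out = apply_deltas(cfg, {"objective": {"views": 2}})
        assert out.objective.views == 2
        with pytest.raises(ConfigurationError):
            apply_deltas(cfg, {"objective": {"view": 2}})

    def test_defaults_match_study_optima(self):
        cfg = make_config({})
        assert cfg.mask.ratio == 0.45
        assert cfg.encoder.arch == "gin" and cfg.encoder.depth == 3
        assert cfg.decoder.heads == 2
        assert cfg.fusion.qformer_tokens == 16


class TestPretrain:
    def test_deterministic_loss_trajectory(self, small_corpus):
        cfg = tiny_config()
        _, _, l1 = pretrain(small_corpus, cfg)
        _, _, l2 = pretrain(small_corpus, cfg)
        assert l1 == l2

    def test_zero_epochs_yields_initial_checkpoint(self, small_corpus):
        cfg = tiny_config(train={"epochs": 0})
        model, ckpt, losses = pretrain(small_corpus, cfg)
        assert losses == []
        fresh = PretrainModel(cfg)
        for k, v in fresh.state_dict().items():
            np.testing.assert_array_equal(ckpt.state[k], v)

    def test_empty_corpus_rejected(self):
        with pytest.raises(DatasetError):
            pretrain([], tiny_config())

    def test_loss_decreases(self, small_corpus):
        cfg = tiny_config(train={"epochs": 10})
        _, _, losses = pretrain(small_corpus, cfg)
        assert losses[-1] < losses[0]


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, small_corpus, tmp_path):
        cfg = tiny_config()
        model, ckpt, _ = pretrain(small_corpus, cfg)
        path = tmp_path / "ckpt.npz"
        ckpt.save(path)
        loaded = Checkpoint.load(path)
        assert loaded.hash == ckpt.hash
        clone = PretrainModel(make_config(loaded.config))
        clone.load_state_dict(loaded.state)
        batch = GraphBatch(small_corpus.graphs[:4])
        np.testing.assert_array_equal(clone.encoder(batch).data,
                                      model.encoder(batch).data)


@pytest.fixture(scope="module")
def pairs():
    return make_pairs(generate_corpus(FixtureSpec(n_molecules=16, seed=2)))


@pytest.fixture(scope="module")
def clf_task():
    ds = generate_corpus(FixtureSpec(n_molecules=80, seed=4,
                                     task="ring_presence", ring_fraction=0.9))
    return scaffold_split(ds)


class TestFusePretrain:
    @pytest.mark.parametrize("strategy", ["dual_tower", "qformer", "dual_view"])
    def test_all_strategies_train_and_loss_drops(self, pairs, strategy):
        cfg = tiny_config(train={"epochs": 4, "batch_size": 8},
                          fusion={"proj_dim": 16, "seq_dim": 16,
                                  "qformer_tokens": 4})
        _, losses = fuse_pretrain(pairs, strategy, cfg)
        assert losses[-1] < losses[0]

    def test_unknown_strategy_rejected(self, pairs):
        with pytest.raises(ConfigurationError):
            fuse_pretrain(pairs, "3d", tiny_config())

    def test_batch_of_one_warns_about_missing_negatives(self, pairs, caplog):
        cfg = tiny_config(train={"epochs": 1, "batch_size": 1},
                          fusion={"proj_dim": 8, "seq_dim": 8})
        with caplog.at_level("WARNING", logger="molmae.harness"):
            fuse_pretrain(pairs[:1], "dual_tower", cfg)
        assert any("no negatives" in r.message for r in caplog.records)

    def test_dual_view_loss_reaches_alignment(self):
        """On a small paired corpus the consistency loss falls below -1
        (its range is [-2, 2]); this is the training sanity bound."""
        pairs = make_pairs(generate_corpus(FixtureSpec(n_molecules=64, seed=3)))
        cfg = tiny_config(train={"epochs": 25, "batch_size": 16, "lr": 3e-3},
                          fusion={"proj_dim": 16, "seq_dim": 16})
        _, losses = fuse_pretrain(pairs, "dual_view", cfg)
        assert losses[-1] < -1.0


class TestFinetune:
    def test_reports_auc_for_classification(self, clf_task):
        cfg = tiny_config(finetune={"epochs": 8, "eval_split": "heldout"})
        report = finetune(None, clf_task, cfg)
        assert report.metric == "roc_auc"
        assert 0.0 <= report.mean <= 1.0
        assert report.split_sizes["train"] > 0

    def test_regression_reports_rmse(self):
        ds = random_split(generate_corpus(
            FixtureSpec(n_molecules=60, seed=5, task="n_heteroatoms")), seed=0)
        cfg = tiny_config(finetune={"epochs": 8, "readout": "sum"})
        report = finetune(None, ds, cfg)
        assert report.metric == "rmse" and report.mean >= 0.0

    def test_mean_over_seeds(self, clf_task):
        cfg = tiny_config(train={"seeds": [0, 1]},
                          finetune={"epochs": 4, "eval_split": "heldout"})
        report = finetune(None, clf_task, cfg)
        assert len(report.per_seed) == 2
        assert report.mean == pytest.approx(np.mean(report.per_seed))

    def test_missing_split_rejected(self):
        ds = generate_corpus(FixtureSpec(n_molecules=10, seed=6))
        with pytest.raises(DatasetError):
            finetune(None, ds, tiny_config())


class TestAblation:
    def test_empty_grid_gives_empty_table(self, small_corpus):
        ds = scaffold_split(generate_corpus(
            FixtureSpec(n_molecules=40, seed=7, task="ring_presence",
                        ring_fraction=0.9)))
        assert evaluate_ablation(tiny_config(), {}, small_corpus, ds) == []

    def test_grid_rows_and_identity_delta(self, small_corpus):
        ds = scaffold_split(generate_corpus(
            FixtureSpec(n_molecules=40, seed=7, task="ring_presence",
                        ring_fraction=0.9)))
        cfg = tiny_config(train={"epochs": 2},
                          finetune={"epochs": 3, "eval_split": "heldout"})
        grid = {"full": {}, "no_remask": {"objective": {"views": 0}}}
        rows = evaluate_ablation(cfg, grid, small_corpus, ds)
        assert [r["name"] for r in rows] == ["full", "no_remask"]
        # identity delta reproduces the direct pipeline exactly
        model, _, _ = pretrain(small_corpus, cfg)
        direct = finetune(model, ds, cfg)
        assert rows[0]["per_seed"] == direct.per_seed

    def test_invalid_delta_key_rejected(self, small_corpus):
        ds = scaffold_split(generate_corpus(
            FixtureSpec(n_molecules=40, seed=7, task="ring_presence",
                        ring_fraction=0.9)))
        with pytest.raises(ConfigurationError):
            evaluate_ablation(tiny_config(), {"bad": {"objective": {"nope": 1}}},
                              small_corpus, ds)
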