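"""Training pipeline: splits, budgets, degeneracies, experiment schema."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

from attnguide import (
    AttentionBudget,
    AugmentationConfig,
    LossConfig,
    RadiographSample,
    SplitSpec,
    TrainConfig,
    assign_attention_budget,
    split_dataset,
    train_model,
)
from attnguide.training import (
    _cosine_lr,
    evaluate_model,
    run_experiment,
)


def _stub_samples(counts):
    out = []
    for cls, n in counts.items():
        for i in range(n):
            out.append(SimpleNamespace(class_label=cls, sample_id=f"{cls}-{i}"))
    return out


def _masked_samples(n, cls="CystTumor"):
    img = np.zeros((64, 64))
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[32, 32] = 1
    return [
        RadiographSample(image=img, class_label=cls, sample_id=f"{cls}-{i}",
                         attention_label=mask.copy())
        for i in range(n)
    ]


TINY_TRAIN = dict(
    backbone="tiny",
    epochs=2,
    cosine_T_max=2,
    patience=2,
    batch_size=4,
    learning_rate=1e-3,
)


def _tiny_config(**kw):
    base = dict(TINY_TRAIN)
    base.setdefault("augmentation", AugmentationConfig(crop_size=(80, 80)))
    base.update(kw)
    return TrainConfig(**base)


class TestSplitDataset:
    def test_ten_samples_6_2_2(self):
        samples = _stub_samples({"Normal": 10})
        tr, va, te = split_dataset(samples, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_floor_counts_remainder_train_first(self):
        samples = _stub_samples({"Normal": 270, "CystTumor": 273, "LMBD": 173})
        tr, va, te = split_dataset(samples, SplitSpec(seed=1))

        def per_class(part, cls):
            return sum(1 for s in part if s.class_label == cls)

        # floor(r*n) with leftovers handed out train-first
        assert [per_class(p, "Normal") for p in (tr, va, te)] == [162, 54, 54]
        assert [per_class(p, "CystTumor") for p in (tr, va, te)] == [164, 55, 54]
        assert [per_class(p, "LMBD") for p in (tr, va, te)] == [104, 35, 34]

    def test_partition_disjoint_and_exhaustive(self):
        samples = _stub_samples({"Normal": 17, "CystTumor": 11})
        tr, va, te = split_dataset(samples, SplitSpec(seed=3))
        ids = [s.sample_id for s in tr + va + te]
        assert len(ids) == len(set(ids)) == len(samples)

    def test_same_seed_identical(self):
        samples = _stub_samples({"Normal": 20, "LMBD": 15})
        a = split_dataset(samples, SplitSpec(seed=9))
        b = split_dataset(samples, SplitSpec(seed=9))
        for pa, pb in zip(a, b):
            assert [s.sample_id for s in pa] == [s.sample_id for s in pb]

    def test_small_class_rejected(self):
        samples = _stub_samples({"Normal": 10, "LMBD": 2})
        with pytest.raises(ValueError, match="fewer than 3"):
            split_dataset(samples, SplitSpec(seed=0))

    def test_bad_ratios(self):
        with pytest.raises(ValueError):
            SplitSpec(ratios=(0.5, 0.2, 0.2))


class TestAttentionBudget:
    def test_rate_zero_flags_nothing(self):
        out = assign_attention_budget(_masked_samples(10), AttentionBudget(0.0, seed=0))
        assert not any(s.use_attention for s in out)

    def test_rate_one_flags_all(self):
        out = assign_attention_budget(_masked_samples(10), AttentionBudget(1.0, seed=0))
        assert all(s.use_attention for s in out)

    def test_exact_ceil_count_259(self):
        out = assign_attention_budget(
            _masked_samples(259), AttentionBudget(0.05, seed=4)
        )
        assert sum(s.use_attention for s in out) == 13  # ceil(0.05 * 259)

    def test_exact_count_100_at_5pct(self):
        out = assign_attention_budget(
            _masked_samples(100), AttentionBudget(0.05, seed=4)
        )
        assert sum(s.use_attention for s in out) == 5

    @pytest.mark.parametrize("r1,r2", [(0.1, 0.3), (0.2, 0.9), (0.0, 1.0)])
    def test_budget_monotone_subset(self, r1, r2):
        samples = _masked_samples(40)
        lo = assign_attention_budget(samples, AttentionBudget(r1, seed=11))
        hi = assign_attention_budget(samples, AttentionBudget(r2, seed=11))
        lo_ids = {s.sample_id for s in lo if s.use_attention}
        hi_ids = {s.sample_id for s in hi if s.use_attention}
        assert lo_ids <= hi_ids

    def test_unmasked_samples_never_flagged(self):
        img = np.zeros((64, 64))
        samples = _masked_samples(5) + [
            RadiographSample(image=img, class_label="Normal", sample_id=f"N-{i}")
            for i in range(5)
        ]
        out = assign_attention_budget(samples, AttentionBudget(1.0, seed=0))
        for s in out:
            if s.attention_label is None:
                assert not s.use_attention

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            AttentionBudget(1.5)


class TestCosineSchedule:
    def test_endpoints(self):
        assert _cosine_lr(1e-3, 0, 50) == pytest.approx(1e-3)
        assert _cosine_lr(1e-3, 50, 50) == pytest.approx(0.0, abs=1e-18)

    def test_two_arcs_over_100_epochs(self):
        # T_max=50 over 100 epochs: anneal to zero then back up
        assert _cosine_lr(1e-3, 100, 50) == pytest.approx(1e-3)

    def test_midpoint(self):
        assert _cosine_lr(2.0, 25, 50) == pytest.approx(1.0)


class TestTrainConfig:
    def test_paper_protocol_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.weight_decay == pytest.approx(1e-5)
        assert cfg.cosine_T_max == 50
        assert cfg.epochs == 100
        assert cfg.batch_size == 8
        assert cfg.patience == 40
        assert cfg.repeats == 5
        assert cfg.dropout_rate == 0.25
        assert cfg.optimizer == "sgd"

    def test_from_dict_nested(self):
        cfg = TrainConfig.from_dict(
            {
                "epochs": 5,
                "patience": 5,
                "loss": {"omega": 10.0},
                "augmentation": {"crop_size": [80, 80], "enabled_ops": ["flip"]},
            }
        )
        assert cfg.loss.omega == 10.0
        assert cfg.augmentation.crop_size == (80, 80)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = _tiny_config()
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = TrainConfig.from_yaml(path)
        assert back == cfg

    def test_invalid_optimizer(self):
        with pytest.raises(ValueError):
            TrainConfig(optimizer="lbfgs")

    def test_patience_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, patience=11)


class TestTrainModel:
    def _split(self, small_dataset, seed=0, rate=1.0):
        samples, _ = small_dataset
        tr, va, te = split_dataset(samples, SplitSpec(seed=seed))
        tr = assign_attention_budget(tr, AttentionBudget(rate, seed=seed))
        return tr, va, te

    def test_runs_and_reports_history(self, small_dataset):
        tr, va, te = self._split(small_dataset)
        res = train_model(tr, va, _tiny_config(seed=0),
                          test_ids={s.sample_id for s in te})
        assert len(res.history) == 2
        assert res.best_val_accuracy == max(h["val_accuracy"] for h in res.history)

    def test_same_seed_identical_loss_history(self, small_dataset):
        tr, va, _ = self._split(small_dataset)
        a = train_model(tr, va, _tiny_config(seed=7))
        b = train_model(tr, va, _tiny_config(seed=7))
        assert [h["train_total"] for h in a.history] == [
            h["train_total"] for h in b.history
        ]
        for ka, kb in zip(a.model.parameters, b.model.parameters):
            np.testing.assert_array_equal(ka.data, kb.data)

    def test_rate0_equals_alpha_att0_trajectory(self, small_dataset):
        tr0, va, _ = self._split(small_dataset, rate=0.0)
        tr1, _, _ = self._split(small_dataset, rate=1.0)
        cfg_r0 = _tiny_config(seed=5)
        cfg_a0 = _tiny_config(seed=5, loss=LossConfig(alpha_att=0.0))
        a = train_model(tr0, va, cfg_r0)
        b = train_model(tr1, va, cfg_a0)
        assert [h["train_total"] for h in a.history] == [
            h["train_total"] for h in b.history
        ]
        assert all(h["train_att"] == 0.0 for h in a.history)

    def test_loss_decomposition_every_batch(self, small_dataset):
        tr, va, _ = self._split(small_dataset, rate=1.0)
        cfg = _tiny_config(seed=3)
        res = train_model(tr, va, cfg)
        for entry in res.batch_log:
            expected = (
                cfg.loss.alpha_cls * entry["cls"] + cfg.loss.alpha_att * entry["att"]
            )
            assert entry["total"] == pytest.approx(expected, abs=1e-6)

    def test_leak_detection_raises(self, small_dataset):
        tr, va, _ = self._split(small_dataset)
        leaked = {tr[0].sample_id}
        with pytest.raises(RuntimeError, match="leak"):
            train_model(tr, va, _tiny_config(seed=0), test_ids=leaked)

    def test_empty_sets_rejected(self, small_dataset):
        tr, va, _ = self._split(small_dataset)
        with pytest.raises(ValueError):
            train_model([], va, _tiny_config())

    def test_attention_batches_counted_at_full_rate(self, small_dataset):
        tr, va, _ = self._split(small_dataset, rate=1.0)
        res = train_model(tr, va, _tiny_config(seed=2))
        assert res.n_flagged == sum(
            1 for s in tr if s.attention_label is not None
        )
        assert any(e["n_att"] > 0 for e in res.batch_log)

    def test_early_stopping_on_patience(self, small_dataset):
        tr, va, _ = self._split(small_dataset, rate=0.0)
        cfg = _tiny_config(seed=1, epochs=6, cosine_T_max=6, patience=1)
        res = train_model(tr, va, cfg)
        last = res.history[-1]["epoch"]
        assert last - res.best_epoch >= 1 or last == cfg.epochs - 1


class TestEvaluateAndExperiment:
    def test_evaluate_model_shapes(self, small_dataset):
        samples, _ = small_dataset
        tr, va, te = split_dataset(samples, SplitSpec(seed=0))
        tr = assign_attention_budget(tr, AttentionBudget(0.0, seed=0))
        res = train_model(tr, va, _tiny_config(seed=0))
        cm, metrics = evaluate_model(res.model, te, (80, 80))
        assert cm.total == len(te)
        assert 0.0 <= metrics.accuracy <= 100.0

    def test_run_experiment_schema(self, small_dataset, tmp_path):
        samples, _ = small_dataset
        cfg = _tiny_config(seed=0)
        runs, summary = run_experiment(
            samples, rates=(0.0,), config=cfg, repeats=1, out_dir=tmp_path
        )
        assert len(runs) == 1
        assert {"rate", "repeat", "accuracy", "sensitivity", "specificity",
                "localization_iou"} <= set(runs.columns)
        assert (tmp_path / "runs.csv").exists()
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "results.json").exists()

    def test_summary_one_row_per_rate(self, small_dataset):
        samples, _ = small_dataset
        cfg = _tiny_config(seed=0)
        _runs, summary = run_experiment(
            samples, rates=(0.0, 1.0), config=cfg, repeats=1
        )
        assert len(summary) == 2
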