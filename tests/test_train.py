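"""Splitting, Spearman evaluation and the training loop contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonmoe import (SyntheticBackbone, SyntheticTaskSpec, TrainConfig,
                      embed_dataset, make_dataset, spearman, split)
from codonmoe.adapters import make_adapter
from codonmoe.errors import ContractError, ValidationError
from codonmoe.nnops import params_equal
from codonmoe.train import evaluate, train


class TestSplit:
    def test_paper_fractions_at_n_1000(self):
        s = split(1000, seed=0)
        assert (s.train.size, s.val.size, s.test.size) == (700, 150, 150)

    def test_floor_floor_remainder_rule(self):
        s = split(10, seed=0)
        assert (s.train.size, s.val.size, s.test.size) == (7, 1, 2)

    def test_deterministic(self):
        a, b = split(50, seed=3), split(50, seed=3)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)

    @given(n=st.integers(10, 300), seed=st.integers(0, 100))
    def test_partition_properties(self, n, seed):
        s = split(n, seed=seed)
        joined = np.sort(np.concatenate([s.train, s.val, s.test]))
        assert np.array_equal(joined, np.arange(n))

    def test_too_small_n_rejected(self):
        with pytest.raises(ValidationError):
            split(3, seed=0)


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        y = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(y, np.exp(y)) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        y = np.array([1.0, 2.0, 5.0])
        assert spearman(y, -y) == pytest.approx(-1.0)

    def test_three_point_rank_oracle(self):
        # ranks of (1,2,3) vs (3,1,2): Pearson of (1,2,3),(3,1,2) = -0.5
        assert spearman(np.array([1.0, 2, 3]), np.array([3.0, 1, 2])) == \
            pytest.approx(-0.5)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        y = rng.standard_normal(50)
        yhat = rng.standard_normal(50)
        base = spearman(y, yhat)
        assert spearman(np.exp(y), yhat ** 3 + 5 * yhat) == pytest.approx(base)

    def test_self_correlation_is_one(self, rng):
        y = rng.standard_normal(30)
        assert spearman(y, y) == pytest.approx(1.0)

    def test_constant_input_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman(np.ones(5), np.arange(5.0)))

    def test_length_mismatch_is_contract_error(self):
        with pytest.raises(ContractError):
            spearman(np.arange(3.0), np.arange(4.0))


@pytest.fixture(scope="module")
def tiny_task():
    data = make_dataset(SyntheticTaskSpec(n=60, M=5, task_kind="usage",
                                          seed=8, noise_sigma=0.0))
    backbone = SyntheticBackbone(4, seed=2)
    E = embed_dataset(backbone, data.sequences)
    return data, backbone, E


class TestTrainLoop:
    def test_zero_epochs_leaves_params_at_init_with_empty_history(self, tiny_task):
        data, backbone, E = tiny_task
        ad = make_adapter("base", 15, 4)
        cfg = TrainConfig(epochs=0, seed=1)
        result = train(ad, data, backbone, split(60, seed=1), cfg, E)
        assert result.history == []
        assert params_equal(result.params,
                            ad.init_params(np.random.default_rng(
                                np.random.SeedSequence(1).spawn(3)[0])))

    def test_backbone_frozen_through_training(self, tiny_task):
        data, backbone, E = tiny_task
        before = backbone.snapshot()
        ad = make_adapter("mean", 15, 4)
        train(ad, data, backbone, split(60, seed=0), TrainConfig(epochs=3, seed=0), E)
        from codonmoe import freeze_check
        assert freeze_check(before, backbone.snapshot())

    def test_history_records_loss_and_val_spearman(self, tiny_task):
        data, backbone, E = tiny_task
        ad = make_adapter("mean", 15, 4)
        result = train(ad, data, backbone, split(60, seed=0),
                       TrainConfig(epochs=4, seed=0), E)
        assert len(result.history) == 4
        assert {"epoch", "train_loss", "val_spearman"} <= set(result.history[0])
        assert all(np.isfinite(h["train_loss"]) for h in result.history)

    def test_same_seed_reproduces_fit(self, tiny_task):
        data, backbone, E = tiny_task
        s = split(60, seed=2)
        cfg = TrainConfig(epochs=3, seed=7)
        r1 = train(make_adapter("base", 15, 4), data, backbone, s, cfg, E)
        r2 = train(make_adapter("base", 15, 4), data, backbone, s, cfg, E)
        assert params_equal(r1.params, r2.params)

    def test_training_reduces_loss_and_eval_reports_all_splits(self, tiny_task):
        data, backbone, E = tiny_task
        s = split(60, seed=0)
        result = train(make_adapter("mean", 15, 4), data, backbone, s,
                       TrainConfig(epochs=30, seed=0), E)
        assert result.history[-1]["train_loss"] < result.history[0]["train_loss"]
        report = evaluate(result, data, s, backbone, E)
        assert set(report.rho) == {"train", "val", "test"}
        assert report.n == {"train": 42, "val": 9, "test": 9}

    def test_sweep_experts_rows_populated_and_finite(self):
        from codonmoe import sweep_experts
        spec = SyntheticTaskSpec(n=60, M=4, task_kind="hotspot", seed=2)
        table = sweep_experts([1, 4], spec, TrainConfig(epochs=3, seed=0),
                              backbone_dim=4, backbone_seed=2)
        assert list(table["K"]) == [1, 4]
        assert np.all(np.isfinite(table["val_spearman"]))

    def test_variable_lengths_rejected(self, tiny_task):
        from codonmoe import Dataset, SequenceRecord
        records = [SequenceRecord(f"s{i}", "ATGAAA", float(i)) for i in range(9)]
        records.append(SequenceRecord("s9", "ATGAAATTT", 9.0))
        data = Dataset(records)
        _, backbone, _ = tiny_task
        with pytest.raises(ValidationError, match="variable"):
            train(make_adapter("mean", 6, 4), data, backbone,
                  split(10, seed=0), TrainConfig(epochs=1))
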