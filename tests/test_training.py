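"""Grouped splitting, the training loop, checkpointing and fine-tuning."""

import os

import numpy as np
import pytest

from pocketseg import (
    CheckpointError,
    ConfigError,
    DatasetIndex,
    FinetuneSchedule,
    IndexEntry,
    NetConfig,
    TrainConfig,
    build_model,
    grouped_split,
    load_checkpoint,
    save_checkpoint,
    train,
)
from pocketseg.synthetic import make_grid_pair
from pocketseg.training import TrainingHistory, finetune, read_manifest


def index_of(groups: dict[str, int]) -> DatasetIndex:
    entries = [
        IndexEntry(f"{g}_{i}_f.npz", f"{g}_{i}_l.npz", g)
        for g, n in groups.items()
        for i in range(n)
    ]
    return DatasetIndex(entries)


def toy_model(seed=0):
    return build_model(
        NetConfig(grid_side=16, in_channels=18, base_width=4, n_stages=2,
                  attention_heads=2, seed=seed)
    )


def pairs_for(seed, n=3):
    return [make_grid_pair(seed * 100 + i, side=16) for i in range(n)]


class TestGroupedSplit:
    def test_ten_singleton_groups_yield_one_validation_group(self):
        idx = index_of({f"g{i}": 1 for i in range(10)})
        tr, va = grouped_split(idx, fraction=0.1, seed=0)
        assert len(va) == 1 and len(tr) == 9

    def test_groups_stay_whole(self):
        idx = index_of({"big": 5, "a": 1, "b": 1, "c": 1, "d": 1, "e": 1})
        tr, va = grouped_split(idx, fraction=0.5, seed=3)
        for side in (tr, va):
            groups = {e.group_key for e in side.entries}
            if "big" in groups:
                assert sum(e.group_key == "big" for e in side.entries) == 5

    def test_no_group_on_both_sides_union_preserved(self):
        idx = index_of({f"g{i}": (i % 3) + 1 for i in range(12)})
        tr, va = grouped_split(idx, fraction=0.3, seed=1)
        assert {e.group_key for e in tr.entries}.isdisjoint(
            {e.group_key for e in va.entries}
        )
        assert len(tr) + len(va) == len(idx)

    def test_deterministic_given_seed(self):
        idx = index_of({f"g{i}": 2 for i in range(8)})
        a = grouped_split(idx, seed=5)
        b = grouped_split(idx, seed=5)
        assert [e.feature_path for e in a[1].entries] == [
            e.feature_path for e in b[1].entries
        ]

    def test_single_group_raises(self):
        with pytest.raises(ConfigError):
            grouped_split(index_of({"only": 4}), seed=0)


class TestManifest:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text("a_f.npz\ta_l.npz\tprotA\tall_alpha\nb_f.npz\tb_l.npz\tprotB\n")
        idx = read_manifest(path)
        assert len(idx) == 2
        assert idx.entries[0].class_label == "all_alpha"
        assert idx.entries[1].class_label == "unknown"

    def test_bad_class_label_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\tg\tnot_a_class\n")
        with pytest.raises(ConfigError):
            read_manifest(path)


class TestTrainingLoop:
    def test_loss_decreases_on_single_example(self):
        model = toy_model()
        pairs = pairs_for(1, n=1)
        hist = train(
            model, pairs,
            TrainConfig(epochs=10, batch_size=1, learning_rate=1e-3, seed=0),
        )
        assert hist.epochs_run == 10
        assert hist.train_loss[-1] < hist.train_loss[0]
        # overall decreasing trend over the first epochs
        assert np.mean(hist.train_loss[5:]) < np.mean(hist.train_loss[:5])

    def test_history_length_equals_epochs(self):
        model = toy_model()
        hist = train(
            model, pairs_for(2),
            TrainConfig(epochs=3, batch_size=3, learning_rate=1e-3, seed=0),
        )
        assert len(hist.train_loss) == 3

    def test_best_checkpoint_tracks_validation(self, tmp_path):
        model = toy_model()
        hist = train(
            model, pairs_for(3), TrainConfig(epochs=4, batch_size=3,
                                             learning_rate=1e-3, seed=0),
            val_dataset=pairs_for(4, n=2), checkpoint_dir=tmp_path,
        )
        assert hist.best_epoch >= 0
        assert hist.best_val_loss == pytest.approx(min(hist.val_loss))
        assert (tmp_path / "best.npz").exists()

    def test_shape_mismatch_fails_before_training(self):
        model = toy_model()
        bad = [make_grid_pair(0, side=12)]
        with pytest.raises(ConfigError):
            train(model, bad, TrainConfig(epochs=1, batch_size=1, seed=0))


class TestCheckpoints:
    def test_round_trip_forward_bit_identical(self, tmp_path, rng):
        model = toy_model(seed=9)
        hist = TrainingHistory(train_loss=[0.5], val_loss=[0.6])
        path = tmp_path / "ck.npz"
        save_checkpoint(path, model, None, 1, None, hist)
        state = load_checkpoint(path)
        x = rng.random((1, 16, 16, 16, 18)).astype(np.float32)
        np.testing.assert_array_equal(model(x).data, state["model"](x).data)
        assert state["history"].train_loss == [0.5]

    def test_missing_checkpoint_raises(self):
        with pytest.raises(CheckpointError):
            load_checkpoint("/nonexistent/ck.npz")

    def test_resume_reproduces_history(self, tmp_path):
        pairs = pairs_for(5, n=4)
        cfg = dict(batch_size=4, learning_rate=1e-3, seed=7, checkpoint_every=2)

        straight = toy_model(seed=7)
        h1 = train(straight, pairs, TrainConfig(epochs=4, **cfg))

        broken = toy_model(seed=7)
        train(broken, pairs, TrainConfig(epochs=4, **cfg),
              checkpoint_dir=tmp_path, stop_epoch=2)
        resumed = toy_model(seed=7)
        h2 = train(
            resumed, pairs,
            TrainConfig(epochs=4, resume_from=str(tmp_path / "ckpt_epoch_00002.npz"), **cfg),
        )
        assert h1.train_loss == h2.train_loss
        for pa, pb in zip(straight.parameters(), resumed.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestFinetune:
    def _baseline(self, tmp_path):
        model = toy_model(seed=2)
        hist = train(
            model, pairs_for(6, n=2),
            TrainConfig(epochs=2, batch_size=2, learning_rate=1e-3, seed=2),
        )
        path = tmp_path / "base.npz"
        save_checkpoint(path, model, None, 2, None, hist)
        return model, path

    def test_schedule_defaults(self):
        sched = FinetuneSchedule()
        assert [
            sched.epochs_for(c)
            for c in ("all_alpha", "all_beta", "alpha_plus_beta", "alpha_slash_beta")
        ] == [100, 200, 400, 500]
        with pytest.raises(ConfigError):
            sched.epochs_for("unknown")

    def test_zero_epochs_is_identity(self, tmp_path):
        base, path = self._baseline(tmp_path)
        tuned, _ = finetune(path, pairs_for(6, n=2), "all_alpha", epochs=0)
        for pa, pb in zip(base.parameters(), tuned.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_architecture_preserved(self, tmp_path):
        base, path = self._baseline(tmp_path)
        tuned, hist = finetune(
            path, pairs_for(7, n=2), "all_alpha", epochs=1, batch_size=2
        )
        assert hist.epochs_run == 1
        assert [p.data.shape for p in tuned.parameters()] == [
            p.data.shape for p in base.parameters()
        ]

    def test_incompatible_architecture_rejected(self, tmp_path):
        _, path = self._baseline(tmp_path)
        state = load_checkpoint(path)
        other = build_model(
            NetConfig(grid_side=16, in_channels=18, base_width=8, n_stages=2,
                      attention_heads=2, seed=0)
        )
        with pytest.raises(ConfigError):
            other.load_state_arrays(state["model"].state_arrays())
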