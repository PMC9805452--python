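import numpy as np
import pytest

import wsimil.training as training
from wsimil.model import MILModel
from wsimil.nn import Adam
from wsimil.tiling import SlideRecord
from wsimil.training import (
    Checkpoint,
    PatchStore,
    TrainConfig,
    build_epoch_roster,
    fit,
    training_step,
)

from conftest import noisy_tissue_patch


def _records(n_wt, n_mut):
    recs = [
        SlideRecord(f"wt{i}", f"pw{i}", 0, None, 20.0) for i in range(n_wt)
    ] + [SlideRecord(f"mu{i}", f"pm{i}", 1, None, 20.0) for i in range(n_mut)]
    return recs


def _store(records, scale, n_patches, rng):
    pre = {
        (r.slide_id, scale): np.stack(
            [noisy_tissue_patch(rng) for _ in range(n_patches)]
        )
        for r in records
    }
    return PatchStore(records, preloaded=pre)


class TestEpochRoster:
    def test_paper_counts(self):
        # 541 wildtype + 140 mutant: roster takes a fresh 140-slide wildtype
        # sample and every mutant slide, 280 total
        recs = _records(541, 140)
        roster = build_epoch_roster(recs, TrainConfig(), np.random.default_rng(0))
        assert len(roster) == 280
        labels = [r.label for r in roster]
        assert sum(labels) == 140
        mut_ids = {r.slide_id for r in roster if r.label == 1}
        assert mut_ids == {f"mu{i}" for i in range(140)}

    def test_auto_shrink_to_smallest_class(self):
        recs = _records(10, 10)
        roster = build_epoch_roster(recs, TrainConfig(), np.random.default_rng(0))
        assert len(roster) == 20
        assert {r.slide_id for r in roster} == {r.slide_id for r in recs}

    def test_majority_resampled_across_epochs(self):
        recs = _records(60, 10)
        rng = np.random.default_rng(0)
        cfg = TrainConfig(n_per_class=10)
        picks = [
            frozenset(r.slide_id for r in build_epoch_roster(recs, cfg, rng) if r.label == 0)
            for _ in range(5)
        ]
        assert len(set(picks)) > 1

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="class 1"):
            build_epoch_roster(_records(5, 0), TrainConfig(), np.random.default_rng(0))

    def test_every_epoch_is_balanced(self):
        recs = _records(23, 9)
        rng = np.random.default_rng(4)
        for _ in range(5):
            roster = build_epoch_roster(recs, TrainConfig(), rng)
            labels = np.array([r.label for r in roster])
            assert labels.sum() == (1 - labels).sum() == 9


class TestTrainingStep:
    def test_uses_all_patches_when_below_cap(self, rng):
        model = MILModel(d=8, seed=0)
        opt = Adam(model.trainable_params(), lr=1e-3)
        pixels = np.stack([noisy_tissue_patch(rng) for _ in range(5)])
        cfg = TrainConfig(patches_per_step=200)
        loss, info = training_step(model, opt, pixels, 1, cfg, rng)
        assert info["batch_size"] == 5
        assert np.isfinite(loss)

    def test_caps_patch_count(self, rng):
        model = MILModel(d=8, seed=0)
        opt = Adam(model.trainable_params(), lr=1e-3)
        pixels = np.stack([noisy_tissue_patch(rng) for _ in range(7)])
        cfg = TrainConfig(patches_per_step=4)
        _, info = training_step(model, opt, pixels, 0, cfg, rng)
        assert info["batch_size"] == 4

    def test_one_color_draw_per_slide_batch(self, rng):
        # the instrumented step exposes exactly one slide-level color draw
        # and one geometric draw per patch
        model = MILModel(d=8, seed=0)
        opt = Adam(model.trainable_params(), lr=1e-3)
        pixels = np.stack([noisy_tissue_patch(rng) for _ in range(6)])
        _, info = training_step(model, opt, pixels, 1, TrainConfig(), rng)
        from wsimil.augment import ColorAugParams

        assert isinstance(info["color_params"], ColorAugParams)
        assert len(info["geom_params"]) == info["batch_size"]

    def test_empty_bag_rejected(self, rng):
        model = MILModel(d=8, seed=0)
        opt = Adam(model.trainable_params(), lr=1e-3)
        with pytest.raises(ValueError):
            training_step(
                model, opt, np.empty((0, 256, 256, 3), np.uint8), 1, TrainConfig(), rng
            )

    def test_loss_decreases_when_overfitting_one_slide(self, rng):
        model = MILModel(d=8, seed=0)
        cfg = TrainConfig(learning_rate=1e-2, enable_color_aug=False, enable_geom_aug=False)
        opt = Adam(model.trainable_params(), lr=cfg.learning_rate)
        pixels = np.stack([noisy_tissue_patch(rng) for _ in range(2)])
        losses = [
            training_step(model, opt, pixels, 1, cfg, rng)[0] for _ in range(25)
        ]
        assert losses[-1] < losses[0]


def _tiny_sets(rng, n_train=4, n_val=2):
    recs = _records(n_train // 2 + n_val // 2, n_train // 2 + n_val // 2)
    train = recs[: n_train // 2] + recs[len(recs) // 2 : len(recs) // 2 + n_train // 2]
    val = [r for r in recs if r not in train][: n_val]
    store = _store(recs, 10.0, 2, rng)
    return train, val, store


class TestFit:
    def test_checkpoint_rule_takes_argmin_val_loss(self, rng, monkeypatch):
        losses = iter([0.7, 0.5, 0.6])
        monkeypatch.setattr(training, "validate", lambda *a, **k: next(losses))
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(scale=10.0, max_epochs=3, embed_dim=8, learning_rate=1e-3)
        ck = fit(train, val, cfg, store)
        assert ck.epoch == 2
        assert ck.val_loss == 0.5

    def test_tie_keeps_earliest_epoch(self, rng, monkeypatch):
        losses = iter([0.6, 0.6, 0.6])
        monkeypatch.setattr(training, "validate", lambda *a, **k: next(losses))
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(scale=10.0, max_epochs=3, embed_dim=8, learning_rate=1e-3)
        assert fit(train, val, cfg, store).epoch == 1

    def test_last_epoch_rule_keeps_final_model(self, rng, monkeypatch):
        losses = iter([0.5, 0.7, 0.9])
        monkeypatch.setattr(training, "validate", lambda *a, **k: next(losses))
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(
            scale=10.0, max_epochs=3, embed_dim=8, learning_rate=1e-3,
            checkpoint_rule="last",
        )
        ck = fit(train, val, cfg, store)
        assert ck.epoch == 3 and ck.val_loss == 0.9

    def test_single_epoch_returns_epoch_one(self, rng):
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(scale=10.0, max_epochs=1, embed_dim=8, learning_rate=1e-3)
        assert fit(train, val, cfg, store).epoch == 1

    def test_nan_validation_aborts(self, rng, monkeypatch):
        monkeypatch.setattr(training, "validate", lambda *a, **k: float("nan"))
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(scale=10.0, max_epochs=2, embed_dim=8, learning_rate=1e-3)
        with pytest.raises(FloatingPointError):
            fit(train, val, cfg, store)

    def test_seeded_training_is_bitwise_reproducible(self, rng):
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(scale=10.0, seed=5, max_epochs=2, embed_dim=8, learning_rate=1e-3)
        ck1 = fit(train, val, cfg, store)
        ck2 = fit(train, val, cfg, store)
        assert ck1.epoch == ck2.epoch and ck1.val_loss == ck2.val_loss
        for k in ck1.state:
            assert np.array_equal(ck1.state[k], ck2.state[k]), k

    def test_checkpoint_serialization_roundtrip(self, rng, tmp_path):
        train, val, store = _tiny_sets(rng)
        cfg = TrainConfig(scale=10.0, max_epochs=1, embed_dim=8, learning_rate=1e-3)
        ck = fit(train, val, cfg, store)
        ck.save(tmp_path / "ck")
        restored = MILModel.load(tmp_path / "ck")
        assert restored.meta["scale"] == 10.0
        stack = np.stack([noisy_tissue_patch(rng)])
        assert restored.predict_slide(
            restored.encode_patches(stack)
        ) == ck.to_model().predict_slide(ck.to_model().encode_patches(stack))
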