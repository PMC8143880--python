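"""Training loops: learning-rate schedule, augmentation, baseline/semi
equivalence at lambda = 0, loss decrease, isolation and checkpointing."""

import numpy as np
import pytest

from lccnet.architecture import BackboneConfig, build_backbone, build_lccnet
from lccnet.checkpoint import load_checkpoint, save_checkpoint
from lccnet.data_io import DataSplit
from lccnet.metrics import evaluate_model
from lccnet.training import (
    TrainConfig,
    apply_geometric,
    augment_sample,
    lr_at_epoch,
    train_semisupervised,
    train_supervised_baseline,
)


class TestLearningRate:
    def test_reference_values(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 0) == 5e-4
        assert lr_at_epoch(cfg, 1000) == pytest.approx(1.25e-4)
        assert lr_at_epoch(cfg, 2500) == pytest.approx(1.5625e-5)

    def test_piecewise_constant_with_exact_drop_count(self):
        cfg = TrainConfig()
        lrs = [lr_at_epoch(cfg, e) for e in range(3000)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))
        drops = sum(1 for a, b in zip(lrs, lrs[1:]) if b < a)
        assert drops == len(cfg.lr_decay_epochs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_decay_epochs=(100, 100))
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), -1)


class TestAugmentation:
    def test_zero_ranges_are_identity(self, rng):
        cfg = TrainConfig(aug_rotate_deg=0.0, aug_scale_range=(1.0, 1.0),
                          aug_shear_deg=0.0, aug_intensity=0.0)
        img = rng.random((16, 16), dtype=np.float32)
        mask = rng.integers(0, 4, (16, 16)).astype(np.int16)
        out_img, out_mask = augment_sample(img, mask, np.random.default_rng(0), cfg)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_full_turn_rotation_is_identity_up_to_interpolation(self, rng):
        img = rng.random((16, 16)).astype(np.float32)
        out, _ = apply_geometric(img, None, angle_deg=360.0, scale=1.0, shear_deg=0.0)
        assert np.allclose(out, img, atol=1e-4)

    def test_mask_values_preserved_by_nearest_neighbor(self, rng):
        cfg = TrainConfig()
        img = rng.random((16, 16), dtype=np.float32)
        mask = rng.integers(0, 4, (16, 16)).astype(np.int16)
        for seed in range(10):
            _, out_mask = augment_sample(img, mask, np.random.default_rng(seed), cfg)
            assert set(np.unique(out_mask)) <= set(np.unique(mask))

    def test_intensity_clipped_to_unit_range(self, rng):
        cfg = TrainConfig(aug_intensity=0.5)
        img = rng.random((8, 8), dtype=np.float32)
        out, _ = augment_sample(img, None, np.random.default_rng(1), cfg)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestTrainers:
    def test_lambda_zero_matches_supervised_only_trajectory(self, micro_cfg, micro_split):
        """With the consistency weight forced to zero and a shared seed, the
        supervised path of the assembly must follow the exact weight
        trajectory of a supervised-only run."""
        cfg = TrainConfig(max_epochs=3, lambda_max=0.0, cutmix_labeled=True, seed=11)
        asm = build_lccnet(micro_cfg, seed=11)
        asm, _ = train_semisupervised(micro_split, asm, cfg)
        net = build_backbone(micro_cfg, seed=11)
        net, _ = train_supervised_baseline(micro_split, net, cfg)
        semi_state = asm.segmentation_network().state_dict()
        base_state = net.state_dict()
        for key in base_state:
            assert np.array_equal(semi_state[key], base_state[key]), key

    def test_supervised_loss_decreases_on_phantom(self, micro_cfg, micro_split):
        cfg = TrainConfig(max_epochs=25, cutmix_labeled=False, seed=0)
        net = build_backbone(micro_cfg, seed=0)
        net, log = train_supervised_baseline(micro_split, net, cfg)
        assert log[-1]["loss_sup"] < log[0]["loss_sup"]

    def test_semisupervised_deterministic_given_seed(self, micro_cfg, micro_split):
        cfg = TrainConfig(max_epochs=2, seed=5)
        logs = []
        for _ in range(2):
            asm = build_lccnet(micro_cfg, seed=5)
            _, log = train_semisupervised(micro_split, asm, cfg)
            logs.append(log)
        assert logs[0] == logs[1]

    def test_baseline_never_touches_unlabeled_pool(self, micro_cfg, micro_split):
        class CountingList(list):
            reads = 0

            def __getitem__(self, i):
                CountingList.reads += 1
                return super().__getitem__(i)

            def __iter__(self):
                CountingList.reads += 1
                return super().__iter__()

        guarded = DataSplit(
            labeled=micro_split.labeled,
            unlabeled=CountingList(micro_split.unlabeled),
            test=micro_split.test,
        )
        CountingList.reads = 0
        net = build_backbone(micro_cfg, seed=0)
        train_supervised_baseline(guarded, net, TrainConfig(max_epochs=2, seed=0))
        assert CountingList.reads == 0

    def test_empty_labeled_pool_rejected(self, micro_cfg, micro_split):
        empty = DataSplit(labeled=[], unlabeled=micro_split.unlabeled, test=[])
        with pytest.raises(ValueError):
            train_supervised_baseline(empty, build_backbone(micro_cfg, seed=0),
                                      TrainConfig())
        with pytest.raises(ValueError):
            train_semisupervised(empty, build_lccnet(micro_cfg, seed=0), TrainConfig())

    def test_epoch_log_satisfies_total_identity(self, micro_cfg, micro_split):
        cfg = TrainConfig(max_epochs=2, seed=1)
        asm = build_lccnet(micro_cfg, seed=1)
        _, log = train_semisupervised(micro_split, asm, cfg)
        for entry in log:
            assert entry["loss"] == pytest.approx(
                entry["loss_sup"] + entry["lambda"] * entry["loss_unsup"]
            )
            assert entry["loss_sup"] >= 0 and entry["loss_unsup"] >= 0


class TestCheckpointing:
    def test_round_trip_reproduces_evaluation(self, tmp_path, micro_cfg, micro_split):
        cfg = TrainConfig(max_epochs=2, seed=3)
        asm = build_lccnet(micro_cfg, seed=3)
        asm, _ = train_semisupervised(micro_split, asm, cfg)
        ref = evaluate_model(asm.segmentation_network(), micro_split.test)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, asm, train_cfg_dict=cfg.to_dict(), epoch=2, seed=3)
        restored, meta = load_checkpoint(path)
        assert meta["kind"] == "lccnet"
        assert meta["epoch"] == 2
        again = evaluate_model(restored.segmentation_network(), micro_split.test)
        assert ref.rows == again.rows

    def test_unet_checkpoint_round_trip(self, tmp_path, micro_cfg, rng):
        net = build_backbone(micro_cfg, seed=0)
        x = rng.random((1, 1, 16, 16), dtype=np.float32)
        ref = net.forward(x)
        save_checkpoint(tmp_path / "c.npz", net)
        restored, meta = load_checkpoint(tmp_path / "c.npz")
        assert meta["kind"] == "unet"
        assert np.array_equal(restored.forward(x), ref)
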