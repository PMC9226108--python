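import numpy as np
import pytest

import sonotkv as sk
from sonotkv.model import _hard_dice


def tiny_dataset(n=6, size=32, seed=0, pid="a"):
    """Synthetic slab set with a clear intensity cue (dark rectangle)."""
    rng = np.random.default_rng(seed)
    imgs = rng.uniform(80, 160, size=(n, 3, size, size)).astype(np.float32)
    masks = np.zeros((n, size, size), dtype=np.uint8)
    for i in range(n):
        r0, c0 = rng.integers(4, size // 2, 2)
        h, w = rng.integers(8, size // 2, 2)
        masks[i, r0:r0 + h, c0:c0 + w] = 1
        imgs[i, :, r0:r0 + h, c0:c0 + w] = rng.uniform(10, 35)
    return sk.SlabDataset(images=imgs, masks=masks, patient_ids=[pid] * n)


def tiny_cfg(**kw):
    kw.setdefault("levels", 3)
    kw.setdefault("base_filters", 4)
    kw.setdefault("max_filters", 16)
    kw.setdefault("slab_size", 32)
    kw.setdefault("learning_rate", 3e-3)
    kw.setdefault("epochs", 3)
    return sk.UNetConfig(**kw)


class TestArchitecture:
    def test_full_scale_encoder_filters_and_parameter_count(self):
        model, summary = sk.build_unet(sk.UNetConfig())
        assert summary["encoder_filters"] == [32, 64, 128, 256, 512, 1024]
        assert summary["kernel_schedule_encoder"] == [7, 7, 5, 5, 3, 3]
        assert summary["kernel_schedule_decoder"] == [3, 5, 5, 7, 7]
        assert 14_000_000 <= summary["parameter_count"] <= 22_000_000
        assert summary["final_activation"] == "sigmoid"

    def test_output_in_unit_interval(self):
        model, _ = sk.build_unet(tiny_cfg())
        x = np.random.default_rng(0).uniform(0, 1, size=(2, 3, 32, 32))
        prob = model.forward(x.astype(np.float32))
        assert prob.shape == (2, 1, 32, 32)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_indivisible_slab_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            sk.build_unet(sk.UNetConfig(levels=4, slab_size=100,
                                        base_filters=4, max_filters=8))

    def test_filters_capped_at_max(self):
        cfg = sk.UNetConfig(levels=6, base_filters=32, max_filters=256,
                            slab_size=64)
        assert cfg.filters() == [32, 64, 128, 256, 256, 256]


class TestDiceLoss:
    def test_perfect_agreement_near_zero(self):
        t = np.zeros((8, 8)); t[2:5, 2:5] = 1
        assert sk.dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_near_one(self):
        a = np.zeros((8, 8)); a[:2] = 1
        b = np.zeros((8, 8)); b[6:] = 1
        assert sk.dice_loss(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_is_half(self):
        # 4-px prediction overlapping a 4-px target in exactly 2 px
        a = np.zeros(8); a[:4] = 1
        b = np.zeros(8); b[2:6] = 1
        assert sk.dice_loss(a, b) == pytest.approx(0.5, abs=1e-6)

    def test_symmetric_for_binary_masks(self):
        rng = np.random.default_rng(5)
        a = (rng.random((10, 10)) < 0.4).astype(float)
        b = (rng.random((10, 10)) < 0.4).astype(float)
        assert sk.dice_loss(a, b) == pytest.approx(sk.dice_loss(b, a), abs=1e-12)

    def test_consistent_with_metrics_dsc(self):
        rng = np.random.default_rng(6)
        a = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        b = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        tp, fp, fn, tn = sk.confusion_counts(a, b)
        dsc = sk.overlap_metrics(tp, fp, fn, tn)[0]
        assert 1.0 - sk.dice_loss(a, b) == pytest.approx(dsc, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sk.dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestTraining:
    def test_single_slab_overfit_reaches_high_dice(self):
        """200 epochs on one slab at the desk learning rate overfits."""
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, size=(1, 3, 64, 64)).astype(np.float32)
        msk = np.zeros((1, 64, 64), np.uint8)
        msk[0, 20:40, 20:44] = 1
        img[0, :, 20:40, 20:44] = 30
        ds = sk.SlabDataset(images=img, masks=msk, patient_ids=["a"])
        cfg = sk.desk_unet_config(epochs=200, seed=1)
        model, _ = sk.build_unet(cfg)
        model, hist = sk.train(model, ds, None, cfg)
        assert hist[-1]["train_dice"] >= 0.95
        assert len(hist) == 200

    def test_empty_training_set_rejected(self):
        cfg = tiny_cfg()
        model, _ = sk.build_unet(cfg)
        empty = sk.SlabDataset(images=np.zeros((0, 3, 32, 32)),
                               masks=np.zeros((0, 32, 32)))
        with pytest.raises(ValueError, match="empty"):
            sk.train(model, empty, None, cfg)

    def test_patient_overlap_between_partitions_rejected(self):
        cfg = tiny_cfg()
        model, _ = sk.build_unet(cfg)
        tr = tiny_dataset(pid="p1")
        va = tiny_dataset(pid="p1", seed=2)
        with pytest.raises(ValueError, match="overlap"):
            sk.train(model, tr, va, cfg)

    def test_training_deterministic_under_seed(self):
        ds = tiny_dataset()
        outs = []
        for _ in range(2):
            cfg = tiny_cfg(epochs=2, seed=3)
            model, _ = sk.build_unet(cfg)
            model, hist = sk.train(model, ds, None, cfg)
            outs.append((hist[-1]["train_dice"],
                         [a.copy() for a in model.state_arrays()]))
        assert outs[0][0] == outs[1][0]
        for a, b in zip(outs[0][1], outs[1][1]):
            assert np.array_equal(a, b)

    def test_pretrained_weights_do_not_start_worse(self, tmp_path):
        """A checkpoint from previous training initialises no worse than
        random weights on the same validation slabs."""
        ds = tiny_dataset(n=8, seed=1)
        val = tiny_dataset(n=4, seed=9, pid="b")
        cfg = tiny_cfg(epochs=60, seed=0)
        model, _ = sk.build_unet(cfg)
        model, hist = sk.train(model, ds, val, cfg)
        assert hist[-1]["val_dice"] > 0.6  # the source model actually learned
        wpath = str(tmp_path / "ckpt.npz")
        model.save_weights(wpath)

        fresh, _ = sk.build_unet(tiny_cfg(seed=123))
        warm, _ = sk.build_unet(tiny_cfg(seed=123, pretrained_weights_path=wpath))
        d_fresh = _hard_dice(fresh, val, 8, 0.5)
        d_warm = _hard_dice(warm, val, 8, 0.5)
        assert d_warm >= d_fresh

    def test_history_csv_roundtrip(self, tmp_path):
        ds = tiny_dataset()
        cfg = tiny_cfg(epochs=2)
        model, _ = sk.build_unet(cfg)
        _, hist = sk.train(model, ds, ds_val := None, cfg)
        path = tmp_path / "curves.csv"
        sk.model.save_history_csv(hist, str(path))
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["epoch", "train_dice", "val_dice", "loss"]
        assert len(df) == 2


class TestPredictStack:
    def make_standardized_stack(self, size=64, z=6):
        vox = np.full((size, size, z), 120, dtype=np.uint8)
        vox[:, :, 0] = 0  # blank frame: removed by the filter
        return sk.UltrasoundStack(voxels=vox, spacing=(1, 1, 1))

    def cfgs(self):
        pre = sk.PreprocessConfig(target_inplane=64, slab_size=32)
        mdl = tiny_cfg()
        return pre, mdl

    def test_constant_negative_model_gives_empty_mask(self):
        pre, mcfg = self.cfgs()
        model, _ = sk.build_unet(mcfg)
        model.final.w.value[...] = 0.0
        model.final.b.value[...] = -50.0  # sigmoid -> ~0 everywhere
        stack = self.make_standardized_stack()
        prob, mask = sk.predict_stack(model, stack, pre)
        assert mask.foreground_count() == 0
        assert sk.mask_volume(mask) == 0.0

    def test_zero_threshold_marks_all_kept_frames(self):
        pre, _ = self.cfgs()
        mcfg = tiny_cfg(binarize_threshold=0.0)
        model, _ = sk.build_unet(mcfg)
        stack = self.make_standardized_stack()
        prob, mask = sk.predict_stack(model, stack, pre)
        kept = sk.filter_blank_frames(stack, pre)
        assert (mask.voxels[:, :, kept] == 1).all()
        assert mask.voxels[:, :, 0].sum() == 0  # blank frame stays empty

    def test_prediction_deterministic(self):
        pre, mcfg = self.cfgs()
        model, _ = sk.build_unet(mcfg)
        stack = self.make_standardized_stack()
        p1, m1 = sk.predict_stack(model, stack, pre)
        p2, m2 = sk.predict_stack(model, stack, pre)
        assert np.array_equal(p1, p2)
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_geometry_mismatch_rejected(self):
        pre = sk.PreprocessConfig(target_inplane=64, slab_size=64)
        model, _ = sk.build_unet(tiny_cfg())  # slab 32
        with pytest.raises(ValueError, match="geometry"):
            sk.predict_stack(model, self.make_standardized_stack(), pre)

    def test_unstandardized_stack_rejected(self):
        pre, mcfg = self.cfgs()
        model, _ = sk.build_unet(mcfg)
        stack = sk.UltrasoundStack(voxels=np.zeros((50, 50, 4), np.uint8),
                                   spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="standardized"):
            sk.predict_stack(model, stack, pre)


def test_weight_roundtrip_preserves_predictions(tmp_path):
    cfg = tiny_cfg(seed=8)
    model, _ = sk.build_unet(cfg)
    x = np.random.default_rng(2).uniform(0, 1, size=(1, 3, 32, 32)).astype(np.float32)
    before = model.forward(x)
    path = str(tmp_path / "w.npz")
    model.save_weights(path)
    model2, _ = sk.build_unet(tiny_cfg(seed=99, pretrained_weights_path=path))
    assert np.allclose(model2.forward(x), before)
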