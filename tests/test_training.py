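import math

import numpy as np
import pytest

from cinefcn.image_io import LabelScheme, SHORT_AXIS_SCHEME
from cinefcn.network import NetworkSpec, build_fcn
from cinefcn.training import (
    TrainConfig,
    apply_affine_pair,
    augment_batch,
    cross_entropy_loss,
    fine_tune,
    make_training_slices,
    train,
)

LV_ONLY = LabelScheme("short_axis", ("background", "lv_cavity", "lv_myocardium"))


def one_hot(labels, k):
    return np.eye(k, dtype=np.float64)[labels]


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        truth = np.random.randint(0, 4, (6, 6))
        loss = cross_entropy_loss(one_hot(truth, 4), truth)
        assert loss.value == pytest.approx(0.0, abs=1e-9)
        assert loss.n_pixels == 36

    def test_uniform_prediction_is_log_k(self):
        truth = np.random.randint(0, 4, (5, 5))
        pred = np.full((5, 5, 4), 0.25)
        loss = cross_entropy_loss(pred, truth)
        assert loss.value == pytest.approx(math.log(4), abs=1e-12)

    def test_ignore_equals_pixel_deletion_oracle(self, rng):
        truth = rng.integers(0, 4, (10, 10))
        pred = rng.random((10, 10, 4))
        pred /= pred.sum(axis=-1, keepdims=True)
        rv = SHORT_AXIS_SCHEME.index("rv_cavity")
        masked = cross_entropy_loss(pred, truth, ignore={"rv_cavity"}, scheme=SHORT_AXIS_SCHEME)
        keep = truth != rv
        oracle = -np.log(
            np.take_along_axis(pred, truth[..., None], axis=-1)[..., 0][keep]
        ).mean()
        assert masked.value == pytest.approx(oracle)
        assert masked.n_pixels == int(keep.sum())

    def test_pixel_permutation_invariance(self, rng):
        truth = rng.integers(0, 3, (8, 8))
        pred = rng.random((8, 8, 3))
        pred /= pred.sum(axis=-1, keepdims=True)
        base = cross_entropy_loss(pred, truth).value
        perm = rng.permutation(64)
        shuffled = cross_entropy_loss(
            pred.reshape(64, 3)[perm].reshape(8, 8, 3),
            truth.reshape(64)[perm].reshape(8, 8),
        ).value
        assert shuffled == pytest.approx(base)

    def test_duplicating_batch_leaves_mean_unchanged(self, rng):
        truth = rng.integers(0, 3, (2, 6, 6))
        pred = rng.random((2, 6, 6, 3))
        pred /= pred.sum(axis=-1, keepdims=True)
        base = cross_entropy_loss(pred, truth).value
        doubled = cross_entropy_loss(
            np.concatenate([pred, pred]), np.concatenate([truth, truth])
        ).value
        assert doubled == pytest.approx(base)

    def test_empty_contributing_set_rejected(self):
        truth = np.zeros((4, 4), dtype=int)
        pred = np.full((4, 4, 2), 0.5)
        with pytest.raises(ValueError):
            cross_entropy_loss(pred, truth, ignore={0})

    def test_probability_floor_bounds_loss(self):
        truth = np.zeros((2, 2), dtype=int)
        pred = np.zeros((2, 2, 2))
        pred[..., 1] = 1.0  # zero probability on the true class
        loss = cross_entropy_loss(pred, truth)
        assert loss.value == pytest.approx(-math.log(1e-12))


class TestAugmentation:
    def test_zero_ranges_are_identity(self, rng):
        cfg = TrainConfig(
            translation_px=0, rotation_deg=0, scale_range=(1.0, 1.0),
            intensity_scale=(1.0, 1.0), intensity_offset=0.0,
        )
        imgs = rng.random((3, 16, 16), dtype=np.float32)
        labs = rng.integers(0, 4, (3, 16, 16))
        out_i, out_l = augment_batch(imgs, labs, cfg, rng)
        np.testing.assert_allclose(out_i, imgs, atol=1e-6)
        np.testing.assert_array_equal(out_l, labs)

    def test_exact_90_degree_rotation_permutes_grid(self):
        lab = np.zeros((16, 16), dtype=np.uint8)
        lab[4:8, 6:12] = 2
        img = lab.astype(np.float32) / 2.0
        img_r, lab_r = apply_affine_pair(img, lab, rotation_deg=90.0)
        assert lab_r.sum() == lab.sum()  # pixel count preserved
        np.testing.assert_array_equal(lab_r, np.rot90(lab, k=-1))

    def test_labels_stay_in_scheme_alphabet(self, rng):
        cfg = TrainConfig()
        imgs = rng.random((4, 32, 32), dtype=np.float32)
        labs = rng.integers(0, 4, (4, 32, 32))
        _, out_l = augment_batch(imgs, labs, cfg, rng)
        assert set(np.unique(out_l)) <= {0, 1, 2, 3}

    def test_image_range_reclipped(self, rng):
        cfg = TrainConfig(intensity_scale=(1.5, 1.5), intensity_offset=0.3)
        imgs = rng.random((2, 16, 16), dtype=np.float32)
        labs = np.zeros((2, 16, 16), dtype=np.uint8)
        out_i, _ = augment_batch(imgs, labs, cfg, rng)
        assert out_i.min() >= 0.0
        assert out_i.max() <= 1.0


class TestTrain:
    def test_default_batch_contains_20_slices(self, training_cases, monkeypatch):
        cfg = TrainConfig(iterations=1, learning_rate=0.0)
        slices = make_training_slices(training_cases, size=64)
        net = build_fcn(4, spec=NetworkSpec.reduced(4), seed=0)
        seen = []
        orig_forward = net.forward

        def spy(batch, training=False):
            seen.append(batch.shape[0])
            return orig_forward(batch, training=training)

        monkeypatch.setattr(net, "forward", spy)
        train(net, slices, cfg)
        assert seen == [20]

    def test_zero_lr_leaves_parameters_unchanged(self, training_cases):
        slices = make_training_slices(training_cases, size=64)
        net = build_fcn(4, spec=NetworkSpec.reduced(4), seed=0)
        before = [p.copy() for p, _ in net.params()]
        cfg = TrainConfig(iterations=3, learning_rate=0.0, batch_size=4)
        train(net, slices, cfg)
        for b, (p, _) in zip(before, net.params()):
            np.testing.assert_array_equal(b, p)

    def test_empty_pool_rejected(self):
        net = build_fcn(4, spec=NetworkSpec.reduced(4))
        with pytest.raises(ValueError):
            train(net, [], TrainConfig(iterations=1))

    def test_loss_history_length(self, training_cases):
        slices = make_training_slices(training_cases, size=64)
        net = build_fcn(4, spec=NetworkSpec.reduced(4), seed=0)
        _, history = train(net, slices, TrainConfig(iterations=5, batch_size=4))
        assert len(history) == 5

    def test_two_class_toy_reaches_99pct_accuracy(self):
        # bright disk on dark background; 1-scale reduced network; majority of 3 seeds
        yy, xx = np.mgrid[:32, :32]
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            slices = []
            for _ in range(6):
                cy, cx = rng.uniform(12, 20, 2)
                r = rng.uniform(5, 9)
                lab = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.uint8)
                img = np.where(lab, 0.9, 0.1).astype(np.float32)
                slices.append((img, lab))
            spec = NetworkSpec(2, widths=(8,), convs_per_scale=(2,), head_widths=(8,))
            net = build_fcn(2, spec=spec, seed=seed)
            cfg = TrainConfig(iterations=500, batch_size=6, seed=seed, augment=False)
            net, _ = train(net, slices, cfg)
            acc = np.mean([
                (net.forward(img[None], training=False)[0].argmax(-1) == lab).mean()
                for img, lab in slices
            ])
            wins += acc > 0.99
        assert wins >= 2


@pytest.fixture(scope="module")
def pretrained(training_cases):
    slices = make_training_slices(training_cases, size=64)
    net = build_fcn(4, spec=NetworkSpec.reduced(4), seed=0)
    cfg = TrainConfig(iterations=30, batch_size=6, seed=0, augment=False)
    train(net, slices, cfg)
    return net, slices


class TestFineTune:
    def test_reduced_scheme_rebuilds_3_feature_head(self, pretrained):
        net, slices = pretrained
        import copy

        tuned = fine_tune(
            copy.deepcopy(net), slices, LV_ONLY,
            TrainConfig(fine_tune_iterations=2, batch_size=4, augment=False),
            data_scheme=SHORT_AXIS_SCHEME,
        )
        assert tuned.spec.n_classes == 3
        out = tuned.forward(np.random.rand(1, 64, 64).astype(np.float32))
        assert out.shape[-1] == 3

    def test_zero_iterations_preserves_body(self, pretrained):
        net, slices = pretrained
        import copy

        src = copy.deepcopy(net)
        body_before = [p.copy() for layer in src.body_layers() for p, _ in layer.params()]
        tuned = fine_tune(
            src, slices, LV_ONLY,
            TrainConfig(fine_tune_iterations=0),
            data_scheme=SHORT_AXIS_SCHEME,
        )
        body_after = [p for layer in tuned.body_layers() for p, _ in layer.params()]
        assert len(body_before) == len(body_after)
        for b, a in zip(body_before, body_after):
            np.testing.assert_array_equal(b, a)

    def test_default_fine_tune_schedule_is_10000(self):
        assert TrainConfig().fine_tune_iterations == 10_000

    def test_default_schedule_constants(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.iterations == 50_000
        assert cfg.batch_size == 20
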