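import numpy as np
import pytest

from cerebseg.model import ModelConfig, build_reference_model
from cerebseg.multiview import n_classes_for_view
from cerebseg.phantom import PhantomSpec, generate_phantom
from cerebseg.training import (
    AdamW,
    AugmentOptions,
    PlateauScheduler,
    TrainConfig,
    composite_loss,
    composite_loss_grad,
    median_frequency_weights,
    plateau_step,
    pretrain_then_finetune,
    train_view,
)


class TestCompositeLoss:
    def test_uniform_prediction_cross_entropy_is_log_c(self, rng):
        c = 5
        probs = np.full((2, c, 6, 6), 1.0 / c, np.float32)
        t = rng.integers(0, c, (2, 6, 6))
        loss = composite_loss(probs, t, dice_weight=0.0)
        assert loss == pytest.approx(np.log(c), rel=1e-5)

    def test_one_hot_correct_prediction_vanishes(self, rng):
        c = 4
        t = rng.integers(0, c, (1, 4, 4))
        probs = np.zeros((1, c, 4, 4), np.float32)
        for k in range(c):
            probs[0, k][t[0] == k] = 1.0
        probs = np.clip(probs, 1e-7, 1 - 1e-7)
        probs /= probs.sum(axis=1, keepdims=True)
        loss = composite_loss(probs, t, smooth=1e-12)
        assert loss == pytest.approx(0.0, abs=1e-4)

    def test_two_pixel_two_class_hand_computed(self):
        # pixels: p(class1) = 0.8 (target 1), p(class1) = 0.3 (target 0)
        probs = np.array([[[[0.2, 0.7]], [[0.8, 0.3]]]], np.float32)  # (1,2,1,2)
        t = np.array([[[1, 0]]])
        w = np.array([1.0, 2.0], np.float32)
        # weighted CE: (2*(-ln .8) + 1*(-ln .7)) / 3
        want_ce = (2 * -np.log(0.8) + 1 * -np.log(0.7)) / 3
        # soft dice per class: c0: 2*.7/(0.9+1); c1: 2*.8/(1.1+1)
        want_dice = 1 - 0.5 * (1.4 / 1.9 + 1.6 / 2.1)
        got = composite_loss(probs, t, w, dice_weight=1.0, smooth=0.0)
        assert got == pytest.approx(want_ce + want_dice, rel=1e-5)

    def test_mismatched_weights_rejected(self, rng):
        probs = np.full((1, 3, 2, 2), 1 / 3, np.float32)
        with pytest.raises(ValueError):
            composite_loss(probs, np.zeros((1, 2, 2), int), np.ones(4))

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal((1, 3, 3, 4))  # channels-last (B,H,W,C)
        t = rng.integers(0, 4, (1, 3, 3))
        w = np.array([0.5, 1.0, 2.0, 1.0], np.float32)
        _, dl = composite_loss_grad(logits, t, w)
        for idx in [(0, 0, 0, 1), (0, 2, 1, 3), (0, 1, 2, 0)]:
            eps = 1e-3
            up = logits.copy()
            up[idx] += eps
            dn = logits.copy()
            dn[idx] -= eps
            num = (composite_loss_grad(up, t, w)[0] - composite_loss_grad(dn, t, w)[0]) / (2 * eps)
            assert dl[idx] == pytest.approx(num, rel=5e-3, abs=1e-5)


class TestClassWeights:
    def test_equal_frequencies_give_unit_weights(self):
        labels = np.repeat(np.arange(3), 10).reshape(3, 10, 1)
        w = median_frequency_weights([labels], 3)
        assert np.allclose(w, 1.0)

    def test_worked_example(self):
        lab = np.concatenate([np.zeros(100), np.ones(200), np.full(400, 2)])
        w = median_frequency_weights([lab.astype(int).reshape(7, 10, 10)], 3)
        assert np.allclose(w, [2.0, 1.0, 0.5])

    def test_invariant_to_total_count(self):
        lab = np.concatenate([np.zeros(10), np.ones(20), np.full(40, 2)]).astype(int)
        w1 = median_frequency_weights([lab.reshape(7, 10, 1)], 3)
        w2 = median_frequency_weights([np.tile(lab, 5).reshape(7, 50, 1)], 3)
        assert np.allclose(w1, w2)

    def test_absent_class_gets_zero_with_warning(self):
        lab = np.concatenate([np.zeros(10), np.ones(10)]).astype(int)
        with pytest.warns(UserWarning, match="absent"):
            w = median_frequency_weights([lab.reshape(4, 5, 1)], 4)
        assert w[2] == 0.0 and w[3] == 0.0

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            median_frequency_weights([np.zeros((4, 4, 4), int)], 3)


class TestPlateauSchedule:
    def test_improving_dice_keeps_lr(self):
        assert plateau_step([0.1, 0.2, 0.3, 0.4, 0.5], 0.01) == 0.01

    def test_flat_dice_reduces_by_factor(self):
        # best at epoch 1, then 4 bad epochs -> one reduction by 0.01
        assert plateau_step([0.5, 0.5, 0.5, 0.5, 0.5], 0.01) == pytest.approx(1e-4)

    def test_improvement_at_patience_boundary_prevents_reduction(self):
        assert plateau_step([0.5, 0.4, 0.4, 0.4, 0.6], 0.01) == 0.01

    def test_counter_resets_after_reduction(self):
        sched = PlateauScheduler(0.01, 0.1, 2)
        for d in (0.5, 0.5, 0.5):  # one reduction after two bad epochs
            lr = sched.step(d)
        assert lr == pytest.approx(1e-3)
        lr = sched.step(0.5)  # only one bad epoch since the reset
        assert lr == pytest.approx(1e-3)

    def test_lr_sequence_non_increasing(self, rng):
        sched = PlateauScheduler(0.01, 0.01, 4)
        lrs = [sched.step(d) for d in rng.random(30)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))


class TestAdamW:
    def test_decay_applies_only_to_conv_weights(self):
        w = np.ones(3, np.float32)
        b = np.ones(3, np.float32)
        params = [("m0.w", w, np.zeros(3, np.float32)),
                  ("m0.gamma", b, np.zeros(3, np.float32))]
        opt = AdamW(params, lr=0.1, weight_decay=0.5)
        opt.step()
        assert np.all(w < 1.0)
        assert np.allclose(b, 1.0)


def _toy_sets(protocol, n_train=3, n_val=1, grid=24):
    from cerebseg.core import robust_normalize

    train, val = [], []
    for i in range(n_train + n_val):
        vol, lab = generate_phantom(
            PhantomSpec(grid_shape=(grid,) * 3, seed=100 + i), protocol
        )
        pair = (robust_normalize(vol), lab)
        (train if i < n_train else val).append(pair)
    return train, val


def _tiny_cfg(protocol, view="axial"):
    return ModelConfig(
        n_classes=n_classes_for_view(protocol, view), view=view,
        levels=2, base_filters=4, competition_enabled=False, crop_side=24,
    )


class TestTrainView:
    def test_zero_epochs_returns_initial_model(self, protocol):
        train, val = _toy_sets(protocol)
        cfg = _tiny_cfg(protocol)
        model = build_reference_model(cfg, np.random.default_rng(0))
        before = {k: v.copy() for k, v in model._state_arrays().items()}
        out, hist = train_view(
            model, train, val, TrainConfig(epochs=0, batch_size=8), protocol
        )
        assert hist.epochs == []
        for k, v in out._state_arrays().items():
            assert np.array_equal(v, before[k])

    def test_seed_determinism_of_loss_curve(self, protocol):
        train, val = _toy_sets(protocol)
        tc = TrainConfig(epochs=2, batch_size=8, micro_batch=8, lr0=1e-3,
                         slices_per_epoch=24, seed=3,
                         augment=AugmentOptions(flip=True, affine=False, bias=False))
        curves = []
        for _ in range(2):
            model = build_reference_model(_tiny_cfg(protocol), np.random.default_rng(0))
            _, hist = train_view(model, train, val, tc, protocol)
            curves.append(hist.train_loss)
        assert curves[0] == curves[1]

    def test_loss_decreases_and_history_consistent(self, protocol):
        train, val = _toy_sets(protocol)
        tc = TrainConfig(epochs=3, batch_size=8, micro_batch=8, lr0=2e-3,
                         slices_per_epoch=48, seed=1,
                         augment=AugmentOptions.none())
        model = build_reference_model(_tiny_cfg(protocol), np.random.default_rng(0))
        _, hist = train_view(model, train, val, tc, protocol)
        assert len(hist.epochs) == 3
        assert hist.train_loss[-1] < hist.train_loss[0]
        # logged lr must replay from the plateau rule applied to the Dice curve
        assert all(b <= a for a, b in zip(hist.lr, hist.lr[1:]))

    def test_empty_sets_rejected(self, protocol):
        model = build_reference_model(_tiny_cfg(protocol), np.random.default_rng(0))
        with pytest.raises(ValueError):
            train_view(model, [], [], TrainConfig(epochs=1), protocol)


class TestPretrainFinetune:
    def test_zero_epoch_finetune_returns_pretrained_state(self, protocol):
        train, val = _toy_sets(protocol)
        cfg = _tiny_cfg(protocol)
        pre_tc = TrainConfig(epochs=1, batch_size=8, micro_batch=8, lr0=1e-3,
                             slices_per_epoch=16, seed=2,
                             augment=AugmentOptions.none())
        fine_tc = TrainConfig(epochs=0, batch_size=8, seed=2)
        model, prov = pretrain_then_finetune(
            cfg, (train, val), (train, val), pre_tc, fine_tc, protocol
        )
        assert prov["stages"] == ["pretrain", "finetune"]
        assert prov["finetune_epochs"] == 0
        # reference: pretraining alone with the same seeds
        ref = build_reference_model(cfg, np.random.default_rng([2, 3]))
        ref, _ = train_view(ref, train, val, pre_tc, protocol)
        for (ka, va), (kb, vb) in zip(
            model._state_arrays().items(), ref._state_arrays().items()
        ):
            assert np.array_equal(va, vb), ka
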