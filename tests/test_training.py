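"""Composite loss, augmentation, scheduler and the training loop."""

import numpy as np
import pytest

import finholo as fh
from finholo.training import (
    LossWeights,
    RandomConvFeatures,
    TrainConfig,
    cosine_annealing_lr,
    loss_and_grad,
)


def dft2x2(x):
    """Hand-expanded 2x2 DFT: F[k,l] = sum_mn x[m,n] (-1)^(km+ln)."""
    return np.array(
        [
            [x[0, 0] + x[0, 1] + x[1, 0] + x[1, 1], x[0, 0] - x[0, 1] + x[1, 0] - x[1, 1]],
            [x[0, 0] + x[0, 1] - x[1, 0] - x[1, 1], x[0, 0] - x[0, 1] - x[1, 0] + x[1, 1]],
        ]
    )


class TestComputeLoss:
    def test_zero_at_identity(self, rng):
        y = rng.normal(size=(2, 8, 8))
        total, mae, cplx, percep = fh.compute_loss(
            y, y.copy(), LossWeights(), RandomConvFeatures(seed=0)
        )
        assert total == mae == cplx == percep == 0.0

    def test_2x2_hand_dft_oracle(self):
        """Single bright pixel target vs zero prediction, gamma = 0."""
        y = np.zeros((2, 2, 2))
        y[0, 0, 0] = 1.0
        yhat = np.zeros_like(y)
        weights = LossWeights(alpha=0.5, beta=1.0, gamma=0.0)
        total, mae, cplx, _ = fh.compute_loss(y, yhat, weights)
        assert mae == pytest.approx(1.0 / 4.0)
        # DFT of [[1,0],[0,0]] is 1 at every frequency
        expected_cplx = np.abs(dft2x2(y[0])).sum() / 4.0
        assert cplx == pytest.approx(expected_cplx)
        assert cplx == pytest.approx(1.0)
        assert total == pytest.approx(0.5 * 0.25 + 1.0 * 1.0)

    def test_paper_weighting_arithmetic(self):
        w = LossWeights(alpha=0.5, beta=1.0, gamma=0.5)
        assert w.alpha * 1.0 + w.beta * 1.0 + w.gamma * 1.0 == pytest.approx(2.0)

    def test_loss_nonnegative_and_faithful(self, rng):
        y = rng.normal(size=(2, 8, 8))
        yhat = y + rng.normal(scale=0.1, size=y.shape)
        total, mae, cplx, percep = fh.compute_loss(
            y, yhat, LossWeights(), RandomConvFeatures(seed=0)
        )
        assert min(total, mae, cplx, percep) >= 0
        assert total > 0

    def test_rotation_invariance_without_perceptual_term(self, rng):
        y = rng.normal(size=(2, 8, 8))
        yhat = rng.normal(size=(2, 8, 8))
        w = LossWeights(gamma=0.0)
        a = fh.compute_loss(y, yhat, w)
        b = fh.compute_loss(
            np.rot90(y, axes=(-2, -1)).copy(), np.rot90(yhat, axes=(-2, -1)).copy(), w
        )
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fh.compute_loss(rng.normal(size=(2, 8, 8)), rng.normal(size=(2, 4, 4)))

    def test_gradient_matches_finite_differences(self, rng):
        y = rng.normal(size=(2, 6, 6))
        yhat = rng.normal(size=(2, 6, 6))
        ext = RandomConvFeatures(seed=1)
        terms, g = loss_and_grad(y, yhat, LossWeights(), ext)
        eps = 1e-6
        for idx in [(0, 2, 3), (1, 4, 1), (0, 0, 0)]:
            up = yhat.copy()
            up[idx] += eps
            down = yhat.copy()
            down[idx] -= eps
            hi, _ = loss_and_grad(y, up, LossWeights(), ext, want_grad=False)
            lo, _ = loss_and_grad(y, down, LossWeights(), ext, want_grad=False)
            numeric = (hi[0] - lo[0]) / (2 * eps)
            assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-8)


class TestAugment:
    def test_rotation_zero_possible_and_identity(self, rng):
        stack = rng.random((2, 8, 8))
        target = rng.random((2, 8, 8))
        # find a seed whose draw is rotation 0
        for seed in range(20):
            s, t = fh.augment(stack, target, seed)
            if np.array_equal(s, stack):
                assert np.array_equal(t, target)
                break
        else:
            pytest.fail("rotation 0 never drawn in 20 seeds")

    def test_four_quarter_turns_is_identity(self, rng):
        stack = rng.random((2, 8, 8))
        out = stack
        for _ in range(4):
            out = np.rot90(out, 1, axes=(-2, -1))
        assert np.array_equal(out, stack)

    def test_rotation_preserves_pixel_multiset(self, rng):
        stack = rng.random((3, 8, 8))
        target = rng.random((2, 8, 8))
        s, t = fh.augment(stack, target, seed=2)
        for a, b in ((s, stack), (t, target)):
            for p in range(a.shape[0]):
                assert sorted(a[p].ravel()) == sorted(b[p].ravel())

    def test_same_rotation_applied_to_stack_and_target(self):
        stack = np.zeros((1, 4, 4))
        stack[0, 0, 1] = 1.0
        target = stack.copy()
        for seed in range(10):
            s, t = fh.augment(stack, target, seed)
            assert np.array_equal(s, t)

    def test_non_square_rejected_for_quarter_turns(self, rng):
        stack = rng.random((1, 4, 6))
        target = rng.random((2, 4, 6))
        raised_or_identity = False
        for seed in range(30):
            try:
                s, _ = fh.augment(stack, target, seed)
                assert s.shape == stack.shape  # 0 or 180 degrees
            except ValueError:
                raised_or_identity = True
        assert raised_or_identity


class TestScheduler:
    def test_starts_at_maximum(self):
        assert cosine_annealing_lr(0, 1e-3, 1e-5, period=50) == pytest.approx(1e-3)

    def test_returns_to_maximum_at_first_restart(self):
        assert cosine_annealing_lr(50, 1e-3, 1e-5, period=50, mult=2) == pytest.approx(1e-3)

    def test_reaches_minimum_late_in_cycle(self):
        lr = cosine_annealing_lr(49, 1e-3, 1e-5, period=50, mult=2)
        assert lr < 1e-4

    def test_second_cycle_is_longer(self):
        # with mult=2 the second restart happens at epoch 50 + 100
        assert cosine_annealing_lr(150, 1e-3, 1e-5, period=50, mult=2) == pytest.approx(1e-3)
        assert cosine_annealing_lr(100, 1e-3, 1e-5, period=50, mult=2) < 1e-3


def tiny_dataset(n_pairs=3, size=16, m=2, seed=0):
    zs = [300.0, 450.0]
    ds = []
    for s in range(n_pairs):
        f = fh.generate_phantom(fh.PhantomParams(size=(size, size), seed=seed + s))
        st = fh.simulate_hologram_stack(f, zs, fh.SensorParams(), seed=s)
        ds.append((np.stack(st.images), np.stack([f.grid.real, f.grid.imag])))
    return ds


def tiny_config(size=16):
    return fh.FINConfig(m=2, channels=4, groups=2, k_schedule=(4, 2), input_size=(size, size))


class TestTrainModel:
    def test_overfit_smoke(self):
        """Loss on one pair drops below 10% of the first epoch's loss."""
        ds = tiny_dataset(1)
        net = fh.FIN(tiny_config(), seed=0)
        net, hist = fh.train_model(
            net, ds,
            TrainConfig(epochs=200, batch_size=1, lr=3e-3, validation_fraction=0.0,
                        augment=False, seed=0),
        )
        assert hist["train_loss"][-1] < 0.10 * hist["train_loss"][0]

    def test_checkpoint_is_validation_argmin(self):
        ds = tiny_dataset(4)
        net = fh.FIN(tiny_config(), seed=0)
        net, hist = fh.train_model(
            net, ds, TrainConfig(epochs=8, batch_size=2, validation_fraction=0.25, seed=0)
        )
        assert hist["best_epoch"] == int(np.argmin(hist["val_loss"]))

    def test_reproducible_given_seed(self):
        ds = tiny_dataset(2)
        results = []
        for _ in range(2):
            net = fh.FIN(tiny_config(), seed=1)
            net, _ = fh.train_model(
                net, ds, TrainConfig(epochs=3, batch_size=1, seed=5)
            )
            results.append(net.parameters())
        for key in results[0]:
            assert np.array_equal(results[0][key], results[1][key])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fh.train_model(fh.FIN(tiny_config(), seed=0), [], TrainConfig(epochs=1))


class TestTransferFinetune:
    def test_zero_epochs_returns_model_unchanged(self):
        net = fh.FIN(tiny_config(), seed=0)
        before = {k: v.copy() for k, v in net.parameters().items()}
        net, _ = fh.transfer_finetune(net, tiny_dataset(2), TrainConfig(epochs=0))
        after = net.parameters()
        for key in before:
            assert np.array_equal(before[key], after[key])

    def test_finetuning_on_new_kind_reduces_its_loss(self):
        """A tissue-trained toy model improves on sparse cells after transfer."""
        zs = [300.0, 450.0]
        def cells_ds(n, seed0):
            ds = []
            for s in range(n):
                f = fh.generate_phantom(
                    fh.PhantomParams(kind="sparse_cells", size=(16, 16), seed=seed0 + s)
                )
                st = fh.simulate_hologram_stack(f, zs, fh.SensorParams(), seed=s)
                ds.append((np.stack(st.images), np.stack([f.grid.real, f.grid.imag])))
            return ds

        net = fh.FIN(tiny_config(), seed=0)
        net, _ = fh.train_model(
            net, tiny_dataset(4),
            TrainConfig(epochs=30, batch_size=2, validation_fraction=0.0, seed=0),
        )
        target_ds = cells_ds(4, 100)
        ext = RandomConvFeatures(seed=0)

        def mean_loss(model):
            losses = []
            for x, y in cells_ds(3, 500):
                pred = model.forward(x)
                losses.append(fh.compute_loss(y, pred, LossWeights(), ext)[0])
            return np.mean(losses)

        before = mean_loss(net)
        net, _ = fh.transfer_finetune(
            net, target_ds,
            TrainConfig(epochs=40, batch_size=2, lr=2e-3, validation_fraction=0.0, seed=1),
        )
        after = mean_loss(net)
        assert after < before
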