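"""3D U-Net: architecture, loss, augmentation, stopping, training, inference."""

import numpy as np
import pytest

import gliotrack as gt
from gliotrack import nn
from gliotrack.errors import ParameterError, ValidationError
from gliotrack.model import (
    TrainConfig,
    UnetConfig,
    _dice_loss_grad,
    build_unet3d,
    predict_volume,
    train,
)


@pytest.fixture(scope="module")
def tiny_net():
    return build_unet3d(UnetConfig(in_channels=3, depth=3, base_filters=2), seed=0)


class TestArchitecture:
    def test_output_shape_and_range(self, tiny_net):
        x = np.random.default_rng(0).standard_normal((3, 16, 16, 16)).astype(np.float32)
        out = tiny_net.forward(x)
        assert out.shape == (16, 16, 16)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_default_training_volume_is_128(self):
        assert TrainConfig().crop_shape == (128, 128, 128)

    def test_indivisible_shape_rejected(self, tiny_net):
        x = np.zeros((3, 12, 16, 16), np.float32)  # 12 not divisible by 2^3
        with pytest.raises(ValidationError):
            tiny_net.forward(x)

    def test_zeroed_head_gives_half_probability(self):
        net = build_unet3d(UnetConfig(depth=2, base_filters=2), seed=1)
        net.head.W[...] = 0.0
        net.head.b[...] = 0.0
        out = net.forward(np.zeros((3, 8, 8, 8), np.float32))
        assert np.allclose(out, 0.5)

    def test_parameter_count_monotone_in_base_filters(self):
        counts = [
            build_unet3d(UnetConfig(base_filters=f, depth=2), seed=0).n_parameters
            for f in (2, 4, 8)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        for layer, shape in [
            (nn.Conv3d(2, 3, 3, rng=np.random.default_rng(1)), (2, 4, 4, 4)),
            (nn.Conv3d(3, 2, 1, rng=np.random.default_rng(2)), (3, 4, 4, 4)),
            (nn.MaxPool3d(), (2, 4, 4, 4)),
            (nn.Upsample3d(), (2, 2, 2, 2)),
        ]:
            x = rng.standard_normal(shape)
            assert nn.gradient_check(layer, x) < 1e-5


class TestSoftDiceLoss:
    def test_perfect_prediction(self):
        t = (np.random.default_rng(0).random((8, 8, 8)) > 0.5).astype(float)
        assert gt.soft_dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)

    def test_complete_miss(self):
        t = np.zeros((8, 8, 8))
        t[:4] = 1.0
        assert gt.soft_dice_loss(1.0 - t, t) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_half_probability_half_target(self):
        """p=0.5 everywhere, half-full target: loss = 1 - N/2 / (N/2+N/2) ... = 0.5."""
        t = np.zeros((8, 8, 8))
        t[:4] = 1.0
        p = np.full((8, 8, 8), 0.5)
        assert gt.soft_dice_loss(p, t) == pytest.approx(0.5, abs=1e-5)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        p = rng.random((4, 4, 4)) * 0.8 + 0.1
        t = (rng.random((4, 4, 4)) > 0.5).astype(float)
        g = _dice_loss_grad(p, t)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            p2 = p.copy()
            p2[idx] += eps
            num = (gt.soft_dice_loss(p2, t) - gt.soft_dice_loss(p, t)) / eps
            assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            gt.soft_dice_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestAugmentation:
    @pytest.fixture
    def sample(self):
        rng = np.random.default_rng(5)
        stack = rng.standard_normal((3, 8, 8, 8)).astype(np.float32)
        label = (rng.random((8, 8, 8)) > 0.7).astype(np.float32)
        return stack, label

    def test_p_zero_is_identity(self, sample):
        stack, label = sample
        s, l, info = gt.augment_sample(stack, label, p=0.0, rng=np.random.default_rng(0))
        assert np.array_equal(s, stack) and np.array_equal(l, label)
        assert not info.flipped and not info.rotated

    def test_p_one_always_transforms(self, sample):
        stack, label = sample
        rng = np.random.default_rng(1)
        for _ in range(10):
            _, _, info = gt.augment_sample(stack, label, p=1.0, rng=rng)
            assert info.flipped and info.rotated

    def test_flip_is_involution(self, sample):
        stack, label = sample
        s1 = np.flip(stack, axis=1)
        s2 = np.flip(s1, axis=1)
        assert np.array_equal(s2, stack)

    def test_image_label_correspondence_preserved(self, sample):
        """A channel equal to the label stays equal after any transform."""
        stack, label = sample
        stack = stack.copy()
        stack[0] = label
        rng = np.random.default_rng(2)
        for _ in range(20):
            s, l, _ = gt.augment_sample(stack, label, p=1.0, rng=rng)
            assert np.array_equal(s[0], l)
            assert gt.dice((l > 0).astype(np.uint8), (s[0] > 0).astype(np.uint8)) == 1.0

    def test_flip_frequency_matches_probability(self, sample):
        """10,000 seeded draws at p=0.5: flip frequency within ±0.015."""
        stack, label = sample
        rng = np.random.default_rng(11)
        flips = sum(
            gt.augment_sample(stack, label, p=0.5, rng=rng)[2].flipped for _ in range(10_000)
        )
        assert flips / 10_000 == pytest.approx(0.5, abs=0.015)


class TestShouldStop:
    def test_exactly_patience_epochs_after_best(self):
        """Best at epoch 5 of 15 with patience 10 stops; at 14 it does not."""
        history = [0.1, 0.2, 0.3, 0.4, 0.9] + [0.9] * 10  # best first at index 4
        assert gt.should_stop(history, patience=10) is True
        assert gt.should_stop(history[:-1], patience=10) is False

    def test_strictly_improving_never_stops(self):
        assert gt.should_stop(list(np.linspace(0, 1, 50)), patience=10) is False

    def test_short_history_never_stops(self):
        assert gt.should_stop([0.5] * 10, patience=10) is False

    def test_ties_do_not_reset(self):
        # plateau at the best value: the first occurrence counts
        assert gt.should_stop([0.9] + [0.9] * 3, patience=3) is True


@pytest.fixture(scope="module")
def micro_pair():
    spec = gt.PhantomSpec(grid_shape=(16, 16, 16), spacing_mm=(6, 6, 6), noise_sd=0.05,
                          cavity_radius_mm=8, rim_thickness_mm=3, edema_radius_mm=18,
                          nodule_radius_mm=0)
    case = gt.generate_phantom(spec)
    stack = gt.standardize_case(case.ce_t1w, case.flair, case.brain_mask, "GTV1")
    return stack, case.gtv1_true


class TestTraining:
    def test_zero_epochs_returns_untrained(self, micro_pair):
        net = build_unet3d(UnetConfig(base_filters=2), seed=0)
        before = net.get_state()
        net, history = train(net, [micro_pair], [micro_pair], TrainConfig(max_epochs=0))
        assert history.epochs == []
        for a, b in zip(before, net.get_state()):
            assert np.array_equal(a, b)

    def test_empty_dataset_rejected(self, micro_pair):
        net = build_unet3d(UnetConfig(base_filters=2), seed=0)
        with pytest.raises(ParameterError):
            train(net, [], [micro_pair], TrainConfig(max_epochs=1))

    def test_scheduler_halves_lr_on_plateau(self, micro_pair):
        """With a tiny LR the validation Dice plateaus immediately, so the
        scheduler must multiply the LR by its factor every `patience` epochs."""
        net = build_unet3d(UnetConfig(base_filters=2, depth=2), seed=0)
        cfg = TrainConfig(
            lr=1e-12,
            max_epochs=6,
            scheduler_patience=2,
            scheduler_factor=0.5,
            early_stop_patience=50,
            crop_shape=(16, 16, 16),
            seed=3,
        )
        _, history = train(net, [micro_pair], [micro_pair], cfg)
        lrs = [e.lr for e in history.epochs]
        # epoch 0 improves (first value); epochs 1,2 plateau -> drop after 2
        assert lrs[:3] == [1e-12, 1e-12, 1e-12]
        assert lrs[3] == pytest.approx(5e-13)
        assert lrs[-1] < 1e-12

    def test_reproducible_with_fixed_seeds(self, micro_pair):
        hists = []
        for _ in range(2):
            net = build_unet3d(UnetConfig(base_filters=2, depth=2), seed=7)
            _, h = train(
                net,
                [micro_pair],
                [micro_pair],
                TrainConfig(lr=1e-3, max_epochs=3, crop_shape=(16, 16, 16), seed=9),
            )
            hists.append([(e.train_loss, e.val_dice) for e in h.epochs])
        assert hists[0] == hists[1]

    def test_overfits_single_phantom(self):
        """Convergence oracle: one easy phantom as train and val reaches
        Dice >= 0.95 well within 200 epochs."""
        spec = gt.PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=(4, 4, 4), noise_sd=0.05)
        case = gt.generate_phantom(spec)
        stack = gt.standardize_case(case.ce_t1w, case.flair, case.brain_mask, "GTV1")
        pair = (stack, case.gtv1_true)
        net = build_unet3d(UnetConfig(base_filters=8, depth=3), seed=0)
        best = 0.0
        for chunk in range(5):  # up to 200 epochs in restartable chunks
            cfg = TrainConfig(
                lr=1e-3,
                max_epochs=40,
                crop_shape=(32, 32, 32),
                seed=1 + chunk,
                early_stop_patience=40,
                aug_probability=0.0,  # pure memorization: the convergence oracle
            )
            net, history = train(net, [pair], [pair], cfg)
            best = max(best, max(history.val_dice))
            if best >= 0.95:
                break
        assert best >= 0.95


class TestPredictVolume:
    def test_whole_volume_equals_direct_forward(self, tiny_net, phantom_bank):
        stack, _ = phantom_bank[0]
        direct = tiny_net.forward(stack.as_array()) >= 0.5
        pred = predict_volume(tiny_net, stack, window=stack.shape)
        assert np.array_equal(pred.voxels.astype(bool), direct)

    def test_constant_probability_stub(self):
        """A head forced to a large positive bias predicts everything."""
        net = build_unet3d(UnetConfig(depth=2, base_filters=2), seed=0)
        net.head.W[...] = 0.0
        net.head.b[...] = 5.0  # sigmoid(5) ≈ 0.99
        pred = predict_volume(net, np.zeros((3, 16, 16, 16), np.float32), threshold=0.5)
        assert pred.voxels.all()

    def test_window_padding_fallback(self, tiny_net, phantom_bank):
        stack, _ = phantom_bank[0]
        pred = predict_volume(tiny_net, stack, window=(64, 64, 64))  # larger than volume
        assert pred.voxels.shape == stack.shape

    def test_indivisible_window_rejected(self, tiny_net, phantom_bank):
        stack, _ = phantom_bank[0]
        with pytest.raises(ParameterError):
            predict_volume(tiny_net, stack, window=(12, 12, 12))

    def test_stitching_consistent_with_whole_volume(self, trained_gtv1):
        """Sliding-window inference agrees with single-pass inference to
        within 1% of voxels on a trained model."""
        net, _, val_pairs = trained_gtv1
        stack, _ = val_pairs[0]
        whole = predict_volume(net, stack)
        stitched = predict_volume(net, stack, window=(16, 16, 16), overlap=0.5)
        disagreement = (whole.voxels != stitched.voxels).mean()
        assert disagreement <= 0.01
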