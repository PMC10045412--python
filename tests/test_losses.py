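"""Loss components: closed forms, brute-force cross-checks, training
descent."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from gsnhv.nn import Tensor, Adam
from gsnhv.blocks import StageSpec
from gsnhv.losses import (LossWeights, bce_loss, dice_loss, mse_loss,
                          msge_loss, joint_loss)
from gsnhv.network import build_network
from gsnhv.postprocess import sobel_kernels
from gsnhv.synthetic import SynthConfig, generate_dataset
from gsnhv.targets import make_training_targets


class TestBCE:
    def test_perfect_prediction_is_nearly_zero(self, rng):
        x = (rng.random((4, 4)) > 0.5).astype(np.float64)
        y = np.clip(x, 1e-7, 1 - 1e-7)
        assert bce_loss(y, x).item() <= 1e-5

    def test_uniform_half_equals_ln2(self, rng):
        x = (rng.random((6, 6)) > 0.3).astype(np.float64)
        assert bce_loss(np.full((6, 6), 0.5), x).item() == pytest.approx(
            np.log(2), abs=1e-9)

    def test_matches_hand_summed_value(self, rng):
        y = rng.uniform(0.05, 0.95, size=(4, 4, 2))
        x = np.zeros((4, 4, 2))
        x[..., 1] = (rng.random((4, 4)) > 0.5)
        x[..., 0] = 1 - x[..., 1]
        manual = -np.mean(x * np.log(y) + (1 - x) * np.log(1 - y))
        assert bce_loss(y, x).item() == pytest.approx(manual, rel=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestDice:
    def test_identical_masks_score_zero(self):
        x = np.zeros((10, 10))
        x[:5, :10] = 1  # 50 foreground pixels
        assert dice_loss(x, x).item() == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_masks_score_near_one(self):
        y = np.zeros((5, 5))
        x = np.zeros((5, 5))
        y.ravel()[:10] = 1
        x.ravel()[10:20] = 1
        expected = 1 - 1e-4 / (20 + 1e-4)
        assert dice_loss(y, x).item() == pytest.approx(expected, rel=1e-9)

    def test_empty_masks_score_zero_via_epsilon(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z).item() == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_joint_permutation(self, rng):
        y = rng.random(30)
        x = (rng.random(30) > 0.5).astype(float)
        perm = rng.permutation(30)
        assert dice_loss(y, x).item() == pytest.approx(
            dice_loss(y[perm], x[perm]).item(), rel=1e-12)


class TestHVLosses:
    def test_zero_when_prediction_equals_target(self, rng):
        gamma = rng.uniform(-1, 1, size=(1, 2, 8, 8))
        mask = np.ones((1, 8, 8))
        assert mse_loss(gamma, gamma).item() == 0.0
        assert msge_loss(gamma, gamma, mask).item() == 0.0

    def test_constant_offset_hits_mse_but_not_msge(self, rng):
        gamma = rng.uniform(-1, 1, size=(1, 2, 8, 8))
        p = gamma + 0.25
        mask = np.ones((1, 8, 8))
        assert mse_loss(p, gamma).item() == pytest.approx(0.25 ** 2, rel=1e-6)
        assert msge_loss(p, gamma, mask).item() == pytest.approx(0.0, abs=1e-10)

    def test_msge_matches_independent_finite_differences(self):
        """1-D ramp prediction vs flat target on a small instance."""
        h, w = 7, 9
        gamma = np.zeros((1, 2, h, w))
        p = np.zeros((1, 2, h, w))
        p[0, 0, 3, 2:7] = np.linspace(-1, 1, 5)  # ramp on the horizontal channel
        mask = np.zeros((1, h, w))
        mask[0, 3, 2:7] = 1
        kx, ky = sobel_kernels(5)
        gx = ndi.correlate(p[0, 0], kx, mode="reflect")
        gy = ndi.correlate(p[0, 1], ky, mode="reflect")
        expected = ((gx ** 2 + gy ** 2) * mask[0]).sum() / mask.sum()
        assert msge_loss(p, gamma, mask).item() == pytest.approx(
            expected, rel=1e-5)

    def test_empty_mask_defines_msge_as_zero(self):
        p = np.ones((1, 2, 4, 4))
        assert msge_loss(p, np.zeros_like(p), np.zeros((1, 4, 4))).item() == 0.0


class _FakeOutputs:
    def __init__(self, q, p, r):
        self.q, self.p, self.r = Tensor(q), Tensor(p), Tensor(r)


class TestJointLoss:
    @pytest.fixture()
    def case(self, rng):
        q = rng.uniform(0.05, 0.95, size=(2, 2, 8, 8))
        p = rng.uniform(-1, 1, size=(2, 2, 8, 8))
        r = rng.uniform(0.05, 0.95, size=(2, 4, 8, 8))
        mask = (rng.random((2, 8, 8)) > 0.5).astype(np.float64)
        targets = {
            "mask_onehot": np.stack([1 - mask, mask], axis=1),
            "hv": rng.uniform(-1, 1, size=(2, 2, 8, 8)),
            "type_onehot": np.eye(4)[rng.integers(0, 4, (2, 8, 8))]
            .transpose(0, 3, 1, 2),
            "mask": mask,
        }
        return _FakeOutputs(q, p, r), targets

    def test_weighted_sum_recomposes_from_components(self, case):
        outputs, targets = case
        w = LossWeights()  # (1, 1, 1, 1, 2, 1)
        total, bd = joint_loss(outputs, targets, w)
        manual = (bce_loss(outputs.q, targets["mask_onehot"]).item()
                  + dice_loss(outputs.q, targets["mask_onehot"]).item()
                  + mse_loss(outputs.p, targets["hv"]).item()
                  + msge_loss(outputs.p, targets["hv"], targets["mask"]).item()
                  + 2 * bce_loss(outputs.r, targets["type_onehot"]).item()
                  + dice_loss(outputs.r, targets["type_onehot"]).item())
        assert total.item() == pytest.approx(manual, rel=1e-6)
        assert all(v >= 0 for v in bd.values())

    def test_zeroing_hv_and_type_weights_leaves_segmentation_loss(self, case):
        outputs, targets = case
        w = LossWeights(lambda_c=0, lambda_d=0, lambda_e=0, lambda_f=0)
        total, _ = joint_loss(outputs, targets, w)
        seg_only = (bce_loss(outputs.q, targets["mask_onehot"]).item()
                    + dice_loss(outputs.q, targets["mask_onehot"]).item())
        assert total.item() == pytest.approx(seg_only, rel=1e-6)

    def test_perfect_predictions_give_negligible_loss(self):
        mask = np.zeros((1, 8, 8))
        mask[0, 2:5, 2:5] = 1
        targets = {
            "mask_onehot": np.stack([1 - mask, mask], axis=1),
            "hv": np.zeros((1, 2, 8, 8)),
            "type_onehot": np.stack(
                [1 - mask, mask, np.zeros_like(mask), np.zeros_like(mask)],
                axis=1),
            "mask": mask,
        }
        outputs = _FakeOutputs(
            np.clip(targets["mask_onehot"], 1e-7, 1 - 1e-7),
            targets["hv"].copy(),
            np.clip(targets["type_onehot"], 1e-7, 1 - 1e-7))
        total, _ = joint_loss(outputs, targets)
        assert total.item() <= 1e-4

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_a=-1.0)
        with pytest.raises(ValueError):
            LossWeights(epsilon=0.0)


def test_loss_decreases_when_overfitting_one_patch(tiny_spec):
    """200 Adam steps on a single patch must at least halve the loss."""
    patch = generate_dataset(SynthConfig(image_size=48, n_images=1,
                                         radius_range=(6.0, 10.0), seed=9))[0]
    image = patch.image.transpose(2, 0, 1)[None]
    targets = {k: v[None] for k, v in
               make_training_targets(patch.instances, patch.types, 3).items()}
    net = build_network(3, spec=tiny_spec, seed=0)
    opt = Adam(net.parameters(), lr=1e-3)
    losses = []
    for _ in range(200):
        net.zero_grad()
        total, _ = joint_loss(net(Tensor(image)), targets)
        total.backward()
        opt.step()
        losses.append(total.item())
    assert losses[-1] < 0.5 * losses[0]
    assert all(np.isfinite(losses))
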