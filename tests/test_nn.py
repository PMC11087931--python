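"""NumPy network engine: layer correctness and the soft Dice loss."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from caaseg.errors import ParameterError
from caaseg.nn import AvgPool2, Conv3d, InstanceNorm, UNet3D, Upsample2
from caaseg.segmenter import _one_hot, dice_loss


@pytest.fixture()
def nn_rng():
    return np.random.default_rng(0)


def test_conv_matches_scipy_correlate(nn_rng):
    conv = Conv3d(2, 3, 3, nn_rng)
    x = nn_rng.standard_normal((2, 5, 7, 6)).astype(np.float32)
    out = conv.forward(x)
    w3 = conv.w.reshape(3, 2, 3, 3, 3)
    for co in range(3):
        ref = sum(
            correlate(x[ci].astype(float), w3[co, ci].astype(float), mode="constant")
            for ci in range(2)
        ) + conv.b[co]
        assert np.abs(out[co] - ref).max() < 1e-5


@pytest.mark.parametrize("k", [1, 3])
def test_conv_backward_is_adjoint(nn_rng, k):
    conv = Conv3d(3, 4, k, nn_rng)
    conv.b[:] = 0
    x = nn_rng.standard_normal((3, 6, 6, 6)).astype(np.float32)
    y = nn_rng.standard_normal((4, 6, 6, 6)).astype(np.float32)
    lhs = float((conv.forward(x) * y).sum())
    rhs = float((x * conv.backward(y)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-4)


def test_conv_weight_gradient(nn_rng):
    conv = Conv3d(2, 3, 3, nn_rng)
    x = nn_rng.standard_normal((2, 5, 5, 5)).astype(np.float32)
    y = nn_rng.standard_normal((3, 5, 5, 5)).astype(np.float32)
    conv.forward(x)
    conv.backward(y)
    v = nn_rng.standard_normal(conv.w.shape).astype(np.float32)
    gdot = float((conv.gw * v).sum())
    eps = 1e-3
    conv.w += eps * v
    lp = float((conv.forward(x) * y).sum())
    conv.w -= 2 * eps * v
    lm = float((conv.forward(x) * y).sum())
    assert (lp - lm) / (2 * eps) == pytest.approx(gdot, rel=1e-3)


@pytest.mark.parametrize("mode", ["nearest", "trilinear"])
def test_upsample_backward_is_adjoint(nn_rng, mode):
    up = Upsample2(mode)
    x = nn_rng.standard_normal((2, 4, 4, 4)).astype(np.float32)
    y = nn_rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
    lhs = float((up.forward(x) * y).sum())
    rhs = float((x * up.backward(y)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-4)


def test_avgpool_backward_is_adjoint(nn_rng):
    pool = AvgPool2()
    x = nn_rng.standard_normal((2, 4, 6, 4)).astype(np.float32)
    y = nn_rng.standard_normal((2, 2, 3, 2)).astype(np.float32)
    lhs = float((pool.forward(x) * y).sum())
    rhs = float((x * pool.backward(y)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-4)


def test_instance_norm_input_gradient(nn_rng):
    norm = InstanceNorm(3)
    norm.g[:] = nn_rng.standard_normal(3)
    x = nn_rng.standard_normal((3, 5, 5, 5)).astype(np.float32)
    y = nn_rng.standard_normal((3, 5, 5, 5)).astype(np.float32)
    norm.forward(x)
    dx = norm.backward(y)
    v = nn_rng.standard_normal(x.shape).astype(np.float32)
    eps = 1e-3
    lp = float((norm.forward(x + eps * v) * y).sum())
    lm = float((norm.forward(x - eps * v) * y).sum())
    assert (lp - lm) / (2 * eps) == pytest.approx(float((dx * v).sum()), rel=5e-3)


def test_unet_shapes_and_depth_guard(nn_rng):
    net = UNet3D(2, 5, depth=3, base_features=4, seed=0)
    x = nn_rng.standard_normal((2, 16, 16, 8)).astype(np.float32)
    assert net.forward(x).shape == (5, 16, 16, 8)
    with pytest.raises(ParameterError):
        UNet3D(2, 5, depth=1)


# --- soft Dice loss -----------------------------------------------------------


def test_perfect_prediction_has_near_zero_loss(nn_rng):
    labels = nn_rng.integers(0, 5, (10, 10, 10))
    onehot = _one_hot(labels, 5)
    assert dice_loss(onehot, onehot, eps=1e-5) < 1e-6


def test_weight_masking_ignores_other_classes(nn_rng):
    labels = nn_rng.integers(0, 5, (8, 8, 8))
    target = _one_hot(labels, 5)
    probs = np.full((5, 8, 8, 8), 0.2, np.float32)
    weights = (0, 1, 0, 0, 0)
    base = dice_loss(probs, target, weights)
    # perturb the probabilities of classes 0 and 2 only, renormalised
    perturbed = probs.copy()
    perturbed[0] += 0.1
    perturbed[2] -= 0.1
    assert dice_loss(perturbed, target, weights) == pytest.approx(base, abs=1e-12)


def test_uniform_prediction_matches_hand_formula():
    """p_c = 1/5 on 100 voxels with 20 class-1 voxels: D_1 = 2*(20/5)/(20+20) = 0.2."""
    labels = np.zeros((100, 1, 1), np.uint8)
    labels[:20] = 1
    target = _one_hot(labels, 5)
    probs = np.full((5, 100, 1, 1), 0.2, np.float64)
    weights = (0, 1, 0, 0, 0)
    loss = dice_loss(probs, target, weights, eps=1e-12)
    assert loss == pytest.approx(1.0 - 0.2, abs=1e-9)


def test_loss_permutation_invariant(nn_rng):
    labels = nn_rng.integers(0, 5, (6, 6, 6))
    target = _one_hot(labels, 5)
    probs = nn_rng.random((5, 6, 6, 6))
    probs /= probs.sum(axis=0, keepdims=True)
    perm = nn_rng.permutation(216)
    probs_p = probs.reshape(5, -1)[:, perm].reshape(5, 6, 6, 6)
    target_p = target.reshape(5, -1)[:, perm].reshape(5, 6, 6, 6)
    assert dice_loss(probs, target) == pytest.approx(dice_loss(probs_p, target_p), abs=1e-12)


def test_loss_bounded_and_shape_checked(nn_rng):
    labels = nn_rng.integers(0, 5, (6, 6, 6))
    target = _one_hot(labels, 5)
    probs = nn_rng.random((5, 6, 6, 6))
    probs /= probs.sum(axis=0, keepdims=True)
    assert 0.0 <= dice_loss(probs, target) <= 1.0
    with pytest.raises(ParameterError):
        dice_loss(probs[:, :3], target)
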