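"""Behavioral and oracle-equivalence tests for the architectural blocks.

Each block's vectorized forward pass is checked against a composition of
loop-based convolution/pooling/normalization oracles on small inputs, plus
the degenerate cases that the block algebra forces (zeros propagation,
residual identity, sigmoid gate range).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poolattnet.autograd as ag
from poolattnet.autograd import Tensor
from poolattnet.blocks import (BN_EPS, ClassificationHead, ConfigurationError,
                               HybridDownsample, InvertedBottleneck,
                               PatchifyStem, PoolingAttention, ShapeError,
                               TNV2Block, tnv2_param_count)

from oracles import (bn_eval_loops, conv2d_loops, gelu_loops, pool2d_loops,
                     sigmoid_scalar, softmax_loops)


def to_tensor(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


def bn_oracle(module, x):
    return bn_eval_loops(x, module.gamma.data.astype(np.float64),
                         module.beta.data.astype(np.float64),
                         module.running_mean.astype(np.float64),
                         module.running_var.astype(np.float64), BN_EPS)


def conv_oracle(module, x):
    return conv2d_loops(x, module.weight.data, module.bias.data,
                        module.stride, module.padding, module.groups)


def randomize_bn(module, rng):
    """Non-trivial inference statistics so oracles exercise the full affine."""
    module.gamma.data = rng.uniform(0.5, 1.5, module.gamma.data.shape).astype(np.float32)
    module.beta.data = rng.normal(0, 0.3, module.beta.data.shape).astype(np.float32)
    module.running_mean = rng.normal(0, 0.3, module.running_mean.shape).astype(np.float32)
    module.running_var = rng.uniform(0.5, 1.5, module.running_var.shape).astype(np.float32)


# ---------------------------------------------------------------------------
# patchify stem
# ---------------------------------------------------------------------------

def test_stem_output_shape_224():
    stem = PatchifyStem(rng=np.random.default_rng(0)).eval()
    out = stem.forward(to_tensor(np.random.default_rng(1).random((1, 3, 224, 224))))
    assert out.data.shape == (1, 96, 56, 56)
    assert np.isfinite(out.data).all()


def test_stem_zeros_propagate():
    stem = PatchifyStem(rng=np.random.default_rng(0)).eval()
    out = stem.forward(to_tensor(np.zeros((1, 3, 224, 224))))
    np.testing.assert_array_equal(out.data, 0.0)


def test_stem_single_patch_embedding_matches_dot_product():
    """A 4x4 image is one patch: its embedding is kernel . patch + bias."""
    rng = np.random.default_rng(5)
    stem = PatchifyStem(out_channels=8, groups=4, rng=rng).eval()
    patch = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
    embedding = stem.patch.forward(to_tensor(patch))
    assert embedding.data.shape == (1, 8, 1, 1)
    manual = np.array([
        float((stem.patch.weight.data[oc].astype(np.float64) * patch[0]).sum())
        + float(stem.patch.bias.data[oc]) for oc in range(8)])
    np.testing.assert_allclose(embedding.data[0, :, 0, 0], manual, atol=1e-5)
    np.testing.assert_allclose(embedding.data, conv_oracle(stem.patch, patch),
                               atol=1e-5)


def test_stem_rejects_bad_inputs():
    stem = PatchifyStem(rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        stem.forward(to_tensor(np.zeros((1, 3, 30, 30))))
    with pytest.raises(ConfigurationError):
        stem.forward(to_tensor(np.zeros((1, 4, 32, 32))))


def test_stem_matches_loop_oracle():
    rng = np.random.default_rng(9)
    stem = PatchifyStem(in_channels=2, out_channels=4, groups=2, rng=rng).eval()
    stem.expand.bias.data = rng.normal(0, 0.2, 16).astype(np.float32)
    stem.project.bias.data = rng.normal(0, 0.2, 4).astype(np.float32)
    randomize_bn(stem.norm, rng)
    x = rng.standard_normal((2, 2, 8, 8)).astype(np.float32)
    got = stem.forward(to_tensor(x)).data
    bp = bn_oracle(stem.norm, conv_oracle(stem.patch, x))
    expected = conv_oracle(stem.project, gelu_loops(conv_oracle(stem.expand, bp))) + bp
    np.testing.assert_allclose(got, expected, atol=1e-5)


# ---------------------------------------------------------------------------
# pooling attention
# ---------------------------------------------------------------------------

def test_attention_gate_open_interval_and_zero_input():
    rng = np.random.default_rng(2)
    att = PoolingAttention(4, rng=rng).eval()
    att.forward(to_tensor(rng.standard_normal((2, 4, 6, 6))))
    gate = att.last_gate.data
    assert (gate > 0).all() and (gate < 1).all()
    att.forward(to_tensor(np.zeros((1, 4, 5, 5))))
    np.testing.assert_allclose(att.last_gate.data, 0.5, atol=1e-7)


def test_attention_hotspot_gate_matches_hand_pooling():
    """Single hotspot: the gate is sigmoid(avg3x3 * max3x3) at every pixel."""
    att = PoolingAttention(1, rng=np.random.default_rng(0)).eval()
    x = np.zeros((1, 1, 4, 4), dtype=np.float32)
    x[0, 0, 2, 2] = 1.0
    att.forward(to_tensor(x))
    avg = pool2d_loops(x, 3, 1, 1, "avg")
    mx = pool2d_loops(x, 3, 1, 1, "max")
    expected = np.vectorize(sigmoid_scalar)(avg * mx)
    np.testing.assert_allclose(att.last_gate.data, expected, atol=1e-6)
    # spot-check the center pixel by hand: full 3x3 window, avg 1/9, max 1
    assert att.last_gate.data[0, 0, 2, 2] == pytest.approx(
        sigmoid_scalar(1.0 / 9.0), abs=1e-6)


def test_attention_preserves_shape_and_matches_oracle():
    rng = np.random.default_rng(4)
    att = PoolingAttention(4, rng=rng).eval()
    att.project.bias.data = rng.normal(0, 0.2, 4).astype(np.float32)
    randomize_bn(att.norm, rng)
    x = rng.standard_normal((2, 4, 7, 5)).astype(np.float32)
    got = att.forward(to_tensor(x)).data
    assert got.shape == x.shape
    bx = bn_oracle(att.norm, x)
    gate = np.vectorize(sigmoid_scalar)(
        pool2d_loops(bx, 3, 1, 1, "avg") * pool2d_loops(bx, 3, 1, 1, "max"))
    mixed = np.concatenate([gate, bx], axis=1)
    expected = conv_oracle(att.project,
                           gelu_loops(pool2d_loops(mixed, 3, 1, 1, "avg"))) + bx
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_attention_rejects_tiny_input():
    att = PoolingAttention(2, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        att.forward(to_tensor(np.zeros((1, 2, 2, 4))))


# ---------------------------------------------------------------------------
# inverted bottleneck
# ---------------------------------------------------------------------------

def test_bottleneck_zero_weights_is_identity():
    ib = InvertedBottleneck(4, groups=4, rng=np.random.default_rng(0)).eval()
    ib.expand.weight.data[:] = 0
    ib.project.weight.data[:] = 0
    x = np.random.default_rng(1).standard_normal((2, 4, 5, 5)).astype(np.float32)
    np.testing.assert_array_equal(ib.forward(to_tensor(x)).data, x)


def test_bottleneck_scalar_chain_oracle():
    """1x1 input: the block is a scalar expand-GELU-compress affine chain."""
    rng = np.random.default_rng(8)
    ib = InvertedBottleneck(4, groups=1, rng=rng).eval()
    ib.expand.bias.data = rng.normal(0, 0.2, 16).astype(np.float32)
    ib.project.bias.data = rng.normal(0, 0.2, 4).astype(np.float32)
    x = rng.standard_normal((1, 4, 1, 1)).astype(np.float32)
    got = ib.forward(to_tensor(x)).data[0, :, 0, 0]
    v = x[0, :, 0, 0].astype(np.float64) / np.sqrt(1.0 + BN_EPS)  # BN, fresh stats
    hidden = ib.expand.weight.data[:, :, 0, 0].astype(np.float64) @ v \
        + ib.expand.bias.data
    from oracles import gelu_scalar
    hidden = np.array([gelu_scalar(h) for h in hidden])
    expected = (ib.project.weight.data[:, :, 0, 0].astype(np.float64) @ hidden
                + ib.project.bias.data + x[0, :, 0, 0])
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_bottleneck_group_divisibility_error():
    with pytest.raises(ConfigurationError):
        InvertedBottleneck(6, groups=4, rng=np.random.default_rng(0))


# ---------------------------------------------------------------------------
# full TNV2 block
# ---------------------------------------------------------------------------

def test_tnv2_preserves_shape_and_counts_convolutions():
    block = TNV2Block(8, rng=np.random.default_rng(0)).eval()
    x = np.random.default_rng(1).standard_normal((1, 8, 6, 6)).astype(np.float32)
    assert block.forward(to_tensor(x)).data.shape == x.shape
    convs = [block.attention.project, block.bottleneck.expand,
             block.bottleneck.project]
    shapes = [c.weight.data.shape for c in convs]
    assert shapes == [(8, 16, 1, 1), (32, 2, 1, 1), (8, 32, 1, 1)]


def test_tnv2_parameter_count_closed_form():
    for f in (8, 96, 192):
        block = TNV2Block(f, rng=np.random.default_rng(0))
        enumerated = sum(p.data.size for _, p in block.named_parameters())
        assert enumerated == tnv2_param_count(f) == 7 * f * f + 10 * f
    assert tnv2_param_count(96) == 65472


def test_tnv2_finite_on_many_gaussian_inputs():
    block = TNV2Block(8, rng=np.random.default_rng(0)).eval()
    x = np.random.default_rng(2).standard_normal((1000, 8, 5, 5)).astype(np.float32)
    out = block.forward(to_tensor(x)).data
    assert np.isfinite(out).all()


# ---------------------------------------------------------------------------
# hybrid downsampling
# ---------------------------------------------------------------------------

def test_downsample_halves_and_doubles():
    down = HybridDownsample(96, rng=np.random.default_rng(0)).eval()
    x = np.random.default_rng(1).standard_normal((1, 96, 56, 56)).astype(np.float32)
    assert down.forward(to_tensor(x)).data.shape == (1, 192, 28, 28)


def test_downsample_constant_input_zero_conv():
    down = HybridDownsample(3, groups=1, rng=np.random.default_rng(0)).eval()
    down.conv.weight.data[:] = 0
    c = 0.7
    out = down.forward(to_tensor(np.full((1, 3, 4, 4), c, dtype=np.float32)))
    from oracles import gelu_scalar
    np.testing.assert_allclose(out.data, gelu_scalar(c), atol=1e-6)


def test_downsample_matches_loop_oracle():
    rng = np.random.default_rng(12)
    down = HybridDownsample(2, groups=2, rng=rng).eval()
    down.conv.bias.data = rng.normal(0, 0.2, 4).astype(np.float32)
    x = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
    got = down.forward(to_tensor(x)).data
    pooled = np.concatenate([pool2d_loops(x, 2, 2, 0, "avg"),
                             pool2d_loops(x, 2, 2, 0, "max")], axis=1)
    expected = gelu_loops(pooled + conv_oracle(down.conv, x))
    np.testing.assert_allclose(got, expected, atol=1e-5)


def test_downsample_rejects_odd_input():
    down = HybridDownsample(2, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        down.forward(to_tensor(np.zeros((1, 2, 5, 6))))


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------

def test_head_gap_and_softmax():
    rng = np.random.default_rng(3)
    head = ClassificationHead(768, 4, rng=rng)
    x = rng.standard_normal((2, 768, 7, 7)).astype(np.float32)
    gap = ag.global_avg_pool(to_tensor(x))
    assert gap.data.shape == (2, 768)
    probs = head.probabilities(to_tensor(x))
    assert probs.shape == (2, 4)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert ((probs > 0) & (probs < 1)).all()
    logits = head.forward(to_tensor(x)).data
    np.testing.assert_allclose(probs, softmax_loops(logits), atol=1e-6)


def test_head_zero_weights_uniform():
    head = ClassificationHead(16, 5, rng=np.random.default_rng(0))
    head.fc.weight.data[:] = 0
    probs = head.probabilities(to_tensor(np.random.default_rng(1)
                                         .standard_normal((3, 16, 2, 2))))
    np.testing.assert_allclose(probs, 0.2, atol=1e-7)


def test_head_rejects_single_class():
    with pytest.raises(ConfigurationError):
        ClassificationHead(16, 1)


# ---------------------------------------------------------------------------
# cross-block properties
# ---------------------------------------------------------------------------

@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       kind=st.sampled_from(["attention", "bottleneck", "tnv2", "down"]),
       train_mode=st.booleans())
def test_blocks_preserve_finiteness(seed, kind, train_mode):
    """Finite input -> finite output under randomized weights and inputs."""
    rng = np.random.default_rng(seed)
    f = int(rng.choice([4, 8]))
    block = {"attention": lambda: PoolingAttention(f, rng=rng),
             "bottleneck": lambda: InvertedBottleneck(f, rng=rng),
             "tnv2": lambda: TNV2Block(f, rng=rng),
             "down": lambda: HybridDownsample(f, rng=rng)}[kind]()
    block.train(train_mode)
    x = (rng.standard_normal((2, f, 6, 6)) * rng.uniform(0.1, 10)).astype(np.float32)
    out = block.forward(to_tensor(x)).data
    assert np.isfinite(out).all()
    if kind in ("attention", "bottleneck", "tnv2"):
        assert out.shape == x.shape
    else:
        assert out.shape == (2, 2 * f, 3, 3)
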