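"""Architectural building blocks of the pooling-attention network.

Four operators make up the architecture:

* **patchify stem** — a 4x4/stride-4 convolution embeds the image into a
  56x56x96 grid, refined by a small inverted bottleneck with a residual from
  the (shared) normalized patch embedding.
* **pooling-based attention** — a parameter-free gate: the sigmoid of the
  elementwise product of 3x3 average- and max-pooled feature maps, depth
  concatenated with the normalized input and projected back to F channels,
  with a residual.  Average pooling tracks the global load distribution;
  max pooling tracks focal peaks.
* **inverted bottleneck** — expand to 4F with a grouped 1x1 convolution,
  GELU, compress back to F, residual (the convolutional analogue of a
  transformer feed-forward block).
* **hybrid downsampling** — stride-2 average and max pooling concatenated to
  2F channels, summed with a stride-2 grouped 2x2 convolution, one GELU.

Plus the GAP + fully connected + softmax classification head.

All blocks run in NCHW layout and preserve finiteness of finite inputs.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

BN_EPS = 1e-5          # batch-norm epsilon
BN_MOMENTUM = 0.1      # running = (1-m)*running + m*batch
EXPANSION_RATIO = 4    # inverted-bottleneck channel expansion


class ConfigurationError(ValueError):
    """Invalid layer/channel/group configuration."""


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with a block."""


# ---------------------------------------------------------------------------
# module base + parametric layers
# ---------------------------------------------------------------------------

class Module:
    """Lightweight parameter container with named state traversal."""

    def __init__(self):
        self.training = False

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            # leaves only: cached activations (graph nodes) are not parameters
            if isinstance(val, Tensor) and val.requires_grad and not val._parents:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        own = set(params) | {n for n, _ in self.named_buffers()}
        missing = own - set(state)
        extra = set(state) - own
        if missing or extra:
            raise ConfigurationError(
                f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ConfigurationError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].copy()
        # buffers are plain arrays on modules; assign by attribute walk
        for name, _ in list(self.named_buffers()):
            obj = self
            parts = name.split(".")
            for part in parts[:-1]:
                obj = getattr(obj, part)
            setattr(obj, parts[-1], state[name].copy())


class Conv2d(Module):
    """Learnable (grouped) convolution; He fan-in init, zero bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ConfigurationError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel * kernel
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels // groups, kernel, kernel))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.weight.data.shape[1] * self.groups:
            raise ConfigurationError(
                f"expected {self.weight.data.shape[1] * self.groups} input channels, "
                f"got {x.data.shape[1]}")
        return ag.conv2d(x, self.weight, self.bias, self.stride,
                         self.padding, self.groups)

    def param_count(self) -> int:
        return self.weight.data.size + self.bias.data.size


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.gamma.data.size:
            raise ConfigurationError(
                f"batch-norm expects {self.gamma.data.size} channels, got {x.data.shape[1]}")
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (m / max(m - 1, 1))
            self.running_mean = ((1 - BN_MOMENTUM) * self.running_mean
                                 + BN_MOMENTUM * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - BN_MOMENTUM) * self.running_var
                                + BN_MOMENTUM * unbiased).astype(self.running_var.dtype)
            return ag.batch_norm(x, self.gamma, self.beta, mean, var, BN_EPS, True)
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, BN_EPS, False)

    def param_count(self) -> int:
        return self.gamma.data.size + self.beta.data.size


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)

    def param_count(self) -> int:
        return self.weight.data.size + self.bias.data.size


# ---------------------------------------------------------------------------
# architectural blocks
# ---------------------------------------------------------------------------

class PatchifyStem(Module):
    """4x4/stride-4 patch embedding refined by a grouped inverted bottleneck.

    out = Conv1x1_F( GELU( GC1x1_4F( BN(P) ) ) ) + BN(P),  P = Conv4x4_F,s4(x).

    The patchify convolution and its batch-norm are each applied once and the
    result shared by both branches.
    """

    def __init__(self, in_channels: int = 3, out_channels: int = 96,
                 groups: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        self.patch = Conv2d(in_channels, out_channels, kernel=4, stride=4, rng=rng)
        self.norm = BatchNorm2d(out_channels)
        self.expand = Conv2d(out_channels, EXPANSION_RATIO * out_channels,
                             kernel=1, groups=groups, rng=rng)
        self.project = Conv2d(EXPANSION_RATIO * out_channels, out_channels,
                              kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if c != self.patch.weight.data.shape[1]:
            raise ConfigurationError(f"stem expects "
                                     f"{self.patch.weight.data.shape[1]} channels, got {c}")
        if h % 4 or w % 4:
            raise ShapeError(f"stem input {h}x{w} not divisible by the patch stride 4")
        bp = self.norm.forward(self.patch.forward(x))
        return ag.add(self.project.forward(ag.gelu(self.expand.forward(bp))), bp)


class PoolingAttention(Module):
    """Parameter-free pooled-attention gate with projection and residual.

    gate  = sigmoid( avg3x3(BN(x)) * max3x3(BN(x)) )          (elementwise)
    mixed = concat(gate, BN(x))                               (2F channels)
    out   = Conv1x1_F( GELU( avg3x3(mixed) ) ) + BN(x)

    One shared batch-norm of x feeds all three appearances.  All 3x3 pools
    are stride 1 with same-padding, so spatial size is preserved.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.norm = BatchNorm2d(channels)
        self.project = Conv2d(2 * channels, channels, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.data.shape
        if h < 3 or w < 3:
            raise ShapeError(f"pooling attention needs >=3x3 input, got {h}x{w}")
        bx = self.norm.forward(x)
        gate = ag.sigmoid(ag.mul(ag.avg_pool2d(bx, 3, 1, 1),
                                 ag.max_pool2d(bx, 3, 1, 1)))
        self.last_gate = gate  # exposed for inspection/testing
        mixed = ag.concat_channels(gate, bx)
        return ag.add(self.project.forward(ag.gelu(ag.avg_pool2d(mixed, 3, 1, 1))), bx)


class InvertedBottleneck(Module):
    """Expand (grouped 1x1, ratio 4) - GELU - compress, with identity residual."""

    def __init__(self, channels: int, groups: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.norm = BatchNorm2d(channels)
        self.expand = Conv2d(channels, EXPANSION_RATIO * channels,
                             kernel=1, groups=groups, rng=rng)
        self.project = Conv2d(EXPANSION_RATIO * channels, channels, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.project.forward(ag.gelu(self.expand.forward(self.norm.forward(x))))
        return ag.add(y, x)


class TNV2Block(Module):
    """Pooling attention followed by an inverted bottleneck (shape preserving)."""

    def __init__(self, channels: int, expansion_groups: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.attention = PoolingAttention(channels, rng=rng)
        self.bottleneck = InvertedBottleneck(channels, groups=expansion_groups, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.bottleneck.forward(self.attention.forward(x))


class HybridDownsample(Module):
    """Halve the resolution, double the channels.

    out = GELU( concat(avg2x2_s2(x), max2x2_s2(x)) + GC2x2_2F,s2(x) )

    The average-pooled map occupies the lower channel indices.  Odd spatial
    sizes are an error: no implicit padding.
    """

    def __init__(self, channels: int, groups: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(channels, 2 * channels, kernel=2, stride=2,
                           groups=groups, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.data.shape
        if h % 2 or w % 2:
            raise ShapeError(f"hybrid downsample needs even spatial dims, got {h}x{w}")
        pooled = ag.concat_channels(ag.avg_pool2d(x, 2, 2), ag.max_pool2d(x, 2, 2))
        return ag.gelu(ag.add(pooled, self.conv.forward(x)))


class ClassificationHead(Module):
    """Global average pool, fully connected layer, softmax probabilities."""

    def __init__(self, channels: int, num_classes: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if num_classes < 2:
            raise ConfigurationError(f"need at least 2 classes, got {num_classes}")
        self.fc = Linear(channels, num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """Return logits (softmax applied by the caller or loss)."""
        return self.fc.forward(ag.global_avg_pool(x))

    def probabilities(self, x: Tensor) -> np.ndarray:
        return ag.softmax(self.forward(x).data)


def conv_param_count(kh: int, kw: int, cin: int, cout: int,
                     groups: int = 1, bias: bool = True) -> int:
    """Closed-form parameter count of one (grouped) convolution."""
    return kh * kw * cin * cout // groups + (cout if bias else 0)


def tnv2_param_count(channels: int, expansion_groups: int = 4) -> int:
    """Closed-form trainable parameters of one TNV2 block.

    Two batch-norms (2F each), the 2F->F attention projection, the grouped
    F->4F expansion and the 4F->F compression.  With groups=4 this reduces
    to 7F^2 + 10F.
    """
    f = channels
    return (2 * f                                         # attention BN
            + conv_param_count(1, 1, 2 * f, f)            # attention projection
            + 2 * f                                       # bottleneck BN
            + conv_param_count(1, 1, f, 4 * f, expansion_groups)
            + conv_param_count(1, 1, 4 * f, f))
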