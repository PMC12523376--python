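"""Network assembly, shape tracing, parameter counting, checkpoints.

The published variant is

    stem -> [TNV2 x R1] -> down -> [TNV2 x R2] -> down -> [TNV2 x R3]
         -> down -> [TNV2 x R4] -> GAP -> FC -> softmax

with stage widths F = (96, 192, 384, 768) and repeats R = (1, 1, 1, 1); a
224x224x3 input then flows 56x56x96 -> 28x28x192 -> 14x14x384 -> 7x7x768 and
the head sees a 768-feature GAP vector.  Widths and repeats are configurable
for lighter or larger variants.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import (
    ClassificationHead, ConfigurationError, HybridDownsample, Module,
    PatchifyStem, TNV2Block, conv_param_count, tnv2_param_count,
)

__all__ = ["NetworkConfig", "Network", "ShapeTrace", "ParamCount",
           "build_network", "trace_shapes", "count_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``filters`` are the per-stage channel widths (strictly doubling between
    consecutive stages), ``repeats`` the TNV2 block count per stage.
    ``group_policy`` is (expansion groups, downsample groups, stem groups).
    """

    filters: tuple[int, ...] = (96, 192, 384, 768)
    repeats: tuple[int, ...] = (1, 1, 1, 1)
    num_classes: int = 2
    group_policy: tuple[int, int, int] = (4, 2, 4)
    input_size: tuple[int, int, int] = (224, 224, 3)
    seed: int = 0

    def __post_init__(self):
        self.filters = tuple(int(f) for f in self.filters)
        self.repeats = tuple(int(r) for r in self.repeats)
        self.group_policy = tuple(int(g) for g in self.group_policy)
        self.input_size = tuple(int(s) for s in self.input_size)
        self.validate()

    def validate(self) -> None:
        if len(self.filters) != len(self.repeats):
            raise ConfigurationError(
                f"{len(self.filters)} filter widths vs {len(self.repeats)} repeats")
        if not self.filters:
            raise ConfigurationError("at least one stage is required")
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >=2, got {self.num_classes}")
        g_exp, g_down, g_stem = self.group_policy
        for i, f in enumerate(self.filters):
            if f < 1:
                raise ConfigurationError(f"stage {i}: width {f} < 1")
            if f % g_exp:
                raise ConfigurationError(
                    f"stage {i}: width {f} not divisible by expansion groups {g_exp}")
            if i + 1 < len(self.filters):
                if self.filters[i + 1] != 2 * f:
                    raise ConfigurationError(
                        f"stage {i + 1}: width {self.filters[i + 1]} must double {f}")
                if f % g_down:
                    raise ConfigurationError(
                        f"stage {i}: width {f} not divisible by downsample groups {g_down}")
        if self.filters[0] % g_stem:
            raise ConfigurationError(
                f"stem width {self.filters[0]} not divisible by stem groups {g_stem}")
        for r in self.repeats:
            if r < 1:
                raise ConfigurationError(f"repeat counts must be >=1, got {r}")
        h, w, c = self.input_size
        if h % 4 or w % 4:
            raise ConfigurationError(f"input {h}x{w} not divisible by the stem stride 4")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


@dataclass
class ShapeTrace:
    """Ordered (stage name, (H, W, C)) output shapes, plus the GAP length."""

    stages: list[tuple[str, tuple[int, int, int]]]
    gap_features: int

    def shapes(self) -> list[tuple[int, int, int]]:
        return [s for _, s in self.stages]


@dataclass
class ParamCount:
    per_layer: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def millions(self, decimals: int = 1) -> float:
        return round(self.total / 1e6, decimals)


class Network(Module):
    """The assembled model.  ``forward`` returns logits and caches the last
    convolutional stage output (pre-GAP) for saliency methods."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        g_exp, g_down, g_stem = cfg.group_policy
        rng = np.random.default_rng(cfg.seed)
        self.stem = PatchifyStem(cfg.input_size[2], cfg.filters[0],
                                 groups=g_stem, rng=rng)
        self._blocks: list[tuple[str, Module]] = []
        for i, (f, r) in enumerate(zip(cfg.filters, cfg.repeats)):
            for j in range(r):
                name = f"stage{i + 1}.block{j + 1}"
                block = TNV2Block(f, expansion_groups=g_exp, rng=rng)
                setattr(self, f"_s{i + 1}b{j + 1}", block)
                self._blocks.append((name, block))
            if i + 1 < len(cfg.filters):
                name = f"down{i + 1}"
                down = HybridDownsample(f, groups=g_down, rng=rng)
                setattr(self, f"_d{i + 1}", down)
                self._blocks.append((name, down))
        self.head = ClassificationHead(cfg.filters[-1], cfg.num_classes, rng=rng)
        self.last_feature: Tensor | None = None

    def features(self, x: Tensor) -> Tensor:
        """Run the convolutional trunk; returns the pre-GAP feature map."""
        t = self.stem.forward(x)
        for _, block in self._blocks:
            t = block.forward(t)
        self.last_feature = t
        return t

    def forward(self, x: Tensor) -> Tensor:
        return self.head.forward(self.features(x))

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Probabilities for NHWC float images in [0, 1]; eval mode, no graph."""
        self.eval()
        out = []
        for start in range(0, images.shape[0], batch_size):
            batch = images[start:start + batch_size].transpose(0, 3, 1, 2)
            logits = self.forward(Tensor(np.ascontiguousarray(batch, dtype=np.float32)))
            out.append(ag.softmax(logits.data))
        return np.concatenate(out, axis=0)


def build_network(cfg: NetworkConfig) -> Network:
    """Construct the model; deterministic given ``cfg.seed``."""
    return Network(cfg)


def trace_shapes(cfg: NetworkConfig) -> ShapeTrace:
    """Symbolic per-stage output shapes; allocates no weights."""
    cfg.validate()
    h, w, _ = cfg.input_size
    h, w = h // 4, w // 4
    stages: list[tuple[str, tuple[int, int, int]]] = []
    stages.append(("stem", (h, w, cfg.filters[0])))
    for i, (f, r) in enumerate(zip(cfg.filters, cfg.repeats)):
        for j in range(r):
            stages.append((f"tnv2_{i + 1}" + (f".{j + 1}" if r > 1 else ""),
                           (h, w, f)))
        if i + 1 < len(cfg.filters):
            if h % 2 or w % 2:
                raise ConfigurationError(
                    f"stage {i + 1} output {h}x{w} is odd; cannot downsample")
            h, w = h // 2, w // 2
            stages.append((f"down_{i + 1}", (h, w, 2 * f)))
    return ShapeTrace(stages=stages, gap_features=cfg.filters[-1])


def count_parameters(cfg: NetworkConfig) -> ParamCount:
    """Closed-form trainable parameter count per layer group.

    Counts convolution kernels and biases, batch-norm scale/shift (running
    statistics are not trainable) and the fully connected head.
    """
    cfg.validate()
    g_exp, g_down, g_stem = cfg.group_policy
    f0 = cfg.filters[0]
    per: dict[str, int] = {}
    per["stem"] = (conv_param_count(4, 4, cfg.input_size[2], f0)
                   + 2 * f0
                   + conv_param_count(1, 1, f0, 4 * f0, g_stem)
                   + conv_param_count(1, 1, 4 * f0, f0))
    for i, (f, r) in enumerate(zip(cfg.filters, cfg.repeats)):
        per[f"stage{i + 1}"] = r * tnv2_param_count(f, g_exp)
        if i + 1 < len(cfg.filters):
            per[f"down{i + 1}"] = conv_param_count(2, 2, f, 2 * f, g_down)
    per["head"] = cfg.filters[-1] * cfg.num_classes + cfg.num_classes
    return ParamCount(per_layer=per, total=sum(per.values()))


def enumerate_parameters(model: Network) -> int:
    """Total trainable parameters by enumerating instantiated weight arrays."""
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Network, path) -> None:
    """Single-archive checkpoint: config JSON + all weight/buffer arrays."""
    state = model.state_dict()
    cfg_json = json.dumps(model.cfg.to_dict())
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> Network:
    """Rebuild the model; forward outputs are bit-identical to save time."""
    with np.load(path) as archive:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(archive["__config__"]).decode()))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model = Network(cfg)
    model.load_state_dict(state)
    return model


def checkpoint_bytes(model: Network) -> bytes:
    buf = io.BytesIO()
    save_checkpoint(model, buf)
    return buf.getvalue()
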