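"""Grad-CAM saliency from the last convolutional stage.

Channel weights are the spatially averaged gradients of the chosen class
score (pre-softmax logit) with respect to the final TNV2 stage's output; the
map is the rectified weighted sum of those activations, bilinearly upsampled
to the input resolution and min-max normalized to [0, 1].  A constant raw
map (e.g. an all-zero-weight head) yields the degenerate all-zeros heat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .autograd import Tensor
from .network import Network

__all__ = ["SaliencyMap", "grad_cam", "overlay_saliency", "save_saliency_png"]

TARGET_LAYER = "stage4"  # output of the last TNV2 stage, pre-GAP


@dataclass
class SaliencyMap:
    heat: np.ndarray          # (H, W) in [0, 1], input resolution
    class_index: int
    layer_name: str = TARGET_LAYER


def grad_cam(model: Network, image: np.ndarray, class_index: int) -> SaliencyMap:
    """Saliency for one HWC image in [0, 1] toward ``class_index``."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    if not 0 <= class_index < model.cfg.num_classes:
        raise ValueError(
            f"class index {class_index} outside [0, {model.cfg.num_classes})")
    model.eval()
    for p in model.parameters():
        p.zero_grad()
    x = Tensor(image.transpose(2, 0, 1)[None])
    logits = model.forward(x)
    seed = np.zeros_like(logits.data)
    seed[0, class_index] = 1.0
    logits.backward(seed)
    feat = model.last_feature
    act = feat.data[0].astype(np.float64)             # (C, h, w)
    grad = feat.grad[0].astype(np.float64)
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    heat = resize(cam, image.shape[:2], order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    span = heat.max() - heat.min()
    if span <= 0 or not np.isfinite(span):
        heat = np.zeros(image.shape[:2])
    else:
        heat = (heat - heat.min()) / span
    for p in model.parameters():
        p.zero_grad()
    return SaliencyMap(heat=heat, class_index=class_index)


def overlay_saliency(image: np.ndarray, saliency: SaliencyMap,
                     alpha: float = 0.45, cmap: str = "viridis") -> np.ndarray:
    """Alpha-blend the heat over the image; returns a uint8 RGB array."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colormaps

    rgb = np.asarray(colormaps[cmap](saliency.heat))[:, :, :3]
    base = np.asarray(image, dtype=np.float64)
    blended = (1 - alpha) * base + alpha * rgb
    return np.clip(np.round(blended * 255), 0, 255).astype(np.uint8)


def save_saliency_png(image: np.ndarray, saliency: SaliencyMap, out_path,
                      overlay_path=None) -> None:
    from PIL import Image

    heat8 = np.clip(np.round(saliency.heat * 255), 0, 255).astype(np.uint8)
    Image.fromarray(heat8).save(out_path)
    if overlay_path is not None:
        Image.fromarray(overlay_saliency(image, saliency)).save(overlay_path)
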