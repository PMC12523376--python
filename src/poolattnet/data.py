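"""Datasets: class-foldered image I/O and a synthetic plantar-pressure generator.

The generator emulates pedobarographic images of barefoot gait: a foot-shaped
contact region, a heel-to-toe center-of-pressure (COP) polyline, and additive
sensor noise, with every image's total load normalized to the same constant
(emulating body-weight normalization).  Two classes are produced:

* ``osteoarthritis`` (focal) — 1-3 compact high-intensity Gaussian hotspots
  at heel/forefoot on a faint base load;
* ``control`` (diffuse) — the same total mass spread smoothly over the whole
  contact surface.

Class indices are lexicographic over class names, so ``control`` is 0 and
``osteoarthritis`` is 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = ["LabeledImageSet", "SyntheticSpec", "read_image_folder",
           "write_image_folder", "split_train_val", "generate_pressure_images",
           "foot_mask"]

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass
class LabeledImageSet:
    """Images (N, H, W, 3) float32 in [0, 1] with integer class labels."""

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    split: str = ""

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError(f"{len(self.images)} images vs {len(self.labels)} labels")
        if len(self.labels) and not (
                (self.labels >= 0) & (self.labels < len(self.class_names))).all():
            raise ValueError("labels out of range of class_names")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices, split: str = "") -> "LabeledImageSet":
        idx = np.asarray(indices)
        return LabeledImageSet(self.images[idx], self.labels[idx],
                               list(self.class_names), split or self.split)


def read_image_folder(root, size: int = 224) -> LabeledImageSet:
    """Read a directory-per-class tree of PNG/JPEG images.

    Classes and files are ordered lexicographically; images are resized to
    ``size`` x ``size`` (bilinear), grayscale replicated to 3 channels and
    scaled to [0, 1].
    """
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"{root}: need at least 2 class subdirectories, "
                         f"found {len(class_dirs)}")
    images, labels = [], []
    for label, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in _IMAGE_EXTENSIONS)
        if not files:
            raise ValueError(f"class directory {cdir} contains no readable images")
        for path in files:
            try:
                with Image.open(path) as img:
                    arr = np.asarray(
                        img.convert("RGB").resize((size, size), Image.BILINEAR))
            except Exception as exc:
                raise ValueError(f"unreadable image {path}: {exc}") from exc
            images.append(arr.astype(np.float32) / 255.0)
            labels.append(label)
    return LabeledImageSet(np.stack(images), np.array(labels),
                           [d.name for d in class_dirs])


def write_image_folder(dataset: LabeledImageSet, root) -> None:
    """Write a dataset back as 8-bit PNGs in a directory-per-class tree."""
    root = Path(root)
    for label, name in enumerate(dataset.class_names):
        cdir = root / name
        cdir.mkdir(parents=True, exist_ok=True)
        for i in np.flatnonzero(dataset.labels == label):
            arr = np.clip(np.round(dataset.images[i] * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(cdir / f"img_{i:05d}.png")


def split_train_val(dataset: LabeledImageSet, fraction: float = 0.8,
                    seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified random split into (train, val); disjoint and exhaustive."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for label, name in enumerate(dataset.class_names):
        idx = np.flatnonzero(dataset.labels == label)
        if len(idx) < 2:
            raise ValueError(f"class {name!r} has {len(idx)} item(s); need >=2 to split")
        perm = rng.permutation(idx)
        n_train = min(max(int(round(fraction * len(idx))), 1), len(idx) - 1)
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:])
    return (dataset.subset(sorted(train_idx), "train"),
            dataset.subset(sorted(val_idx), "val"))


# ---------------------------------------------------------------------------
# synthetic plantar-pressure generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Generation parameters; generation is a pure function of this spec.

    Lengths are fractions of the image side.  ``total_mass_fraction`` sets the
    common normalized load: every image sums to ``total_mass_fraction * size**2``.
    """

    n_per_class: int = 100
    size: int = 224
    noise_level: float = 0.02
    hotspot_count: tuple[int, int] = (1, 3)
    hotspot_radius: tuple[float, float] = (0.04, 0.06)
    hotspot_intensity: tuple[float, float] = (0.55, 0.75)
    cop_waypoints: int = 5
    cop_width: float = 0.012
    cop_intensity: float = 0.10
    focal_base: float = 0.18
    diffuse_base: float = 0.30
    total_mass_fraction: float = 0.038
    seed: int = 0
    class_names: tuple[str, str] = ("control", "osteoarthritis")

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >=1")
        if self.size < 32:
            raise ValueError("size must be >=32")
        if self.hotspot_radius[1] > 0.12:
            raise ValueError(
                f"hotspot radius {self.hotspot_radius[1]} exceeds the foot-mask "
                "regions (max 0.12 of the image side)")
        if not self.hotspot_radius[0] <= self.hotspot_radius[1]:
            raise ValueError("hotspot_radius range inverted")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >=0")


# anatomical anchor regions in unit coordinates (x, y), y=0 at the toes
_HEEL = (0.50, 0.78)
_FOREFOOT = (0.52, 0.33)
_TOES = (0.53, 0.16)


def foot_mask(size: int, soft_sigma_frac: float = 0.01) -> np.ndarray:
    """Soft [0, 1] foot-shaped contact mask (union of heel, arch, forefoot, toes)."""
    jj, ii = np.meshgrid(np.arange(size), np.arange(size))
    x = (jj + 0.5) / size
    y = (ii + 0.5) / size
    regions = [
        ((x - _HEEL[0]) / 0.13) ** 2 + ((y - _HEEL[1]) / 0.13) ** 2,
        ((x - 0.47) / 0.105) ** 2 + ((y - 0.58) / 0.17) ** 2,     # medial arch
        ((x - _FOREFOOT[0]) / 0.17) ** 2 + ((y - _FOREFOOT[1]) / 0.14) ** 2,
        ((x - _TOES[0]) / 0.155) ** 2 + ((y - _TOES[1]) / 0.07) ** 2,
    ]
    hard = np.zeros((size, size), dtype=np.float64)
    for r2 in regions:
        hard = np.maximum(hard, (r2 <= 1.0).astype(np.float64))
    return gaussian_filter(hard, sigma=max(soft_sigma_frac * size, 0.5))


def _cop_field(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Heel-to-toe COP polyline rendered as a Gaussian-profile ridge."""
    s = spec.size
    ys = np.linspace(_HEEL[1] + 0.02, _TOES[1], spec.cop_waypoints)
    xs = 0.5 + rng.uniform(-0.04, 0.04, size=spec.cop_waypoints)
    xs[0] = _HEEL[0]
    # densify the polyline
    t = np.linspace(0, 1, 24 * spec.cop_waypoints)
    px = np.interp(t, np.linspace(0, 1, spec.cop_waypoints), xs) * s
    py = np.interp(t, np.linspace(0, 1, spec.cop_waypoints), ys) * s
    jj, ii = np.meshgrid(np.arange(s), np.arange(s))
    d2 = ((jj[:, :, None] - px[None, None, :]) ** 2
          + (ii[:, :, None] - py[None, None, :]) ** 2).min(axis=2)
    sigma = spec.cop_width * s
    return spec.cop_intensity * np.exp(-0.5 * d2 / sigma ** 2)


def _render_image(rng: np.random.Generator, focal: bool, spec: SyntheticSpec,
                  mask: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """One pressure map (2-D, normalized mass) plus the hotspot mask (focal only)."""
    s = spec.size
    jj, ii = np.meshgrid(np.arange(s), np.arange(s))
    field = np.zeros((s, s), dtype=np.float64)
    hotspot_mask = None
    if focal:
        field += spec.focal_base * mask
        k = int(rng.integers(spec.hotspot_count[0], spec.hotspot_count[1] + 1))
        hotspot_mask = np.zeros((s, s), dtype=bool)
        anchors = [_HEEL, _FOREFOOT, _TOES]
        chosen = rng.choice(len(anchors), size=min(k, len(anchors)), replace=False)
        for a in chosen:  # distinct anchors: hotspots never stack
            ax, ay = anchors[a]
            cx = (ax + rng.uniform(-0.06, 0.06)) * s
            cy = (ay + rng.uniform(-0.04, 0.04)) * s
            sigma = rng.uniform(*spec.hotspot_radius) * s
            amp = rng.uniform(*spec.hotspot_intensity)
            d2 = (jj - cx) ** 2 + (ii - cy) ** 2
            field += amp * np.exp(-0.5 * d2 / sigma ** 2)
            hotspot_mask |= d2 <= (2.0 * sigma) ** 2
    else:
        # smooth large-scale unevenness on top of an even base load
        rough = rng.standard_normal((s, s))
        rough = gaussian_filter(rough, sigma=0.08 * s)
        rough /= max(np.abs(rough).max(), 1e-12)
        field += spec.diffuse_base * mask * (1.0 + 0.3 * rough)
    field += _cop_field(rng, spec)
    if spec.noise_level > 0:
        field += spec.noise_level * rng.standard_normal((s, s))
    field = np.maximum(field, 0.0)
    # body-weight normalization: identical total load for every image
    total = field.sum()
    if total <= 0:
        raise ValueError("degenerate image: zero total pressure")
    field *= (spec.total_mass_fraction * s * s) / total
    return np.minimum(field, 1.0), hotspot_mask


def generate_pressure_images(spec: SyntheticSpec, return_masks: bool = False):
    """Generate the two-class synthetic dataset described by ``spec``.

    Deterministic under ``spec.seed``.  With ``return_masks`` also returns a
    per-image list of boolean hotspot masks (``None`` for diffuse images),
    for localization checks against saliency maps.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = foot_mask(spec.size)
    names = sorted(spec.class_names)
    focal_name = spec.class_names[1]          # "osteoarthritis-like" class
    images, labels, masks = [], [], []
    for label, name in enumerate(names):
        for _ in range(spec.n_per_class):
            field, hmask = _render_image(rng, name == focal_name, spec, mask)
            images.append(np.repeat(field[:, :, None], 3, axis=2).astype(np.float32))
            labels.append(label)
            masks.append(hmask)
    dataset = LabeledImageSet(np.stack(images), np.array(labels), names, "synthetic")
    if return_masks:
        return dataset, masks
    return dataset
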