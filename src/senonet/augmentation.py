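"""Label-preserving augmentation for small microscopy datasets.

The training set is enlarged with random rotations, translations and flips
applied identically to all three channels, with zero fill where the
transformed image leaves the frame. Cropping, stretching, zoom and shear are
deliberately excluded: they would deform the spatial arrangement and
apparent concentration of lipid droplets and mitochondria, the very features
carrying the senescence signal. The default makes 11 transformed copies per
image, so 170 training fields of view become 2040. Augmentation of the test
split is refused outright — a data-leakage guard, since test images must
remain untouched by any training-side processing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._rng import mix_seed, rng_from
from .data_io import DatasetBundle, MultimodalImage, Split


@dataclass(frozen=True)
class AugmentationConfig:
    copies_per_image: int = 11
    rotation_range_deg: tuple[float, float] = (-180.0, 180.0)
    translation_fraction: float = 0.10
    flip_horizontal: bool = True
    flip_vertical: bool = True
    fill_value: float = 0.0
    interpolation_order: int = 1  # bilinear; 0 = nearest-neighbor for exactness checks
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation_range_deg", tuple(self.rotation_range_deg))
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")
        if not 0.0 <= self.translation_fraction < 1.0:
            raise ValueError("translation_fraction must lie in [0, 1)")
        if self.fill_value != 0.0:
            raise ValueError("fill value is fixed at zero (zero-fill augmentation)")


def _transform_planes(planes: np.ndarray, angle_deg: float, shift: tuple[int, int],
                      flip_h: bool, flip_v: bool, order: int) -> np.ndarray:
    """Apply rotation -> integer translation -> flips to an (H, W, C) stack."""
    out = planes
    if angle_deg != 0.0:
        lo, hi = float(np.nanmin(out)), float(np.nanmax(out))
        out = ndimage.rotate(out, angle_deg, axes=(0, 1), reshape=False, order=order,
                             mode="constant", cval=0.0, prefilter=False)
        # bilinear weights cannot overshoot, but guard the range anyway
        out = np.clip(out, min(0.0, lo), hi)
    dr, dc = shift
    if dr or dc:
        shifted = np.zeros_like(out)
        h, w = out.shape[:2]
        src_r = slice(max(0, -dr), min(h, h - dr))
        dst_r = slice(max(0, dr), min(h, h + dr))
        src_c = slice(max(0, -dc), min(w, w - dc))
        dst_c = slice(max(0, dc), min(w, w + dc))
        shifted[dst_r, dst_c] = out[src_r, src_c]
        out = shifted
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def random_transform(img: MultimodalImage, cfg: AugmentationConfig,
                     rng: np.random.Generator) -> MultimodalImage:
    """One random rotation + translation + flips, identical across channels.

    Translation offsets are integer pixel shifts of at most
    ``translation_fraction`` of each dimension; vacated pixels are exactly
    zero. The label and metadata are copied; dimensions never change.
    """
    angle = float(rng.uniform(*cfg.rotation_range_deg))
    h, w = img.height, img.width
    dr = int(rng.integers(-int(cfg.translation_fraction * h), int(cfg.translation_fraction * h) + 1))
    dc = int(rng.integers(-int(cfg.translation_fraction * w), int(cfg.translation_fraction * w) + 1))
    flip_h = bool(cfg.flip_horizontal and rng.random() < 0.5)
    flip_v = bool(cfg.flip_vertical and rng.random() < 0.5)
    return apply_transform(img, angle, (dr, dc), flip_h, flip_v, cfg.interpolation_order)


def apply_transform(img: MultimodalImage, angle_deg: float, shift: tuple[int, int],
                    flip_h: bool, flip_v: bool, order: int = 1) -> MultimodalImage:
    """Deterministic counterpart of :func:`random_transform`."""
    planes = _transform_planes(img.to_array(), angle_deg, shift, flip_h, flip_v, order)
    out = img.with_channels(planes)
    if img.marker_mask is not None:
        mask = _transform_planes(img.marker_mask.astype(float)[..., None], angle_deg, shift,
                                 flip_h, flip_v, order=0)[..., 0]
        out = replace(out, marker_mask=mask >= 0.5)
    return out


def augment_dataset(ds: DatasetBundle, cfg: AugmentationConfig) -> DatasetBundle:
    """Originals plus ``copies_per_image`` random transforms of each image.

    Output size is exactly ``len(ds) * (copies_per_image + 1)`` and class
    proportions are preserved exactly (every copy keeps its source label).

    Raises ``ValueError`` if ``ds`` is the test split: augmenting evaluation
    data would leak training-side processing into the measurement.
    """
    if ds.split is Split.TEST:
        raise ValueError("refusing to augment the TEST split (data-leakage guard)")
    images = list(ds.images)
    for i, img in enumerate(ds.images):
        for c in range(cfg.copies_per_image):
            rng = rng_from(cfg.seed, i, c)
            aug = random_transform(img, cfg, rng)
            aug = replace(aug, source_id=f"{img.source_id}_aug{c:02d}")
            images.append(aug)
    return DatasetBundle(images, ds.split)


def per_learner_datasets(ds: DatasetBundle, n_learners: int,
                         cfg: AugmentationConfig) -> list[DatasetBundle]:
    """One independently augmented bundle per ensemble learner.

    Each learner sees the same originals but its own random transforms,
    drawn from a sub-seed mixed deterministically from ``cfg.seed`` and the
    learner index. This diversity between weak learners is what gives the
    ensemble its generalization edge.
    """
    if n_learners < 1:
        raise ValueError("n_learners must be >= 1")
    bundles = []
    for li in range(n_learners):
        sub = replace(cfg, seed=mix_seed(cfg.seed, li) if n_learners > 1 else cfg.seed)
        bundles.append(augment_dataset(ds, sub))
    return bundles
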