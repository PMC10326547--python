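"""Grad-CAM interpretability for the senescence classifiers.

Gradient-weighted class activation mapping: the gradient of the senescence
score (the pre-sigmoid logit) with respect to the final convolutional
stage's feature maps is spatially averaged into one importance weight per
feature channel; the rectified, weighted sum of the feature maps is a
coarse localization map of the evidence driving the prediction. The coarse
map (e.g. 6 x 8 cells for deep backbones on a 250 x 300 input — set by the
last convolutional layer's spatial size) is upscaled to image resolution by
bilinear interpolation and normalized to [0, 1] (an all-zero map stays
all-zero). Bright regions are the ones pushing the classifier toward
"senescent"; a confidently control-classified image shows negligible
activation.

On synthetic data, where the implanted lipid-droplet / mitochondrial-focus
supports are known, the point-biserial correlation between the upscaled map
and the marker mask quantifies how well the attention colocalizes with the
true senescence markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps
from skimage.transform import resize

from .architectures import LearnerModel
from .data_io import ChannelImage, Label, MultimodalImage


@dataclass
class GradCAMMap:
    coarse: np.ndarray  # (h, w) rectified, normalized map at feature-map resolution
    target: Label = Label.SENESCENT
    upscaled: np.ndarray | None = None  # (H, W) after bilinear upscaling

    @property
    def map(self) -> np.ndarray:
        return self.upscaled if self.upscaled is not None else self.coarse


def _normalize(m: np.ndarray) -> np.ndarray:
    top = float(m.max())
    return m / top if top > 0 else m


def gradcam_map(model: LearnerModel, img: MultimodalImage | np.ndarray,
                target: Label = Label.SENESCENT) -> GradCAMMap:
    """Coarse Grad-CAM map of one image for the requested class.

    The class score is the pre-sigmoid logit for SENESCENT (its negative for
    CONTROL, since a single sigmoid output encodes both classes). Channel
    weights are the spatial means of d score / d feature-map; the map is
    ReLU(sum_k weight_k * map_k), normalized to [0, 1]. A constant-output
    model has zero gradients everywhere and yields an all-zero map.
    """
    if model.last_conv_index < 0:
        raise ValueError("model has no identifiable final convolutional stage")
    x = img.to_array() if isinstance(img, MultimodalImage) else np.asarray(img)
    xb = model.preprocess_fn(x[None].astype(np.float32)).astype(np.float32)
    net = model.network
    li = model.last_conv_index
    # forward in training=True mode ONLY in the sense of caching activations;
    # dropout must stay inactive, so run eval forward but keep layer caches
    _, fmap = net.forward(xb, training=False, capture=li)
    # seed d score / d logit = +/-1 at the output of the last Dense layer
    sign = 1.0 if target is Label.SENESCENT else -1.0
    grad0 = np.full((1, 1), sign, dtype=np.float32)
    sig_ix = len(net.layers) - 1
    # caches from the eval forward are valid for backward (dropout passes through)
    dfmap = net.backward_from(grad0, from_layer=sig_ix - 1, to_layer=li + 1)
    weights = dfmap.mean(axis=(1, 2))  # (1, C) spatially averaged gradients
    cam = np.maximum((fmap * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    return GradCAMMap(coarse=_normalize(cam), target=target)


def upscale_map(m: GradCAMMap, height: int, width: int) -> GradCAMMap:
    """Bilinear upscaling of the coarse map to image resolution.

    Values stay within [0, 1]; a constant coarse map upscales to the same
    constant; upscaling to the coarse size itself is the identity.
    """
    if m.coarse.size == 0:
        raise ValueError("empty coarse map")
    if m.coarse.shape == (height, width):
        up = m.coarse.copy()
    else:
        up = resize(m.coarse.astype(np.float64), (height, width), order=1,
                    mode="edge", anti_aliasing=False)
    return GradCAMMap(coarse=m.coarse, target=m.target, upscaled=np.clip(up, 0.0, 1.0))


def ensemble_gradcam(learners: list[LearnerModel], img: MultimodalImage,
                     target: Label = Label.SENESCENT, per_learner: bool = False
                     ) -> GradCAMMap | list[GradCAMMap]:
    """Grad-CAM for an ensemble: per-learner maps averaged at image scale.

    ``per_learner=True`` returns the individual upscaled maps instead of
    their average.
    """
    h, w = img.height, img.width
    maps = [upscale_map(gradcam_map(m, img, target), h, w) for m in learners]
    if per_learner:
        return maps
    mean = np.mean([mp.upscaled for mp in maps], axis=0)
    if len({mp.coarse.shape for mp in maps}) == 1:
        coarse = np.mean([mp.coarse for mp in maps], axis=0)
    else:  # heterogeneous backbones: keep the first learner's coarse grid
        coarse = maps[0].coarse
    return GradCAMMap(coarse=np.asarray(coarse), target=target, upscaled=mean)


def colocalization_score(m: GradCAMMap, marker_mask: np.ndarray) -> float:
    """Point-biserial correlation between map values and marker membership.

    1.0 when the map equals the mask, -1.0 for the inverted mask, about 0
    for maps independent of the markers. NaN when the mask is empty or full
    (the correlation is undefined without both groups).
    """
    vals = m.map
    mask = np.asarray(marker_mask, dtype=bool)
    if vals.shape != mask.shape:
        raise ValueError(f"map shape {vals.shape} != mask shape {mask.shape}")
    if mask.all() or not mask.any():
        return float("nan")
    flat_mask = mask.ravel().astype(float)
    flat_vals = vals.ravel().astype(float)
    if np.allclose(flat_vals, flat_vals[0]):
        return float("nan")
    r, _ = sps.pointbiserialr(flat_mask, flat_vals)
    return float(r)


def render_overlay(m: GradCAMMap, channel: ChannelImage, out_path: str | Path,
                   alpha: float = 0.6, cmap: str = "jet") -> Path:
    """Side-by-side PNG: the raw channel next to its Grad-CAM blend.

    The blend weight is alpha * map, so an all-zero map leaves the channel
    untouched. Output bytes are deterministic for fixed inputs.
    """
    from matplotlib import colormaps
    from PIL import Image

    vals = m.map
    if vals.shape != channel.pixels.shape:
        raise ValueError("map and channel dimensions differ")
    lo, hi = float(channel.pixels.min()), float(channel.pixels.max())
    gray = (channel.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(channel.pixels)
    gray3 = np.stack([gray] * 3, axis=-1)
    heat = np.asarray(colormaps[cmap](vals))[..., :3]
    w = (alpha * vals)[..., None]
    blended = (1.0 - w) * gray3 + w * heat
    panel = np.concatenate([gray3, blended], axis=1)
    img8 = (np.clip(panel, 0, 1) * 255).round().astype(np.uint8)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img8).save(out_path, format="PNG")
    return out_path
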