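"""Multimodal image containers, manifest I/O and shallow preprocessing.

A field of view is a co-registered three-channel image: SRS at the
2850 cm^-1 CH2 lipid stretching mode (lipid droplets appear bright), TPEF of
the endogenous NADH/FAD coenzymes (metabolic / mitochondrial contrast) and
optical transmission (morphology). Preprocessing is deliberately shallow so
the physical signals are not distorted: percentile-based outlier clipping,
background suppression, then per-channel rescaling to the 0-255 range
expected by ImageNet-style backbones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("id", "path_srs", "path_tpef", "path_trans", "label", "split")

#: Default image geometry: 250 x 300 pixels at 0.35 um pitch.
DEFAULT_HEIGHT = 250
DEFAULT_WIDTH = 300
DEFAULT_PIXEL_SIZE_UM = 0.35


class Modality(str, Enum):
    SRS = "SRS"
    TPEF = "TPEF"
    TRANS = "TRANS"


#: Canonical channel order used when stacking a field of view into an array.
MODALITIES = (Modality.SRS, Modality.TPEF, Modality.TRANS)


class Label(str, Enum):
    SENESCENT = "SENESCENT"
    CONTROL = "CONTROL"
    UNLABELED = "UNLABELED"


class Split(str, Enum):
    TRAIN = "TRAIN"
    VALIDATION = "VALIDATION"
    TEST = "TEST"


def parse_label(text: str) -> Label:
    """Parse a manifest label string, case-insensitively."""
    key = str(text).strip().upper()
    if key in ("SENESCENT", "TIS", "1"):
        return Label.SENESCENT
    if key in ("CONTROL", "UNTREATED", "0"):
        return Label.CONTROL
    if key in ("UNLABELED", ""):
        return Label.UNLABELED
    raise ValueError(f"unrecognized label {text!r}")


@dataclass
class ChannelImage:
    """One 2-D intensity channel of a field of view."""

    pixels: np.ndarray
    modality: Modality
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("channel pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("channel pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class MultimodalImage:
    """A labeled three-channel field of view (SRS, TPEF, TRANS)."""

    channels: Mapping[Modality, ChannelImage]
    label: Label = Label.UNLABELED
    source_id: str = ""
    treatment_tag: str = ""
    #: Optional ground-truth senescence-marker support (synthetic data only):
    #: union of the implanted lipid-droplet and mitochondrial-focus blobs.
    marker_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [m for m in MODALITIES if m not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {[m.value for m in missing]}")
        shapes = {self.channels[m].shape for m in MODALITIES}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if not isinstance(self.label, Label):
            self.label = Label(self.label)

    @property
    def height(self) -> int:
        return self.channels[Modality.SRS].shape[0]

    @property
    def width(self) -> int:
        return self.channels[Modality.SRS].shape[1]

    def to_array(self) -> np.ndarray:
        """Stack channels into an (H, W, 3) array in (SRS, TPEF, TRANS) order."""
        return np.stack([self.channels[m].pixels for m in MODALITIES], axis=-1)

    def with_channels(self, planes: np.ndarray) -> "MultimodalImage":
        """A copy with pixel planes replaced by an (H, W, 3) array."""
        chans = {
            m: ChannelImage(planes[..., i], m, self.channels[m].pixel_size_um)
            for i, m in enumerate(MODALITIES)
        }
        return replace(self, channels=chans)


@dataclass
class DatasetBundle:
    """An ordered collection of fields of view with a split tag."""

    images: list[MultimodalImage] = field(default_factory=list)
    split: Split = Split.TRAIN

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def class_counts(self) -> dict[Label, int]:
        counts: dict[Label, int] = {}
        for img in self.images:
            counts[img.label] = counts.get(img.label, 0) + 1
        return counts

    def labels(self) -> list[Label]:
        return [img.label for img in self.images]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (N, H, W, 3) pixels and (N,) binary labels (senescent=1)."""
        x = np.stack([img.to_array() for img in self.images])
        y = np.array([1 if img.label is Label.SENESCENT else 0 for img in self.images])
        return x, y


@dataclass(frozen=True)
class PreprocessConfig:
    """Percentile clipping / background subtraction / byte-range scaling knobs.

    The defaults clip each channel at its 1st and 99th percentile, estimate
    the background as the 10th-percentile intensity, and rescale to [0, 255].
    Values are kept as floats (no quantization) so backbone-specific scaling
    is not applied on top of a rounding step.
    """

    low_percentile: float = 0.01
    high_percentile: float = 0.99
    background_quantile: float = 0.10
    output_min: float = 0.0
    output_max: float = 255.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_percentile < self.high_percentile <= 1.0:
            raise ValueError("need 0 <= low < high <= 1")
        if self.output_max <= self.output_min:
            raise ValueError("output_max must exceed output_min")


# ---------------------------------------------------------------------------
# preprocessing operations


def remove_outliers(img: ChannelImage, cfg: PreprocessConfig = PreprocessConfig()) -> ChannelImage:
    """Clip intensities to the [low, high] percentile band of the channel.

    Hot pixels (detector spikes) are lowered to the high-percentile value and
    under-shoots raised to the low-percentile value; a constant channel is
    returned unchanged (its percentiles coincide).
    """
    lo = np.quantile(img.pixels, cfg.low_percentile)
    hi = np.quantile(img.pixels, cfg.high_percentile)
    return replace(img, pixels=np.clip(img.pixels, lo, hi))


def suppress_background(img: ChannelImage, cfg: PreprocessConfig = PreprocessConfig()) -> ChannelImage:
    """Subtract the background level and clamp negatives to zero.

    The background is estimated as the ``background_quantile`` intensity of
    the channel — a robust stand-in for the empty-field signal level.
    """
    bg = np.quantile(img.pixels, cfg.background_quantile)
    return replace(img, pixels=np.maximum(img.pixels - bg, 0.0))


def rescale_to_byte_range(img: ChannelImage, cfg: PreprocessConfig = PreprocessConfig()) -> ChannelImage:
    """Affine map sending the channel min to 0 and max to 255.

    Constant channels map to all zeros (there is no contrast to preserve).
    """
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if hi == lo:
        return replace(img, pixels=np.zeros_like(img.pixels))
    scaled = (img.pixels - lo) / (hi - lo) * (cfg.output_max - cfg.output_min) + cfg.output_min
    return replace(img, pixels=scaled)


def preprocess_image(img: MultimodalImage, cfg: PreprocessConfig = PreprocessConfig()) -> MultimodalImage:
    """Outlier clipping -> background suppression -> byte-range scaling, per channel."""
    chans = {}
    for m in MODALITIES:
        ch = img.channels[m]
        ch = remove_outliers(ch, cfg)
        ch = suppress_background(ch, cfg)
        ch = rescale_to_byte_range(ch, cfg)
        chans[m] = ch
    return replace(img, channels=chans)


def preprocess_dataset(ds: DatasetBundle, cfg: PreprocessConfig = PreprocessConfig()) -> DatasetBundle:
    """Apply the per-channel preprocessing chain to every image of a bundle.

    Labels, split membership, image order and dimensions are untouched.
    """
    return DatasetBundle([preprocess_image(img, cfg) for img in ds.images], ds.split)


# ---------------------------------------------------------------------------
# manifest I/O


class ManifestFormatError(ValueError):
    """The manifest CSV is missing required columns or has malformed rows."""


def _read_channel(path: Path, modality: Modality) -> ChannelImage:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path))
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim == 3 and pixels.shape[-1] == 1:
        pixels = pixels[..., 0]
    return ChannelImage(pixels, modality)


def load_manifest(path: str | Path, split: Split | None = None) -> DatasetBundle:
    """Read a CSV manifest into a :class:`DatasetBundle`.

    The manifest has columns ``id, path_srs, path_tpef, path_trans, label,
    split`` with per-channel image paths relative to the manifest location.
    If ``split`` is given, only rows of that split are loaded; otherwise the
    manifest must contain a single split (mixed-split manifests must be read
    one split at a time so no bundle ever spans splits).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest {path} missing columns {missing}")
    if split is not None:
        df = df[df["split"].str.upper() == split.value]
    elif len(df) and df["split"].str.upper().nunique() > 1:
        raise ManifestFormatError(
            f"manifest {path} mixes splits {sorted(df['split'].unique())}; pass split="
        )
    if len(df) == 0:
        logger.warning("manifest %s contains no rows%s", path, f" for split {split}" if split else "")
        return DatasetBundle([], split or Split.TRAIN)

    base = path.parent
    images = []
    for _, row in df.iterrows():
        chans = {}
        for mod, col in ((Modality.SRS, "path_srs"), (Modality.TPEF, "path_tpef"), (Modality.TRANS, "path_trans")):
            p = base / row[col]
            try:
                chans[mod] = _read_channel(p, mod)
            except (OSError, FileNotFoundError) as exc:
                raise IOError(f"manifest row id={row['id']!r}: cannot read {col}={p}") from exc
        mask = None
        if "path_mask" in df.columns and row.get("path_mask", ""):
            mask = tifffile.imread(base / row["path_mask"]).astype(bool)
        images.append(
            MultimodalImage(
                channels=chans,
                label=parse_label(row["label"]),
                source_id=str(row["id"]),
                treatment_tag=str(row.get("treatment_tag", "")),
                marker_mask=mask,
            )
        )
    bundle_split = split or Split(df["split"].iloc[0].upper())
    return DatasetBundle(images, bundle_split)


def save_bundle(
    ds: DatasetBundle,
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
    write_masks: bool = True,
) -> Path:
    """Write a bundle to disk as per-channel TIFFs plus a CSV manifest.

    Returns the manifest path. Channel files are float32 TIFFs named
    ``<id>_<modality>.tif``; synthetic marker masks, when present, are
    written as uint8 TIFFs referenced by an extra ``path_mask`` column.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    any_mask = write_masks and any(img.marker_mask is not None for img in ds.images)
    for img in ds.images:
        row = {"id": img.source_id, "label": img.label.value.capitalize(), "split": ds.split.value,
               "treatment_tag": img.treatment_tag}
        for mod, col in ((Modality.SRS, "path_srs"), (Modality.TPEF, "path_tpef"), (Modality.TRANS, "path_trans")):
            fname = f"{img.source_id}_{mod.value.lower()}.tif"
            tifffile.imwrite(out_dir / fname, img.channels[mod].pixels.astype(np.float32))
            row[col] = fname
        if any_mask:
            fname = f"{img.source_id}_mask.tif"
            mask = img.marker_mask if img.marker_mask is not None else np.zeros((img.height, img.width), bool)
            tifffile.imwrite(out_dir / fname, mask.astype(np.uint8))
            row["path_mask"] = fname
        rows.append(row)
    cols = list(MANIFEST_COLUMNS) + (["path_mask"] if any_mask else []) + ["treatment_tag"]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    manifest = out_dir / manifest_name
    df.to_csv(manifest, index=False)
    return manifest


def total_value_count(n_images: int, height: int = DEFAULT_HEIGHT, width: int = DEFAULT_WIDTH,
                      n_channels: int = 3) -> int:
    """Total scalar count of a dataset of ``n_images`` fields of view.

    224 images of 250 x 300 x 3 hold 50,400,000 values — the "more than
    50 M values" scale of a full acquisition campaign.
    """
    return int(n_images) * int(height) * int(width) * int(n_channels)


def concat_bundles(bundles: Iterable[DatasetBundle], split: Split) -> DatasetBundle:
    images: list[MultimodalImage] = []
    for b in bundles:
        images.extend(b.images)
    return DatasetBundle(images, split)
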