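"""Classifier architectures: scratch CNN, transfer-learning head, backbones.

Three model families share one output contract — a single sigmoid
probability of the senescent class:

* a small CNN trained from scratch: three 3x3 convolutional layers with 6,
  12 and 24 filters, 2-D max pooling between them, then global max pooling,
  dropout, a 4-neuron ReLU dense layer and a 1-neuron sigmoid output;
* a transfer-learning classifier: a pre-trained convolutional backbone
  (frozen or fine-tuned) under a small head — global max pooling, dropout
  at rate 0.8, a 4-neuron ReLU dense layer carrying L1 and L2 penalties of
  0.01, and the sigmoid output neuron;
* the backbone registry names the seven ImageNet-trained networks the
  ensemble is built from (InceptionV3, EfficientNetB4, DenseNet121,
  ResNet50, MobileNet, Xception, InceptionResNetV2) plus STUB, a tiny
  deterministic two-stage convolutional extractor that satisfies the same
  interface with no weight download, used for testing and desk-scale runs.

Requesting a named backbone raises immediately rather than silently
substituting the stub: their ImageNet weights are not shipped and must be
wired in by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._rng import rng_from
from .data_io import MODALITIES, Modality, MultimodalImage
from .nn import ChannelScale, Conv2D, Dense, Dropout, GlobalMaxPool2D, MaxPool2D, Network, ReLU, Sigmoid

BACKBONE_NAMES = (
    "InceptionV3",
    "EfficientNetB4",
    "DenseNet121",
    "ResNet50",
    "MobileNet",
    "Xception",
    "InceptionResNetV2",
)

MIN_INPUT_SIZE = 8


class BackboneWeightsUnavailable(RuntimeError):
    pass


@dataclass
class TLHeadSpec:
    """The dense classification head placed on top of a backbone."""

    dropout_rate: float = 0.8
    hidden_units: int = 4
    l1: float = 0.01
    l2: float = 0.01


@dataclass
class BackboneHandle:
    """A convolutional feature extractor behind a uniform interface.

    ``network`` maps a preprocessed (N, H, W, 3) batch to the last
    convolutional stage's feature tensor; ``feature_vector_fn`` pools that
    tensor into one fixed-length descriptor per image (off-the-shelf
    features for the hybrid PCA+SVM path).
    """

    name: str
    network: Network
    n_features: int
    preprocess_fn: Callable[[np.ndarray], np.ndarray]
    trainable: bool = False

    def feature_map_fn(self, x: np.ndarray) -> np.ndarray:
        return self.network.forward(self.preprocess_fn(np.asarray(x, dtype=np.float32)))

    def feature_vector_fn(self, x: np.ndarray) -> np.ndarray:
        fmap = self.feature_map_fn(x)
        # mean and max pooling concatenated: captures both average signal
        # level and peak responses of every feature channel
        return np.concatenate([fmap.mean(axis=(1, 2)), fmap.max(axis=(1, 2))], axis=1)


@dataclass
class LearnerModel:
    """One trainable classifier with its training state."""

    network: Network
    kind: str  # "scratch" | "tl"
    backbone_name: str = ""
    backbone_n_layers: int = 0
    last_conv_index: int = -1  # index of the last convolutional stage's output
    preprocess_fn: Callable[[np.ndarray], np.ndarray] = lambda x: x
    trained: bool = False

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Senescence probability per image; dropout inactive (deterministic)."""
        x = self.preprocess_fn(np.asarray(x, dtype=np.float32))
        out = [self.network.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out)[:, 0]

    def n_parameters(self, trainable_only: bool = False) -> int:
        total = 0
        for i, layer in enumerate(self.network.layers):
            if trainable_only and (not layer.trainable or i in self.network.frozen):
                continue
            total += sum(v.size for v in layer.params().values())
        return total


# ---------------------------------------------------------------------------
# builders


def _check_input(input_shape: tuple[int, int, int]) -> None:
    h, w, c = input_shape
    if h < MIN_INPUT_SIZE or w < MIN_INPUT_SIZE:
        raise ValueError(f"input must be at least {MIN_INPUT_SIZE}x{MIN_INPUT_SIZE}, got {h}x{w}")
    if c != 3:
        raise ValueError("expected a three-channel input (SRS, TPEF, TRANS)")


def build_scratch_cnn(input_shape: tuple[int, int, int] = (250, 300, 3), seed: int = 0,
                      dropout_rate: float = 0.5) -> LearnerModel:
    """The from-scratch CNN: conv(6) -> pool -> conv(12) -> pool -> conv(24)
    -> global max pool -> dropout -> dense(4, ReLU) -> dense(1, sigmoid).

    The global-pooling tail makes the trainable parameter count independent
    of the image size (3444 convolutional + 105 dense parameters).
    """
    _check_input(input_shape)
    rng = rng_from(seed, 101)
    layers = [
        Conv2D(3, 6, 3, rng), ReLU(), MaxPool2D(),
        Conv2D(6, 12, 3, rng), ReLU(), MaxPool2D(),
        Conv2D(12, 24, 3, rng), ReLU(),
        GlobalMaxPool2D(), Dropout(dropout_rate),
        Dense(24, 4, rng=rng, bias_init=0.1), ReLU(),
        Dense(4, 1, rng=rng, zero_init=True), Sigmoid(),
    ]
    net = Network(layers)
    net.seed_dropout(seed)
    # last convolutional stage = post-activation output of the third conv
    return LearnerModel(net, kind="scratch", last_conv_index=7,
                        preprocess_fn=lambda x: x / 255.0)


def build_stub_backbone(channels: int = 3, seed: int = 0,
                        widths: tuple[int, int] = (8, 16)) -> BackboneHandle:
    """A tiny deterministic two-stage convolutional feature extractor.

    conv(w0) -> ReLU -> pool -> conv(w1) -> ReLU -> pool, He-initialized from
    ``seed``; the feature map is ceil(H/4) x ceil(W/4) x w1 and the feature
    vector is 2*w1 (mean+max pooled). No network access, no stored weights.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    rng = rng_from(seed, 202)
    w0, w1 = widths
    net = Network([
        Conv2D(channels, w0, 3, rng), ReLU(), MaxPool2D(),
        Conv2D(w0, w1, 3, rng), ReLU(), MaxPool2D(),
    ])
    # calibrated response normalization: fix per-channel gains so feature
    # maps are O(1) on byte-range input, the role batch statistics play in
    # real pretrained backbones. Data-independent (noise batch from seed).
    preprocess = lambda x: x / 127.5 - 1.0  # noqa: E731
    cal = rng.uniform(0.0, 255.0, (8, 32, 32, channels)).astype(np.float32)
    fmap = net.forward(preprocess(cal))
    gain = 1.0 / (fmap.std(axis=(0, 1, 2)) + 1e-3)
    net.layers.append(ChannelScale(gain))
    return BackboneHandle(name="STUB", network=net, n_features=2 * w1,
                          preprocess_fn=preprocess)


def get_backbone(name: str, seed: int = 0, channels: int = 3) -> BackboneHandle:
    """Look up a backbone by registry name.

    ``STUB`` is always available. The seven named ImageNet backbones require
    pre-trained weights that this package does not ship; requesting one
    raises :class:`BackboneWeightsUnavailable` with an explicit message — it
    never silently falls back to the stub.
    """
    if name.upper() == "STUB":
        return build_stub_backbone(channels=channels, seed=seed)
    if name in BACKBONE_NAMES:
        raise BackboneWeightsUnavailable(
            f"backbone {name!r} is registered but its ImageNet weights are not "
            "bundled with this package; provide a weight source or use 'STUB'"
        )
    raise KeyError(f"unknown backbone {name!r}; known: {BACKBONE_NAMES + ('STUB',)}")


def build_tl_classifier(backbone: BackboneHandle, head: TLHeadSpec = TLHeadSpec(),
                        seed: int = 0, frozen: bool = True) -> LearnerModel:
    """A backbone with the dense classification head on top.

    ``frozen=True`` marks the backbone layers as excluded from optimization
    (off-the-shelf mode); the fine-tuning stage unfreezes them.
    """
    fmap = backbone.network.layers
    n_backbone = len(fmap)
    # infer the backbone's channel count from its last convolution
    conv_channels = None
    for layer in reversed(fmap):
        if isinstance(layer, Conv2D):
            conv_channels = layer.out_channels
            break
    if conv_channels is None:
        raise ValueError("backbone has no convolutional stage")
    rng = rng_from(seed, 303)
    head_layers = [
        GlobalMaxPool2D(), Dropout(head.dropout_rate),
        Dense(conv_channels, head.hidden_units, l1=head.l1, l2=head.l2, rng=rng, bias_init=0.1), ReLU(),
        Dense(head.hidden_units, 1, rng=rng, zero_init=True), Sigmoid(),
    ]
    net = Network(fmap + head_layers)
    net.seed_dropout(seed)
    if frozen:
        net.frozen = set(range(n_backbone))
    # the last ReLU of the backbone is the final convolutional stage output
    last_conv = max(i for i, l in enumerate(fmap) if isinstance(l, (Conv2D, ReLU)))
    return LearnerModel(net, kind="tl", backbone_name=backbone.name,
                        backbone_n_layers=n_backbone, last_conv_index=last_conv,
                        preprocess_fn=backbone.preprocess_fn)


# ---------------------------------------------------------------------------
# channel plumbing


@dataclass(frozen=True)
class ChannelOrder:
    """Bijective mapping of modalities onto the (R, G, B) plane positions."""

    order: tuple[Modality, Modality, Modality] = field(
        default=(Modality.SRS, Modality.TPEF, Modality.TRANS)
    )

    def __post_init__(self) -> None:
        if sorted(m.value for m in self.order) != sorted(m.value for m in MODALITIES):
            raise ValueError("order must be a permutation of (SRS, TPEF, TRANS)")

    def permutation(self) -> tuple[int, int, int]:
        """Plane ``i`` of the output holds canonical channel ``permutation()[i]``."""
        return tuple(MODALITIES.index(m) for m in self.order)  # type: ignore[return-value]

    def inverse(self) -> "ChannelOrder":
        perm = self.permutation()
        inv = tuple(MODALITIES[int(j)] for j in np.argsort(perm))
        return ChannelOrder(inv)  # type: ignore[arg-type]


def map_channels_to_rgb(img: MultimodalImage, order: ChannelOrder = ChannelOrder()) -> np.ndarray:
    """Arrange the three channels into an (H, W, 3) array per ``order``.

    Backbone-specific intensity scaling (``preprocess_fn``) is applied by
    the caller afterwards, not here.
    """
    return np.stack([img.channels[m].pixels for m in order.order], axis=-1)
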