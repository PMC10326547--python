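import numpy as np
import pytest

from senonet.data_io import ChannelImage, Label, Modality, MultimodalImage, Split
from senonet.synthetic import SynthConfig, default_params, generate_bundle

SMALL_H, SMALL_W = 64, 80


def make_image(pixels_by_modality=None, label=Label.CONTROL, h=12, w=16, source_id="img0",
               fill=10.0):
    """A tiny hand-made multimodal image for plumbing tests."""
    chans = {}
    for m in Modality:
        px = None if pixels_by_modality is None else pixels_by_modality.get(m)
        if px is None:
            px = np.full((h, w), fill)
        chans[m] = ChannelImage(np.asarray(px, dtype=float), m)
    return MultimodalImage(channels=chans, label=label, source_id=source_id)


@pytest.fixture(scope="session")
def small_params():
    return default_params(SMALL_H, SMALL_W, effect_size=1.0)


@pytest.fixture(scope="session")
def tiny_train_bundle(small_params):
    """12 senescent + 10 control small synthetic images (raw, unpreprocessed)."""
    return generate_bundle(SynthConfig(SMALL_H, SMALL_W, 12, 10, seed=11), small_params,
                           Split.TRAIN)


@pytest.fixture(scope="session")
def preprocessed_bundle(tiny_train_bundle):
    from senonet.data_io import preprocess_dataset

    return preprocess_dataset(tiny_train_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
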