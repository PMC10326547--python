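"""Manifest I/O and the shallow preprocessing chain."""

import numpy as np
import pytest

from senonet.data_io import (
    ChannelImage,
    DatasetBundle,
    Label,
    ManifestFormatError,
    Modality,
    PreprocessConfig,
    Split,
    load_manifest,
    preprocess_dataset,
    remove_outliers,
    rescale_to_byte_range,
    save_bundle,
    suppress_background,
    total_value_count,
)
from senonet.synthetic import SynthConfig, generate_dataset

from conftest import make_image


def percentile_clip_oracle(values, low, high):
    """Brute-force percentile clipping: sort, linear-interpolated index."""
    flat = np.sort(np.asarray(values, float).ravel())

    def q(frac):
        pos = frac * (len(flat) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        return flat[lo] + (pos - lo) * (flat[hi] - flat[lo])

    return np.clip(values, q(low), q(high))


class TestRemoveOutliers:
    def test_matches_sort_based_oracle(self, rng):
        for _ in range(5):
            px = rng.uniform(0, 1000, (25, 40))
            img = ChannelImage(px, Modality.SRS)
            got = remove_outliers(img, PreprocessConfig(low_percentile=0.01, high_percentile=0.99))
            np.testing.assert_allclose(got.pixels, percentile_clip_oracle(px, 0.01, 0.99))

    def test_ramp_image_clipped_at_both_ends(self):
        px = np.arange(100, dtype=float).reshape(10, 10)
        got = remove_outliers(ChannelImage(px, Modality.SRS),
                              PreprocessConfig(low_percentile=0.01, high_percentile=0.99))
        assert got.pixels.min() == pytest.approx(np.quantile(px, 0.01))
        assert got.pixels.max() == pytest.approx(np.quantile(px, 0.99))

    def test_hot_pixel_is_clipped(self, rng):
        px = rng.normal(100, 5, (20, 20))
        px[3, 7] = 1e6
        got = remove_outliers(ChannelImage(px, Modality.TPEF), PreprocessConfig())
        assert got.pixels.max() <= np.quantile(px, 0.99)

    def test_constant_image_unchanged(self):
        img = ChannelImage(np.zeros((8, 8)), Modality.SRS)
        assert np.array_equal(remove_outliers(img, PreprocessConfig()).pixels, np.zeros((8, 8)))


class TestSuppressBackground:
    def test_uniform_background_goes_to_zero(self):
        img = ChannelImage(np.full((10, 10), 37.0), Modality.TPEF)
        assert np.array_equal(suppress_background(img).pixels, np.zeros((10, 10)))

    def test_blob_retains_height_above_background(self):
        px = np.full((20, 20), 50.0)
        px[8:12, 8:12] = 50.0 + 80.0
        got = suppress_background(ChannelImage(px, Modality.SRS), PreprocessConfig())
        assert got.pixels[10, 10] == pytest.approx(80.0)
        assert got.pixels[0, 0] == pytest.approx(0.0)

    def test_never_negative(self, rng):
        px = rng.uniform(0, 50, (15, 15))
        got = suppress_background(ChannelImage(px, Modality.SRS), PreprocessConfig())
        assert (got.pixels >= 0).all()


class TestRescale:
    def test_affine_identity(self):
        img = ChannelImage(np.array([[0.0, 0.5, 1.0]]), Modality.SRS)
        np.testing.assert_allclose(rescale_to_byte_range(img).pixels, [[0.0, 127.5, 255.0]])

    def test_constant_maps_to_zero(self):
        img = ChannelImage(np.full((4, 4), 9.0), Modality.SRS)
        assert np.array_equal(rescale_to_byte_range(img).pixels, np.zeros((4, 4)))

    def test_full_range_property(self, rng):
        for _ in range(10):
            px = rng.normal(0, 100, (9, 11))
            out = rescale_to_byte_range(ChannelImage(px, Modality.SRS)).pixels
            assert out.min() == pytest.approx(0.0)
            assert out.max() == pytest.approx(255.0)


class TestPreprocessDataset:
    def test_output_in_byte_range_and_metadata_untouched(self, tiny_train_bundle):
        out = preprocess_dataset(tiny_train_bundle)
        assert len(out) == len(tiny_train_bundle)
        assert out.split is tiny_train_bundle.split
        assert out.labels() == tiny_train_bundle.labels()
        for img in out:
            arr = img.to_array()
            assert arr.shape == (64, 80, 3)
            assert arr.min() >= 0.0 and arr.max() <= 255.0

    def test_second_pass_changes_little_on_clean_data(self):
        # blob-free image: after one pass the data are already clipped and
        # rescaled, so a second pass moves values by less than one byte level
        px = np.linspace(0, 200, 300).reshape(15, 20)
        img = make_image({m: px for m in Modality}, h=15, w=20)
        once = preprocess_dataset(DatasetBundle([img], Split.TRAIN))
        twice = preprocess_dataset(once)
        diff = np.abs(once.images[0].to_array() - twice.images[0].to_array())
        assert diff.max() < 1.0


class TestManifests:
    def test_round_trip_counts_and_pixels(self, tmp_path, small_params):
        bundle, manifest = generate_dataset(SynthConfig(32, 40, 2, 1, seed=3), small_params,
                                            tmp_path)
        loaded = load_manifest(manifest)
        assert loaded.class_counts == {Label.SENESCENT: 2, Label.CONTROL: 1}
        assert loaded.split is Split.TRAIN
        np.testing.assert_allclose(loaded.images[0].to_array(), bundle.images[0].to_array(),
                                   rtol=1e-6)

    def test_empty_manifest(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path_srs,path_tpef,path_trans,label,split\n")
        assert len(load_manifest(p)) == 0

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path_srs,label,split\na,x.tif,Senescent,TRAIN\n")
        with pytest.raises(ManifestFormatError):
            load_manifest(p)

    def test_missing_file_names_offending_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path_srs,path_tpef,path_trans,label,split\n"
                     "row7,gone.tif,gone.tif,gone.tif,Senescent,TRAIN\n")
        with pytest.raises(IOError, match="row7"):
            load_manifest(p)

    def test_mixed_split_manifest_requires_split_argument(self, tmp_path):
        bundle = DatasetBundle([make_image(source_id="a"), make_image(source_id="b")],
                               Split.TRAIN)
        manifest = save_bundle(bundle, tmp_path)
        text = manifest.read_text().replace("a_srs", "a_srs").splitlines()
        text[2] = text[2].replace("TRAIN", "TEST")
        manifest.write_text("\n".join(text) + "\n")
        with pytest.raises(ManifestFormatError, match="mixes splits"):
            load_manifest(manifest)
        assert len(load_manifest(manifest, split=Split.TEST)) == 1


def test_dataset_value_count_full_campaign():
    # 224 fields of view at 250 x 300 x 3 hold 50.4 million scalar values
    assert total_value_count(224) == 50_400_000
    assert total_value_count(224) > 50_000_000
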