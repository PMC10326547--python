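"""Grad-CAM maps, upscaling, colocalization and overlays."""

import numpy as np
import pytest

from senonet.architectures import build_scratch_cnn, build_stub_backbone, build_tl_classifier
from senonet.data_io import ChannelImage, Label, Modality
from senonet.interpretability import (
    GradCAMMap,
    colocalization_score,
    ensemble_gradcam,
    gradcam_map,
    render_overlay,
    upscale_map,
)
from senonet.nn import Conv2D, Dense, Network, Sigmoid



def _linear_toy_model(n_maps=3, pick=1, h=8, w=10):
    """Target score = spatial mean of feature map ``pick``: Grad-CAM must
    reproduce that map (rectified) and ignore the others."""
    from senonet.architectures import LearnerModel

    conv = Conv2D(3, n_maps, 3, np.random.default_rng(0))
    gap_w = np.zeros((n_maps, 1), dtype=np.float32)
    gap_w[pick, 0] = 1.0

    class SpatialMean:
        trainable = False

        def forward(self, x, training=False):
            self._shape = x.shape
            return x.mean(axis=(1, 2))

        def backward(self, dy):
            n, hh, ww, c = self._shape
            return np.broadcast_to(dy[:, None, None, :], self._shape) / (hh * ww)

        def params(self):
            return {}

        def grads(self):
            return {}

        def penalty(self):
            return 0.0

        def add_penalty_grads(self):
            pass

    dense = Dense(n_maps, 1, rng=np.random.default_rng(1))
    dense.w = gap_w
    dense.b[...] = 0.0
    net = Network([conv, SpatialMean(), dense, Sigmoid()])
    return LearnerModel(net, kind="toy", last_conv_index=0)


class TestGradCAM:
    def test_linear_toy_model_recovers_selected_feature_map(self, rng):
        model = _linear_toy_model(pick=1)
        x = rng.uniform(0, 255, (8, 10, 3)).astype(np.float32)
        fmap = model.network.layers[0].forward(x[None])[0]
        cam = gradcam_map(model, x, Label.SENESCENT)
        expected = np.maximum(fmap[:, :, 1] / 3, 0.0)  # weight 1/3 on the picked map
        if expected.max() > 0:
            expected = expected / expected.max()
        np.testing.assert_allclose(cam.coarse, expected, atol=1e-5)

    def test_constant_output_model_gives_all_zero_map(self, rng):
        model = _linear_toy_model()
        dense = model.network.layers[2]
        dense.w[...] = 0.0  # score no longer depends on any feature map
        cam = gradcam_map(model, rng.uniform(0, 255, (8, 10, 3)))
        assert np.array_equal(cam.coarse, np.zeros_like(cam.coarse))

    def test_map_shape_equals_feature_map_shape(self, preprocessed_bundle):
        model = build_tl_classifier(build_stub_backbone(seed=0), seed=0)
        img = preprocessed_bundle.images[0]
        cam = gradcam_map(model, img)
        # last convolutional stage output (post-ReLU, pre-pool): 64/2 x 80/2
        assert cam.coarse.shape == (32, 40)

    def test_scratch_cnn_map_resolution(self, preprocessed_bundle):
        model = build_scratch_cnn((64, 80, 3), seed=0)
        cam = gradcam_map(model, preprocessed_bundle.images[0])
        assert cam.coarse.shape == (16, 20)  # two pools: 64/4 x 80/4
        assert cam.coarse.min() >= 0.0 and cam.coarse.max() <= 1.0

    def test_model_without_conv_stage_rejected(self):
        from senonet.architectures import LearnerModel

        net = Network([Dense(4, 1), Sigmoid()])
        model = LearnerModel(net, kind="dense", last_conv_index=-1)
        with pytest.raises(ValueError):
            gradcam_map(model, np.zeros((8, 10, 3)))


class TestUpscale:
    def test_constant_map_stays_constant(self):
        cam = GradCAMMap(coarse=np.full((6, 8), 0.4))
        up = upscale_map(cam, 250, 300)
        np.testing.assert_allclose(up.upscaled, 0.4, atol=1e-9)
        assert up.upscaled.shape == (250, 300)

    def test_left_right_gradient_monotone_along_rows(self):
        cam = GradCAMMap(coarse=np.array([[0.0, 1.0], [0.0, 1.0]]))
        up = upscale_map(cam, 20, 30)
        assert (np.diff(up.upscaled, axis=1) >= -1e-12).all()

    def test_identity_at_native_size(self, rng):
        coarse = rng.uniform(0, 1, (6, 8))
        up = upscale_map(GradCAMMap(coarse=coarse), 6, 8)
        np.testing.assert_array_equal(up.upscaled, coarse)

    def test_range_preserved(self, rng):
        coarse = rng.uniform(0, 1, (6, 8))
        up = upscale_map(GradCAMMap(coarse=coarse), 100, 120)
        assert up.upscaled.min() >= 0.0 and up.upscaled.max() <= 1.0


class TestColocalization:
    def test_map_equal_to_mask_scores_one(self, rng):
        mask = rng.random((20, 24)) > 0.7
        cam = GradCAMMap(coarse=mask.astype(float), upscaled=mask.astype(float))
        assert colocalization_score(cam, mask) == pytest.approx(1.0)

    def test_inverted_mask_scores_minus_one(self, rng):
        mask = rng.random((20, 24)) > 0.7
        cam = GradCAMMap(coarse=1.0 - mask, upscaled=1.0 - mask.astype(float))
        assert colocalization_score(cam, mask) == pytest.approx(-1.0)

    def test_independent_map_scores_near_zero(self, rng):
        scores = []
        mask = rng.random((30, 40)) > 0.5
        for _ in range(50):
            cam = GradCAMMap(coarse=rng.random((30, 40)))
            cam = GradCAMMap(coarse=cam.coarse, upscaled=cam.coarse)
            scores.append(colocalization_score(cam, mask))
        assert abs(np.mean(scores)) < 0.05

    def test_empty_and_full_masks_undefined(self):
        cam = GradCAMMap(coarse=np.random.rand(5, 5))
        assert np.isnan(colocalization_score(cam, np.zeros((5, 5), bool)))
        assert np.isnan(colocalization_score(cam, np.ones((5, 5), bool)))

    def test_dimension_mismatch_rejected(self):
        cam = GradCAMMap(coarse=np.zeros((5, 5)))
        with pytest.raises(ValueError):
            colocalization_score(cam, np.zeros((6, 6), bool))


class TestOverlay:
    def test_png_written_with_panel_dims(self, tmp_path, rng):
        from PIL import Image

        chan = ChannelImage(rng.uniform(0, 255, (20, 24)), Modality.SRS)
        cam = GradCAMMap(coarse=rng.uniform(0, 1, (5, 6)))
        cam = upscale_map(cam, 20, 24)
        path = render_overlay(cam, chan, tmp_path / "o.png")
        img = Image.open(path)
        assert img.size == (48, 20)  # side-by-side panel

    def test_deterministic_bytes(self, tmp_path, rng):
        chan = ChannelImage(rng.uniform(0, 255, (20, 24)), Modality.TPEF)
        cam = upscale_map(GradCAMMap(coarse=rng.uniform(0, 1, (5, 6))), 20, 24)
        p1 = render_overlay(cam, chan, tmp_path / "a.png")
        p2 = render_overlay(cam, chan, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_map_overlay_equals_plain_channel(self, tmp_path, rng):
        from PIL import Image

        chan = ChannelImage(rng.uniform(0, 255, (16, 20)), Modality.SRS)
        cam = GradCAMMap(coarse=np.zeros((16, 20)), upscaled=np.zeros((16, 20)))
        path = render_overlay(cam, chan, tmp_path / "z.png")
        arr = np.asarray(Image.open(path), dtype=float)
        left, right = arr[:, :20], arr[:, 20:]
        np.testing.assert_array_equal(left, right)


class TestEnsembleGradCAM:
    def test_average_and_per_learner_modes(self, preprocessed_bundle):
        learners = [build_tl_classifier(build_stub_backbone(seed=s), seed=s) for s in (1, 2)]
        img = preprocessed_bundle.images[0]
        mean_map = ensemble_gradcam(learners, img)
        per = ensemble_gradcam(learners, img, per_learner=True)
        assert mean_map.upscaled.shape == (img.height, img.width)
        assert len(per) == 2
        stacked = np.mean([m.upscaled for m in per], axis=0)
        np.testing.assert_allclose(mean_map.upscaled, stacked, atol=1e-12)
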