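"""Loss closed forms, validation splitting, early stopping, stage mechanics."""

import numpy as np
import pytest

from senonet.architectures import TLHeadSpec, build_stub_backbone, build_tl_classifier
from senonet.data_io import DatasetBundle, Label, Modality, Split
from senonet.training import (
    Stage,
    TrainingConfig,
    binary_cross_entropy,
    early_stop_check,
    split_validation,
    train_stage,
)

from conftest import make_image


class TestBinaryCrossEntropy:
    def test_perfect_prediction_tends_to_zero(self):
        assert binary_cross_entropy([1.0], [1.0 - 1e-9]) == pytest.approx(0.0, abs=1e-6)
        assert binary_cross_entropy([0.0], [1e-9]) == pytest.approx(0.0, abs=1e-6)

    def test_maximally_uncertain_batch_is_log_two(self):
        assert binary_cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-9)

    def test_hand_evaluated_batch(self):
        # -(1/2) [log 0.8 + log 0.7]
        expected = -(np.log(0.8) + np.log(0.7)) / 2
        assert binary_cross_entropy([1, 0], [0.8, 0.3]) == pytest.approx(expected, abs=1e-12)

    def test_wrong_confident_is_worse_than_wrong_mild(self):
        assert binary_cross_entropy([1], [0.25]) > binary_cross_entropy([1], [0.75])

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            binary_cross_entropy([1], [1.5])
        with pytest.raises(ValueError):
            binary_cross_entropy([], [])

    def test_agrees_with_sklearn_log_loss(self, rng):
        from sklearn.metrics import log_loss

        y = rng.integers(0, 2, 30)
        p = rng.uniform(0.01, 0.99, 30)
        assert binary_cross_entropy(y, p) == pytest.approx(log_loss(y, p), abs=1e-9)


class TestSplitValidation:
    @staticmethod
    def _bundle(n_sen=95, n_ctl=75):
        imgs = [make_image(label=Label.SENESCENT, source_id=f"s{k}", h=4, w=4)
                for k in range(n_sen)]
        imgs += [make_image(label=Label.CONTROL, source_id=f"c{k}", h=4, w=4)
                 for k in range(n_ctl)]
        return DatasetBundle(imgs, Split.TRAIN)

    def test_reference_counts_170_to_127_plus_43(self):
        tr, val = split_validation(self._bundle(), n_val=43, seed=0)
        assert (len(tr), len(val)) == (127, 43)
        assert val.split is Split.VALIDATION

    def test_exact_per_class_counts(self):
        tr, val = split_validation(self._bundle(), seed=0, exact_counts=(24, 19))
        assert val.class_counts == {Label.SENESCENT: 24, Label.CONTROL: 19}

    def test_no_overlap_and_seed_reproducible(self):
        b = self._bundle(20, 20)
        tr1, val1 = split_validation(b, n_val=10, seed=7)
        tr2, val2 = split_validation(b, n_val=10, seed=7)
        assert [i.source_id for i in val1.images] == [i.source_id for i in val2.images]
        assert set(i.source_id for i in tr1.images).isdisjoint(
            i.source_id for i in val1.images)

    def test_zero_validation(self):
        b = self._bundle(5, 5)
        tr, val = split_validation(b, n_val=0, seed=0)
        assert len(tr) == 10 and len(val) == 0

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            split_validation(self._bundle(3, 3), n_val=6)


class TestEarlyStopRule:
    CFG = TrainingConfig(patience_epochs=20, min_delta=0.005)

    def test_strict_improvement_never_stops(self):
        losses = list(np.linspace(1.0, 0.0, 30))
        assert not early_stop_check(losses, self.CFG)

    def test_constant_loss_stops_at_patience_plus_one(self):
        assert not early_stop_check([1.0] * 20, self.CFG)
        assert early_stop_check([1.0] * 21, self.CFG)

    def test_sub_min_delta_drift_counts_as_no_improvement(self):
        # 0.004/epoch improvements never clear the 0.005 threshold
        losses = [1.0 - 0.004 * k for k in range(21)]
        assert early_stop_check(losses, self.CFG)

    def test_exactly_min_delta_resets_patience(self):
        losses = [1.0 - 0.005 * k for k in range(40)]
        assert not early_stop_check(losses, self.CFG)

    def test_late_improvement_resets(self):
        losses = [1.0] * 15 + [0.5] + [0.5] * 10
        assert not early_stop_check(losses, self.CFG)


def _feature_bundle(rng, n=24, h=16, w=20, separation=120.0):
    """Linearly separable two-class bundle: class-dependent brightness."""
    imgs = []
    for k in range(n):
        sen = k % 2 == 0
        base = 30.0 + (separation if sen else 0.0)
        planes = {m: np.clip(rng.normal(base, 10.0, (h, w)), 0, 255) for m in Modality}
        imgs.append(make_image(planes, label=Label.SENESCENT if sen else Label.CONTROL,
                               source_id=f"i{k}", h=h, w=w))
    return DatasetBundle(imgs, Split.TRAIN)


class TestTrainStage:
    def test_head_stage_drives_loss_below_tenth_on_separable_features(self):
        # penalty-free head, patience widened to the epoch cap so the check
        # isolates the optimizer's ability to fit (the stopping rule has its
        # own tests above)
        train = _feature_bundle(np.random.default_rng(12), n=120)
        val = _feature_bundle(np.random.default_rng(13), n=20)
        model = build_tl_classifier(build_stub_backbone(seed=1), TLHeadSpec(0.0, 4, 0.0, 0.0),
                                    seed=1)
        cfg = TrainingConfig(seed=1, batch_size=5, patience_epochs=200)
        hist = train_stage(model, (train, val), cfg, Stage.HEAD)
        assert hist.stop_epoch <= cfg.max_epochs
        x, y = train.to_arrays()
        probs = model.predict_proba(x)
        assert binary_cross_entropy(y, probs) < 0.1
        assert ((probs >= 0.5).astype(int) == y).mean() >= 0.9

    def test_finetune_moves_backbone_weights(self, rng):
        train = _feature_bundle(rng, n=20)
        val = _feature_bundle(rng, n=8)
        model = build_tl_classifier(build_stub_backbone(seed=2), TLHeadSpec(0.0, 4, 0.01, 0.01),
                                    seed=2)
        cfg = TrainingConfig(seed=2, batch_size=10, max_epochs=24)
        train_stage(model, (train, val), cfg, Stage.HEAD)
        before = [w.copy() for w in model.network.get_weights()]
        train_stage(model, (train, val), cfg, Stage.FINETUNE)
        after = model.network.get_weights()
        nb_arrays = sum(len(l.params()) for l in model.network.layers[:model.backbone_n_layers])
        assert any(not np.array_equal(a, b)
                   for a, b in zip(after[:nb_arrays], before[:nb_arrays]))

    def test_empty_training_data_rejected(self):
        model = build_tl_classifier(build_stub_backbone(seed=0), seed=0)
        with pytest.raises(ValueError):
            train_stage(model, (DatasetBundle([], Split.TRAIN),
                                DatasetBundle([], Split.VALIDATION)),
                        TrainingConfig(), Stage.HEAD)

    def test_deterministic_given_seed(self, rng):
        train = _feature_bundle(rng, n=16)
        val = _feature_bundle(rng, n=8)
        hists = []
        finals = []
        for _ in range(2):
            model = build_tl_classifier(build_stub_backbone(seed=4),
                                        TLHeadSpec(0.0, 4, 0.01, 0.01), seed=4)
            cfg = TrainingConfig(seed=4, batch_size=8, max_epochs=30)
            hists.append(train_stage(model, (train, val), cfg, Stage.HEAD))
            finals.append(model.network.get_weights())
        assert hists[0].val_loss == hists[1].val_loss
        for a, b in zip(*finals):
            np.testing.assert_array_equal(a, b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(lr_finetune=1e-3, lr_head=5e-4)  # finetune must be smaller
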