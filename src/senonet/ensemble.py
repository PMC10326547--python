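"""Ensemble learning by unweighted probability averaging.

Each of n weak learners l_i (a backbone + dense head classifier) predicts a
probability p_ij for class c_j; the ensemble's decision is

    predicted class = argmax_j (1/n) * sum_i p_ij

i.e. the per-class probabilities are equally averaged — a non-weighted
voting scheme — and the larger-mean class wins. With sigmoid learners the
two-class vector is (p, 1-p), so the argmax is equivalent to thresholding
the mean senescence probability at 0.5 (an exact tie resolves to SENESCENT:
missing a senescent cell is the costlier error).

Diversity between weak learners comes from each learner training on its own
independently augmented dataset, its own validation split, its own
initialization seed. FROZEN mode trains heads only (off-the-shelf
backbones); FULLY_TRAINED then fine-tunes backbone weights too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from ._rng import mix_seed
from .architectures import BackboneHandle, LearnerModel, TLHeadSpec, build_tl_classifier, get_backbone
from .augmentation import AugmentationConfig, augment_dataset
from .data_io import DatasetBundle, Label
from .training import TrainingConfig, TrainingHistory, split_validation, train_learner


class EnsembleMode(str, Enum):
    FROZEN = "FROZEN"
    FULLY_TRAINED = "FULLY_TRAINED"


@dataclass
class EnsemblePrediction:
    """Per-learner probabilities, their unweighted mean, and the decision."""

    learner_probs: np.ndarray  # senescence probability per learner
    mean_prob: float
    predicted: Label
    source_id: str = ""


@dataclass
class EnsembleModel:
    learners: list[LearnerModel]
    mode: EnsembleMode
    learner_seeds: list[int] = field(default_factory=list)
    histories: list[list[TrainingHistory]] = field(default_factory=list)

    @property
    def n_learners(self) -> int:
        return len(self.learners)

    @property
    def trained(self) -> bool:
        return all(m.trained for m in self.learners)


def average_probabilities(probs: Sequence[float]) -> float:
    """Unweighted arithmetic mean of learner probabilities (order-invariant)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("cannot average an empty probability list")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(probs.mean())


def predict_class(mean_prob: float, threshold: float = 0.5) -> Label:
    """SENESCENT iff the mean probability reaches the threshold.

    Exactly 0.5 resolves to SENESCENT (documented tie rule). Equivalent to
    argmax over the (p, 1-p) two-class vector away from the tie.
    """
    if not 0.0 <= mean_prob <= 1.0:
        raise ValueError("mean_prob must lie in [0, 1]")
    return Label.SENESCENT if mean_prob >= threshold else Label.CONTROL


def _resolve_backbone(spec: BackboneHandle | str, seed: int) -> BackboneHandle:
    if isinstance(spec, BackboneHandle):
        return spec
    return get_backbone(spec, seed=seed)


def train_ensemble(base: DatasetBundle, backbones: Sequence[BackboneHandle | str],
                   cfg: TrainingConfig, mode: EnsembleMode = EnsembleMode.FULLY_TRAINED,
                   aug_cfg: AugmentationConfig | None = None,
                   n_val: int | None = None,
                   head: TLHeadSpec | None = None) -> EnsembleModel:
    """Train one TL classifier per backbone and wrap them as an ensemble.

    Per learner i: a sub-seed is mixed from ``cfg.seed`` and i; a fresh
    validation split is drawn from ``base``; the remaining training images
    are augmented with that learner's own transforms; the head is trained
    (HEAD stage), and in FULLY_TRAINED mode the whole network is then
    fine-tuned. Validation images are split off *before* augmentation so no
    transformed copy of a validation image can reach the training set.
    """
    if not backbones:
        raise ValueError("need at least one backbone")
    aug_cfg = aug_cfg or AugmentationConfig()
    head = head or TLHeadSpec(l1=cfg.l1, l2=cfg.l2)
    if n_val is None:
        n_val = max(1, round(len(base) * 43 / 170))
    learners, seeds, histories = [], [], []
    for i, spec in enumerate(backbones):
        sub_seed = mix_seed(cfg.seed, i)
        backbone = _resolve_backbone(spec, seed=sub_seed)
        model = build_tl_classifier(backbone, head=head, seed=sub_seed, frozen=True)
        tr, val = split_validation(base, n_val=n_val, seed=sub_seed)
        tr_aug = augment_dataset(tr, AugmentationConfig(
            copies_per_image=aug_cfg.copies_per_image,
            rotation_range_deg=aug_cfg.rotation_range_deg,
            translation_fraction=aug_cfg.translation_fraction,
            flip_horizontal=aug_cfg.flip_horizontal,
            flip_vertical=aug_cfg.flip_vertical,
            interpolation_order=aug_cfg.interpolation_order,
            seed=sub_seed,
        ))
        lcfg = TrainingConfig(**{**cfg.__dict__, "seed": sub_seed})
        hists = train_learner(model, tr_aug, val, lcfg,
                              fine_tune=(mode is EnsembleMode.FULLY_TRAINED))
        learners.append(model)
        seeds.append(sub_seed)
        histories.append(hists)
    return EnsembleModel(learners, mode, seeds, histories)


def predict_ensemble(model: EnsembleModel, ds: DatasetBundle) -> list[EnsemblePrediction]:
    """Per-image learner probabilities, their mean, and the argmax class.

    Inference is deterministic (dropout inactive); repeated calls give
    identical outputs.
    """
    if not model.trained:
        raise RuntimeError("ensemble has untrained learners")
    x, _ = ds.to_arrays()
    per_learner = np.stack([m.predict_proba(x) for m in model.learners])  # (L, N)
    out = []
    for j, img in enumerate(ds.images):
        mean = average_probabilities(per_learner[:, j])
        out.append(EnsemblePrediction(per_learner[:, j].copy(), mean, predict_class(mean),
                                      source_id=img.source_id))
    return out


def ensemble_probabilities(model: EnsembleModel, ds: DatasetBundle) -> np.ndarray:
    """Mean senescence probability per image, as a vector."""
    return np.array([p.mean_prob for p in predict_ensemble(model, ds)])
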