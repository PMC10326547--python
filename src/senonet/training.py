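"""Training protocol: binary cross-entropy, two-stage optimization, early stop.

Every classifier minimizes the binary cross-entropy

    L = -(1/n) * sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]

where y_i is the ground-truth label (senescent = 1) and p_i the predicted
senescence probability, plus L1/L2 penalties (coefficient 0.01) on the
4-neuron dense layer. Transfer-learning classifiers train in two stages:
HEAD, with the backbone frozen and the dense layers learning at 5e-4; then
FINETUNE, where the backbone parameters also move, at the much smaller rate
2e-5 to avoid catastrophic overfitting on a small dataset (the head keeps
its own rate by default). Both stages stop early when the validation
cross-entropy fails to improve by at least 0.005 over 20 consecutive
epochs, and the best-validation weights are restored.

The optimizer is Adam (the paper-era Keras default for fine-tuning work).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._rng import rng_from
from .architectures import LearnerModel
from .data_io import DatasetBundle, Label, Split
from .nn import Adam, ChannelScale, GlobalMaxPool2D, Network

EPS_CLIP = 1e-7


class Stage(str, Enum):
    HEAD = "HEAD"
    FINETUNE = "FINETUNE"


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 20
    max_epochs: int = 200
    lr_head: float = 5e-4
    lr_finetune: float = 2e-5
    patience_epochs: int = 20
    min_delta: float = 0.005
    l1: float = 0.01
    l2: float = 0.01
    seed: int = 0
    restore_best: bool = True
    #: if True the head also drops to lr_finetune during the FINETUNE stage
    unify_finetune_lr: bool = False
    #: optional epoch cap for the FINETUNE stage only (defaults to
    #: max_epochs); at the 2e-5 backbone rate the stage moves weights very
    #: little per epoch, so reduced-size protocols cap it for tractability
    max_epochs_finetune: int | None = None

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience_epochs) <= 0:
            raise ValueError("batch_size, max_epochs and patience_epochs must be positive")
        if not 0 < self.lr_finetune < self.lr_head:
            raise ValueError("need 0 < lr_finetune < lr_head")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0
    stage: Stage = Stage.HEAD


def binary_cross_entropy(y: np.ndarray, p: np.ndarray, eps: float = EPS_CLIP) -> float:
    """Mean binary cross-entropy of predicted senescence probabilities.

    Probabilities are clipped to [eps, 1-eps] before the logarithm.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("y and p must be equal-length, non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def split_validation(train: DatasetBundle, n_val: int = 43, seed: int = 0,
                     stratified: bool = True,
                     exact_counts: tuple[int, int] | None = None) -> tuple[DatasetBundle, DatasetBundle]:
    """Randomly partition a training bundle into (train', validation).

    By default the split is stratified by class with ``n_val`` total images
    (the reference protocol extracts 43 validation images from 170).
    ``exact_counts`` = (n_senescent, n_control) forces exact per-class
    validation counts — e.g. (24, 19) — since a proportional split does not
    always land on the published numbers. Seed-reproducible; no image
    appears in both parts.
    """
    if exact_counts is not None:
        n_val = sum(exact_counts)
    if not 0 <= n_val < len(train):
        raise ValueError(f"n_val must lie in [0, {len(train)})")
    rng = rng_from(seed, 404)
    if n_val == 0:
        return DatasetBundle(list(train.images), train.split), DatasetBundle([], Split.VALIDATION)

    idx_sen = [i for i, img in enumerate(train.images) if img.label is Label.SENESCENT]
    idx_ctl = [i for i in range(len(train)) if i not in set(idx_sen)]
    if exact_counts is not None:
        k_sen, k_ctl = exact_counts
    elif stratified and idx_sen and idx_ctl:
        k_sen = int(round(n_val * len(idx_sen) / len(train)))
        k_sen = min(max(k_sen, 0), len(idx_sen))
        k_ctl = n_val - k_sen
    else:
        all_ix = rng.permutation(len(train))[:n_val]
        val_set = set(int(i) for i in all_ix)
        tr = [img for i, img in enumerate(train.images) if i not in val_set]
        va = [img for i, img in enumerate(train.images) if i in val_set]
        return DatasetBundle(tr, train.split), DatasetBundle(va, Split.VALIDATION)
    if k_sen > len(idx_sen) or k_ctl > len(idx_ctl):
        raise ValueError("requested validation counts exceed available class counts")
    val_set = set(int(i) for i in rng.permutation(idx_sen)[:k_sen])
    val_set |= set(int(i) for i in rng.permutation(idx_ctl)[:k_ctl])
    tr = [img for i, img in enumerate(train.images) if i not in val_set]
    va = [img for i, img in enumerate(train.images) if i in val_set]
    return DatasetBundle(tr, train.split), DatasetBundle(va, Split.VALIDATION)


def early_stop_check(val_losses: list[float], cfg: TrainingConfig) -> bool:
    """True iff training should halt after the recorded validation losses.

    The rule: an epoch counts as an improvement only when it beats the best
    validation loss seen before it by at least ``min_delta``. If none of the
    last ``patience_epochs`` epochs did so, stop. A slow drift of less than
    ``min_delta`` per epoch therefore does not keep training alive, and a
    constant validation loss halts at epoch ``patience_epochs + 1``.
    """
    if not val_losses:
        raise ValueError("need at least one recorded validation loss")
    wait = 0
    best = float(val_losses[0])
    for v in val_losses[1:]:
        if v <= best - cfg.min_delta:
            wait = 0
        else:
            wait += 1
        best = min(best, float(v))
        if wait >= cfg.patience_epochs:
            return True
    return wait >= cfg.patience_epochs


# ---------------------------------------------------------------------------
# the optimization loop


def _bundle_to_xy(bundle: DatasetBundle) -> tuple[np.ndarray, np.ndarray]:
    x, y = bundle.to_arrays()
    return x.astype(np.float32), y.astype(np.float32)


def _epoch_pass(net: Network, x: np.ndarray, y: np.ndarray, opt: Adam, batch_size: int,
                rng: np.random.Generator, start_layer: int = 0) -> float:
    """One optimization epoch; returns the mean training loss.

    ``start_layer`` > 0 means ``x`` is already the output of the layers
    below it (cached frozen-backbone features) and backprop stops there.
    """
    n = len(x)
    order = rng.permutation(n)
    total = 0.0
    sig_ix = len(net.layers) - 1  # final Sigmoid
    for lo in range(0, n, batch_size):
        ix = order[lo:lo + batch_size]
        xb, yb = x[ix], y[ix]
        p = net.forward_range(xb, start=start_layer, training=True)[:, 0]
        pc = np.clip(p, EPS_CLIP, 1 - EPS_CLIP)
        loss = float(-np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))) + net.penalty()
        total += loss * len(ix)
        # gradient of mean BCE at the logit (sigmoid folded in, numerically stable)
        grad = ((p - yb) / len(ix))[:, None].astype(np.float32)
        net.backward_from(grad, from_layer=sig_ix - 1, to_layer=start_layer)
        net.add_penalty_grads()
        opt.step()
    return total / n


def _eval_loss(net: Network, x: np.ndarray, y: np.ndarray, start_layer: int = 0,
               batch_size: int = 256) -> float:
    ps = [net.forward_range(x[i:i + batch_size], start=start_layer)[:, 0]
          for i in range(0, len(x), batch_size)]
    return binary_cross_entropy(y, np.concatenate(ps)) + net.penalty()


def train_stage(model: LearnerModel, data: tuple[DatasetBundle, DatasetBundle],
                cfg: TrainingConfig, stage: Stage = Stage.HEAD) -> TrainingHistory:
    """Run one training stage (HEAD or FINETUNE) with early stopping.

    HEAD freezes the backbone (its outputs are computed once and cached, so
    only the dense head runs per epoch); FINETUNE unfreezes everything, with
    ``lr_finetune`` on backbone parameters and ``lr_head`` on the head
    (unless ``unify_finetune_lr``). The model is left at the
    best-validation-loss weights when ``restore_best`` is set.
    """
    train_bundle, val_bundle = data
    if len(train_bundle) == 0:
        raise ValueError("training bundle is empty")
    net = model.network
    nb = model.backbone_n_layers
    xt, yt = _bundle_to_xy(train_bundle)
    xt = model.preprocess_fn(xt).astype(np.float32)
    has_val = len(val_bundle) > 0
    if has_val:
        xv, yv = _bundle_to_xy(val_bundle)
        xv = model.preprocess_fn(xv).astype(np.float32)

    if stage is Stage.HEAD and nb > 0:
        net.frozen = set(range(nb))
        # cache activations once through the frozen backbone and through any
        # leading deterministic parameter-free head layers (global pooling):
        # nothing below the first trainable layer changes during this stage
        boundary = nb
        while boundary < len(net.layers) - 1 and isinstance(
                net.layers[boundary], (GlobalMaxPool2D, ChannelScale)):
            boundary += 1
        xt = net.forward_range(xt, 0, boundary)
        if has_val:
            xv = net.forward_range(xv, 0, boundary)
        start_layer = boundary
        groups = [(net.trainable_entries(slice(nb, None)), cfg.lr_head)]
    elif stage is Stage.HEAD:
        start_layer = 0
        groups = [(net.trainable_entries(), cfg.lr_head)]
    else:
        net.frozen = set()
        start_layer = 0
        head_lr = cfg.lr_finetune if cfg.unify_finetune_lr else cfg.lr_head
        groups = [(net.trainable_entries(slice(0, nb)), cfg.lr_finetune),
                  (net.trainable_entries(slice(nb, None)), head_lr)]

    opt = Adam(groups)
    rng = rng_from(cfg.seed, 505, 0 if stage is Stage.HEAD else 1)
    net.seed_dropout(rng.integers(0, 2**31 - 1))
    hist = TrainingHistory(stage=stage)
    best = np.inf
    best_weights = net.get_weights() if cfg.restore_best else None
    epoch_cap = cfg.max_epochs
    if stage is Stage.FINETUNE and cfg.max_epochs_finetune is not None:
        epoch_cap = min(epoch_cap, cfg.max_epochs_finetune)
    for epoch in range(1, epoch_cap + 1):
        tr_loss = _epoch_pass(net, xt, yt, opt, cfg.batch_size, rng, start_layer)
        hist.train_loss.append(tr_loss)
        monitor = _eval_loss(net, xv, yv, start_layer) if has_val else tr_loss
        hist.val_loss.append(monitor)
        if monitor < best:
            best = monitor
            hist.best_epoch = epoch
            if cfg.restore_best:
                best_weights = net.get_weights()
        hist.stop_epoch = epoch
        if early_stop_check(hist.val_loss, cfg):
            break
    if cfg.restore_best and best_weights is not None:
        net.set_weights(best_weights)
    model.trained = True
    return hist


def train_learner(model: LearnerModel, train_bundle: DatasetBundle, val_bundle: DatasetBundle,
                  cfg: TrainingConfig, fine_tune: bool = False) -> list[TrainingHistory]:
    """HEAD stage, then optionally FINETUNE, on the same data."""
    hists = [train_stage(model, (train_bundle, val_bundle), cfg, Stage.HEAD)]
    if fine_tune:
        hists.append(train_stage(model, (train_bundle, val_bundle), cfg, Stage.FINETUNE))
    return hists
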