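# Methods

## The classification problem

Therapy-induced senescent (TIS) cancer cells differ from proliferating
controls in two label-free optical signatures: lipid droplets aggregate
(bright, numerous blobs in the SRS channel at the 2850 cm⁻¹ CH₂ stretch)
and the mitochondrial network collapses from a diffuse cytoplasmic web into
clustered bright foci (TPEF of NADH/FAD). The transmission channel carries
morphology but little class contrast. The classifiers here map one
250 × 300 × 3 field of view to the probability of the senescent class;
senescent is the positive class throughout.

## Preprocessing

Each channel is clipped to its 1st–99th percentile band (detector spikes),
has its 10th-percentile intensity subtracted as the background estimate
(clamped at zero), and is affinely rescaled so min → 0 and max → 255. The
percentile choices and the quantile background estimator are this package's
defaults — robust, monotone and testable — and are configurable
(`PreprocessConfig`). Normalization is per image and per channel; there is
no global reference, so absolute intensities are not comparable across
images after preprocessing. Values stay floating point: quantizing to bytes
before backbone-specific scaling would double-round.

## Synthetic phenotypes

The generator renders cells as smoothed random polygons (radial cosine
perturbation of a circle) containing a darker nuclear disk. Lipid droplets
and mitochondrial foci are Gaussian-profile disks; droplets scatter
uniformly in the cytoplasm, foci cluster around a perinuclear anchor
(σ = 0.18 cell radius). Additive Gaussian noise (σ = 5 intensity units) is
clamped at zero. At the 0.35 µm pixel pitch, senescent droplets are 1.8–3.5
px in radius (≈ 1.3–2.5 µm diameter), 20–30 per cell at intensity 150–220;
controls have 1–4 droplets per cell at 0.8–1.6 px and 50–90. Senescent TPEF
adds 10–16 foci per cell at 140–200 over the shared diffuse level of 70;
controls have none. An `effect_size` knob in [0, 1] linearly interpolates
every senescent parameter from the control baseline (0: both classes are
drawn from the same distribution, by construction) to the full contrast
(1). Every image retains the union of its implanted blob supports (at half
maximum) as a ground-truth marker mask — for both classes, so
attention-colocalization can be compared across classes.

What the generator does **not** emulate: real HepG2 texture statistics,
channel cross-talk, uneven illumination, focus drift, cell-cycle
heterogeneity, or any SRS/TPEF physics. Passing the desk-scale experiments
therefore demonstrates that the pipeline's mechanics (preprocessing,
augmentation, two-stage optimization, ensembling, evaluation,
interpretability) recover a planted, well-separated signal without leakage
— not that the models would reach any particular accuracy on real
microscopy data.

## Augmentation

Rotations are uniform over ±180° (cell orientation is physically
arbitrary), translations are integer shifts of at most 10 % of each
dimension, and horizontal/vertical flips toss fair coins; all three
channels (and the marker mask, nearest-neighbor) receive the identical
transform, with exact zeros where the support leaves the frame. Rotation
interpolation is bilinear with a clamp to [0, 255]; nearest-neighbor is
available for exactness checks. Cropping, stretching, zoom, shear and
intensity jitter are deliberately excluded — they would distort the spatial
arrangement and apparent concentration of the organelles that carry the
signal. The default 11 copies per image takes 170 training images to 2040.
Per-learner datasets share the originals but draw each learner's transforms
from a sub-seed mixed from the base seed and the learner index
(multiplicative integer hash, stated in `senonet._rng`), which is what
diversifies the ensemble's weak learners.

## Models and training

All models end in a single sigmoid: the two-class probability vector is
(p, 1 − p), so the argmax-of-mean ensemble rule and a 0.5 threshold on the
mean senescence probability coincide (tie → senescent; missing a senescent
cell is the costlier error).

Training minimizes the mean binary cross-entropy with probabilities clipped
at ε = 10⁻⁷, plus L1 and L2 penalties (0.01 each) on the 4-neuron dense
layer's kernel. The optimizer is Adam (the community default for this kind
of fine-tuning work; the learning rates are the protocol's: 5 × 10⁻⁴ for
the dense head, 2 × 10⁻⁵ for backbone fine-tuning, and the head keeps its
own rate during fine-tuning unless `unify_finetune_lr` is set). Batches of
20, at most 200 epochs. Early stopping: an epoch counts as an improvement
only when it beats the best validation loss seen so far by at least 0.005;
if none of the last 20 epochs did, training halts and the best-validation
weights are restored (restoration is this package's choice; reporting the
degraded final epoch would be worse). Under this reading a constant
validation loss halts at epoch 21 and a sub-threshold drift (e.g.
0.004/epoch) does not keep training alive. Validation splits are stratified
by class (43 from 170 by default, mirroring the reference protocol); an
exact-count mode exists because the published 24/19 split is not exactly
proportional. The validation split is drawn *before* augmentation so no
transformed copy of a validation image reaches the training set.

Each learner's training is fully determined by (seed, data, config) on a
fixed platform; cross-platform bit-exactness is not claimed.

### The NumPy engine

No deep-learning framework is a dependency: layers (stride-1 "same"
convolution via im2col, 2 × 2 max pooling, global max pooling, dense,
ReLU/sigmoid, inverted dropout), Adam, and the backward passes are
implemented in NumPy and verified against finite differences in the test
suite. Two numerical conventions: max-pool gradients are split equally
among tied maxima, and the engine runs float32 with float64 reductions
where it matters (loss, metrics).

Two initialization choices stabilize small heads: dense layers feeding a
ReLU get a +0.1 bias (dead-unit guard) and output layers start at zero
weights, so every classifier begins at p = 0.5 instead of spending epochs
undoing a confident random logit.

### The stub backbone

The STUB backbone is a two-stage conv/pool feature extractor
(He-initialized from its seed, 8 then 16 channels) with a fixed per-channel
output gain calibrated at build time on a noise batch so feature maps are
O(1) — the role batch statistics play inside real pretrained backbones. Its
feature vector for the hybrid path concatenates global mean and max pooling
(32 values). It is a *structural* stand-in: it satisfies the backbone
interface deterministically and without downloads, but its random-weight
features are far weaker than ImageNet features.

### Desk-scale protocol

The self-contained reference experiment (`desk_scale_config`) uses 64 × 80
images (the generator's small-size mode), a 160-image training pool
(95 senescent / 65 control) with a 40-image validation split, a 40-image
test set (22/18), 9 augmented copies per training image, three STUB
learners, and the two-stage protocol with the fine-tuning stage capped at
21 epochs — the floor the patience-20 rule allows, and past the point where
the 2 × 10⁻⁵ backbone rate still moves anything materially. The TL head's
dropout is 0 in this protocol: a rate of 0.8 is sized for the 512–2048
feature channels of real backbones, where ~100–400 features survive each
step; on a 16-channel stub it leaves ~3, and head training degenerates into
noise. The 0.8 default stands wherever a real backbone is used. Three
repeat seeds (the full protocol uses nine; three keeps the study inside a
desk-scale compute budget) are summarized as mean ± SD, with max AUC across
runs.

## Hybrid TL/ML path

Off-the-shelf (frozen) backbone features per image → PCA fitted on training
rows only, keeping 95 % variance (configurable, or a fixed component
count) → polynomial-kernel SVM with degree ∈ {2, 3} and C ∈ {0.1, 1, 10}
chosen by stratified 5-fold cross-validation on accuracy (the fold count
shrinks if a class has fewer members than folds). Each backbone votes a
label; the majority wins (ties — possible only for even ensembles — go to
senescent). The vote count serves as an ordinal score: thresholding "at
least t of n learners" at t = 0 … n+1 traces this classifier's ROC. PCA and
SVM objects fitted on training data are *applied* to held-out rows, never
refitted — the leakage guard of this path.

## Evaluation

Accuracy, precision, recall and F1 from the four-cell confusion counts;
zero-denominator cells are NaN, not 0, so summaries cannot be silently
inflated. The ROC sweeps the unique predicted probabilities (∪ +∞) as
thresholds with "senescent iff p ≥ t", and AUC is trapezoidal — equal to
the pairwise concordance statistic, which the tests verify exhaustively.
Multi-run summaries report the population SD across runs (the convention
that reproduces "mean 0.9, SD 0.1" for runs {0.8, 1.0}) and the maximum AUC
across runs. Channel-subset ablations zero-fill the dropped channel(s),
keeping the architecture fixed — the least invasive mechanism.

## Grad-CAM

For one image, the class score is the pre-sigmoid logit (negated for the
control class). The gradient of that score with respect to the last
convolutional stage's feature maps is spatially averaged into one weight
per channel; the map is ReLU(Σ weight·map), normalized to [0, 1] per map
(an all-zero map stays zero), then bilinearly upscaled to image size. For
the stub TL classifier the "last convolutional stage" is the post-ReLU
output of its final convolution (pre-pooling), giving a 32 × 40 coarse map
at 64 × 80 input; deep backbones at 250 × 300 would give the familiar
single-digit map sizes. Ensemble maps default to the mean of per-learner
upscaled maps, with a per-learner mode by flag. Colocalization against a
marker mask is the point-biserial correlation between map values and mask
membership (NaN for empty/full masks or constant maps). Because the head
uses global max pooling, gradients reach only argmax spatial positions, so
maps are sparser than with average pooling — colocalization scores are
expected to be modest but class-ordered.

## Numerical and degenerate-input conventions

Constant channels: outlier clipping and background subtraction leave them
unchanged (zero), byte-rescaling maps them to zero. Constant probability
vectors give AUC 0.5 by the tie rule. Empty manifests load as empty bundles
with a warning. PCA on rank-deficient input keeps what exists. An exact
ensemble tie at 0.5 predicts senescent.

## Known limitations

- The stub backbone's random features make desk-scale absolute accuracies
  incommensurable with published full-scale numbers; only the *relations*
  (ensemble ≥ individual learners, full contrast ≫ zero contrast,
  senescent colocalization > control) are meaningful at this scale.
- The NumPy engine is single-threaded and CPU-bound; it is sized for
  desk-scale studies, not for training on full 250 × 300 datasets.
- Per-image normalization discards absolute intensity, which itself may
  carry class signal in real data.
- Grad-CAM through a global-max-pooling head attributes through argmax
  paths only; Grad-CAM++-style refinements are out of scope.
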