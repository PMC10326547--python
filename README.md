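# senonet

Classification of therapy-induced senescent (TIS) versus proliferating
cancer cells from three-channel, label-free nonlinear-optical microscopy
images.

Cancer cells pushed into senescence by chemo- or radiotherapy stop dividing
but stay metabolically active, and can later escape arrest — so telling
senescent from proliferating cells quickly and without labels matters for
therapy monitoring. Two optical markers distinguish them: aggregated lipid
droplets, bright in stimulated Raman scattering (SRS) at the 2850 cm⁻¹ CH₂
lipid mode, and an aggregated mitochondrial network, visible as clustered
foci in two-photon excited fluorescence (TPEF) of the endogenous NADH/FAD
coenzymes. Together with an optical transmission channel for morphology,
each field of view is a co-registered 250 × 300 × 3 image with a binary
label ("Senescent" / "Control").

`senonet` implements the full classification workflow for such data:

- **data_io** — CSV-manifest datasets of per-channel TIFF/PNG images, and a
  shallow preprocessing chain: percentile outlier clipping → background
  suppression → per-channel rescaling to [0, 255].
- **synthetic** — a phenotype generator producing labeled three-channel
  fields of view (droplets, mitochondrial foci, nuclei, noise) with a
  tunable senescent-vs-control contrast and ground-truth marker masks, so
  the whole pipeline is testable with no downloads.
- **augmentation** — label-preserving random rotations, translations and
  flips with zero fill (no cropping or stretching); 11 copies per image by
  default, so 170 training images become 2040. Augmenting the test split is
  refused outright.
- **architectures / nn** — a small from-scratch CNN (3×3 convolutions with
  6, 12, 24 filters), a transfer-learning head (global max pooling, dropout
  0.8, a 4-neuron ReLU layer with L1/L2 penalties of 0.01, sigmoid output),
  a registry naming the seven ImageNet backbones (InceptionV3,
  EfficientNetB4, DenseNet121, ResNet50, MobileNet, Xception,
  InceptionResNetV2 — weights not bundled) plus a STUB backbone for
  self-contained runs. All layers run on a compact NumPy engine with
  explicit, finite-difference-verified backprop.
- **training** — binary cross-entropy, Adam, the two-stage protocol (head
  at 5 × 10⁻⁴ with a frozen backbone, then fine-tuning the backbone at
  2 × 10⁻⁵), early stopping when the validation loss fails to improve by
  ≥ 0.005 over 20 consecutive epochs, best-weights restoration.
- **hybrid** — off-the-shelf deep features → PCA (95 % variance) →
  polynomial-kernel SVM with cross-validated hyperparameters, one per
  backbone, combined by hard voting; a ROC traced by the senescent vote
  count.
- **ensemble** — unweighted probability averaging over the per-backbone
  classifiers (predicted class = argmax of the mean class probability), in
  frozen (off-the-shelf) and fully trained (fine-tuned) modes, each learner
  trained on its own augmented dataset and validation split.
- **evaluation** — confusion counts with senescent as the positive class,
  accuracy / precision / recall / F1, threshold-swept ROC with trapezoidal
  AUC, and mean ± SD summaries over repeated training runs (nine by
  default).
- **interpretability** — Grad-CAM from the last convolutional stage,
  bilinear upscaling to image resolution, channel overlays, and a
  point-biserial colocalization score against the synthetic marker masks.
- **experiment / cli** — YAML-configured end-to-end experiments (scratch /
  hybrid / frozen ensemble / fully trained ensemble), channel-subset
  ablations by zero-filling, and a comparison table across architectures.

## Worked example

Train the hybrid voting classifier on synthetic data and evaluate it:

```python
from senonet.synthetic import SynthConfig, default_params, generate_bundle
from senonet.data_io import Split, preprocess_dataset
from senonet.architectures import build_stub_backbone
from senonet.hybrid import fit_hybrid, predict_hybrid, roc_by_vote_count
from senonet.evaluation import compute_metrics, confusion_counts

params = default_params(64, 80, effect_size=1.0)   # small-size mode
train = preprocess_dataset(generate_bundle(SynthConfig(64, 80, 30, 30, seed=0),
                                           params, Split.TRAIN))
test = preprocess_dataset(generate_bundle(SynthConfig(64, 80, 12, 12, seed=1),
                                          params, Split.TEST))

backbones = [build_stub_backbone(seed=s) for s in (0, 1, 2)]
model = fit_hybrid(backbones, train, seed=0)
pred, records = predict_hybrid(model, test)
_, truth = test.to_arrays()

m = compute_metrics(confusion_counts(pred, truth))
roc = roc_by_vote_count(records, truth)
print(f"accuracy  {m.accuracy:.3f}")
print(f"precision {m.precision:.3f}")
print(f"recall    {m.recall:.3f}")
print(f"F1        {m.f1:.3f}")
print(f"vote-count AUC {roc.auc:.3f}")
```

Output:

```
accuracy  0.958
precision 0.923
recall    1.000
F1        0.960
vote-count AUC 0.976
```

The metrics read as usual: of the 24 held-out fields of view, 95.8 % are
classified correctly; precision 0.923 means one control image was called
senescent; recall 1.000 means every senescent image was found; and the AUC
of 0.976 summarizes the ROC traced by sweeping the "at least t of 3
backbones vote senescent" threshold.

The same experiment is available from the shell:

```sh
senonet synth --n-senescent 30 --n-control 30 --height 64 --width 80 \
    --effect-size 1.0 --seed 0 --out data/train
senonet synth --n-senescent 12 --n-control 12 --height 64 --width 80 \
    --effect-size 1.0 --seed 1 --out data/test
# (tag the test manifest's split column as TEST first)
senonet hybrid --manifest data/train/manifest.csv \
    --test-manifest data/test/manifest.csv --seed 0 --out results/hybrid
```

Other subcommands: `preprocess`, `augment`, `train`, `ensemble-train`,
`predict`, `evaluate`, `gradcam`, `run` (YAML experiment), `compare`.

## Scope notes

The seven named ImageNet backbones are exposed through the registry but
their pre-trained weights are not bundled; requesting one raises a clear
error rather than substituting the stub. Reproducing the published
performance of the full seven-backbone ensemble on the real microscopy
dataset requires those weights, the deposited data and hours of GPU
training, and is outside the scope of this package's self-contained test
suite; see `docs/methods.md` for what the desk-scale experiments do and do
not demonstrate.
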