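# Methods

## Problem and model

`hemoct` classifies volumetric non-contrast head CT scans into normal (N) and
four acute-hemorrhage classes — subarachnoid (SAH), intraparenchymal (IPH),
acute subdural (ASDH), and combined polytrauma hemorrhage (BPH) — with a small
3D convolutional network, optionally preceded by a class-histogram intensity
threshold that suppresses the Hounsfield range common to both classes of a
binary task.

The classifier is a plain feed-forward stack on a `(width, length, depth)`
voxel grid, channels last:

| layer        | kernel | stride | output on 50×50×28 |
|--------------|--------|--------|---------------------|
| Conv3D       | 3×3×3  | 1      | 50×50×28×32 |
| MaxPool3D    | 2×2×2  | 2      | 25×25×14×32 |
| Conv3D       | 3×3×3  | 1      | 25×25×14×64 |
| MaxPool3D    | 2×2×2  | 2      | 13×13×7×64 |
| Conv3D       | 3×3×3  | 1      | 13×13×7×128 |
| MaxPool3D    | 2×2×2  | 2      | 7×7×4×128 |
| Flatten      | —      | —      | 25 088 |
| Dense + ReLU | —      | —      | 1 024 |
| Dropout 0.2  | —      | —      | 1 024 |
| Dense        | —      | —      | n_classes (logits) |

Convolutions are zero-padded "same" convolutions in the mathematical sense
(the kernel is reflected before the sliding inner product); for learned
kernels this differs from cross-correlation only by a relabelling of the
weights. Pooling is non-overlapping and **ceiling-mode**: an incomplete
trailing window still emits an output, so spatial sizes follow
`d -> ceil(d/2)` (50→25→13→7, and 25→13 rather than 12). This convention is
forced by the flattened width 7·7·4·128 = 25 088 of the dense head.

Each output voxel of a conv layer is
`h_k = relu( sum_j (h_j * W_{j,k}) + b_k )`, the triple sum running over the
kernel's spatial offsets and all input feature maps; the final Dense layer
emits logits and softmax lives inside the cross-entropy loss for numerical
stability.

The network is implemented directly on numpy arrays with hand-written
forward/backward passes (verified against finite differences and, for the
convolution, against `scipy.ndimage.convolve` and a literal nested-sum
oracle). The forward convolution uses a sliding-window view contracted by
`tensordot`; the backward pass shifts-and-accumulates over the 27 kernel
offsets, which avoids materializing the much larger window expansion of the
output gradient. Training runs in float32 (halving memory traffic roughly
doubles throughput on BLAS); the standalone `conv3d_forward` operation and all
metric computations stay in float64.

## Intensity thresholding

Normal head CTs are highly homogeneous across patients, and an abnormal scan
behaves like a normal scan plus added blood signal in a narrow band (acute
blood ≈ 50–90 HU, above brain parenchyma ≈ 20–40 HU, far below bone). The
threshold operator:

1. builds per-volume intensity histograms on a shared equal-width grid
   (default 256 bins spanning the pooled foreground range; exact-zero voxels
   are treated as padding/air background and excluded, configurable),
   normalizes each to unit mass, and averages them with equal weight per
   volume within each class (voxel pooling is available as a switch);
2. computes the target class's per-bin **excess mass**
   `d_i = max(b_i − a_i, 0)` over the reference class and the retained
   fraction `R(t) = Σ_{bins ≥ t} d_i / Σ d_i` at every bin edge `t`;
3. returns the largest edge with `R(t) ≥ 1 − δ` (default δ = 0.05): the
   widest discard range that loses at most a δ fraction of the excess-blood
   signal. Voxels strictly below the cutoff are set to 0; nothing is rescaled.

The one-sided excess is deliberate. Under per-volume normalization the tissue
band's mass *deficit* in abnormal scans exactly mirrors the blood band's
excess, so a symmetric L1 objective would always spend half its retention
budget protecting the tissue band and the cutoff could never clear it; the
excess-mass form discards the common range and keeps the band where the
abnormal class is over-represented, which is the operator's purpose. The
search is exhaustive over bin edges (B ≤ a few hundred, so O(B²) is free) and
is property-tested against an independent exhaustive oracle.

The cutoff is a class-pair construct: it is fitted for one normal-vs-abnormal
task, on that fold's *training* scans only (refit per fold; fitting on
held-out data would leak), and the multi-class pipeline never applies it.
Identical histograms (no excess anywhere) raise a fit error rather than
returning an arbitrary cutoff.

Noise sensitivity: with noisy volumes the class-mean histograms carry
sampling noise of order `sqrt(p/ (V·n))` per bin, which inflates the excess
mass in non-signal bins and pulls the cutoff down when the fitting set is
small. At the fitting-set sizes used here (≥ 60 scans per class) the fitted
cutoff on noisy phantoms lands between the tissue and blood bands, as it
should; on noiseless phantoms it sits just under the blood band.

## Training

* **Loss/optimizer:** softmax cross-entropy, Adam. Defaults: learning rate
  1e-3, β₂ = 0.999, ε = 1e-8, dropout 0.2 after the wide dense layer,
  batch size 8. β₁ defaults to 1e-3 — an unusual, essentially momentum-free
  setting kept for fidelity with the protocol this package operationalizes;
  the conventional 0.9 is one config field away.
* **Initialization:** zero-mean Gaussian kernels. The default scale is
  fan-in adjusted (`std = sqrt(2/fan_in)` per layer); a fixed numeric std can
  be passed instead, but with three stacked convs a fixed small std (e.g.
  0.01) shrinks activations by ~`0.01·sqrt(27·C)` per layer, the logits reach
  ~1e-5, conv-layer gradients fall below Adam's ε and the loss pins at ln 2.
* **Input scaling and centering:** inputs are divided by `input_scale`
  (default 300, the bone band, mapping scans roughly into [0, 1]) and then
  centered by subtracting the mean training volume. Mean-image centering
  matters here: the skull shell is a class-constant structure an order of
  magnitude brighter than the lesion contrast, and without centering it
  dominates every activation and stalls optimization. The mean image is
  fitted on the training split only and stored with the network, so held-out
  data and checkpoints see identical preprocessing.
* **Cross-validation:** a single stratified 5-fold plan over *base* scan
  ids (repeated cross-validation, when wanted, is obtained by re-planning
  under a different seed); every
  augmented variant (`source_id` suffix `::rot<a>_flip<f>`) travels with its
  scan. Within a plan, fold i tests on bucket i, validates on bucket i+1
  (mod k), and trains on the rest. Per-class test counts differ by at most 1
  across folds. Deterministic given the seed.
* **Augmentation:** eight-fold — rotation angles {0°, −45°, −15°, +15°} ×
  {unflipped, flipped}, rotations applied slice-wise in the axial plane
  (trilinear, zero fill), the flip mirroring each slice's vertical axis. The
  identity is kept among the variants so the original scan is always present.
  Augmentation defaults to the training split only; augmenting validation and
  test sets is supported as a switch for protocol parity.
* **Grid search:** every combination of the supplied learning-rate / dropout /
  kernel-size grids is trained and ranked by validation F1, ties broken by an
  epochs × parameter-count cost proxy. Even conv kernels (2×2×2) are not
  representable because same-padding convolutions here are centered;
  odd sizes {1, 3, 5} and pooling {1, 2} cover the intended sweep.

## Metrics

Confusion matrices are oriented **rows = predicted, columns = actual**; for
class c, TP is the diagonal entry, FP the rest of row c, FN the rest of
column c. Sensitivity S = TP/(TP+FN), precision P = TP/(TP+FP),
F1 = 2/(1/S + 1/P). The overall score is the micro-average trace/total
(equal to accuracy for single-label multi-class problems); the macro average
of defined per-class F1s is also reported. Zero-denominator metrics are NaN
with a warning, never silently 0. AUC is the Mann–Whitney rank statistic
(ties counted ½), invariant under monotone transforms of the scores and equal
to the trapezoidal ROC area.

## Synthetic phantoms

The phantom generator stands in for a private hospital cohort (default class
counts 130 N / 141 SAH / 61 IPH / 32 ASDH / 35 BPH). Each phantom is an
ellipsoidal bone shell (~300 HU) around brain-intensity interior (~30 HU)
with a small central ventricle (~10 HU), plus optional Gaussian noise
(default sd 5 HU); abnormal classes paint blood-intensity lesions (~70 HU):

* **SAH** — thin tracks along the inner brain surface plus a midline slab
  (subarachnoid blood follows sulci and cisterns);
* **IPH** — one compact ellipsoid at a random interior position;
* **ASDH** — a thick lens against the inner skull on a random side, with the
  ventricle displaced contralaterally by `midline_shift_voxels` (mass
  effect). The lens is deliberately thick: acute subdurals with mass effect
  are centimeters thick, and a 1-voxel film would in any case be erased by
  three rounds of max pooling next to bone;
* **BPH** — the union of two or three of the above.

Lesion geometry is drawn per seed (random centers, sides, directions) so a
classifier cannot memorize positions. Each lesion is realized by ranking
candidate brain voxels with a class-specific geometric score and keeping
exactly `round(lesion_volume_fraction · brain_voxels)` of them (default
fraction 0.05), so the lesion load is controlled. Default grid 50×50×28 at
(4.4, 4.4, 5.0) mm spacing; any shape works, including a raw 512×512×28 mode
for exercising the resampler. Volumes are deterministic given the master
seed, with per-volume seeds spawned from it.

What the phantoms do **not** model: real anatomy (gyri, gray/white contrast),
scanner physics (beam hardening, streaks, partial-volume blur), inter-patient
variability of head shape, or subtle lesions mixed into tissue intensities.
Passing phantom experiments therefore demonstrates that the pipeline is
correctly wired and that the method behaves as designed on data with the
statistical structure it exploits (class-specific intensity bands and
geometry); it says nothing quantitative about clinical performance.

## Numerical and design choices

* Resampling is trilinear over voxel centers (`(i+0.5)·src/target − 0.5`),
  which makes resampling idempotent at the target shape and exact for
  constant volumes; downsizing 512×512 → 50×50 interpolates rather than
  crops, so the skull periphery survives.
* DICOM loading applies rescale slope/intercept so in-memory values are HU;
  series with inconsistent slice geometry fail loudly, naming the slice.
* Intensities remain floating point end-to-end; no 8-bit quantization.
* The desk-scale experiment configuration (reduced widths 8/16/32 filters,
  256 dense units, 4 epochs, one fold of the 5-fold plan, no augmentation)
  was sized so a full paired thresholded/unthresholded comparison across five
  seeds completes in minutes on one CPU while the classes remain cleanly
  separable; the full-width architecture is the default everywhere else.
* Feature visualization writes per-map maximum-intensity projections along
  the slice axis rather than a deconvolution reconstruction — enough to
  compare thresholded and unthresholded activations side by side.

## Known limitations

* Convolutions support stride 1 and odd kernels only; pooling supports
  kernel == stride. This covers the architecture family used here.
* Pure-numpy training is single-device and unaccelerated; at the full 32/64/
  128-filter width an epoch over a few hundred scans takes minutes, which is
  fine for desk-scale studies but not for large cohorts.
* The threshold search assumes the abnormal signal lies *above* the common
  range (acute blood); hypodense pathology (e.g. chronic subdurals, ischemia)
  would need a mirrored operator.
* AUC is reported for binary tasks only.
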