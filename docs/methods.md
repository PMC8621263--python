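# Methods

This note records the scientific and numerical choices behind the
package: what the pipeline computes, what the synthetic phantoms do and
do not emulate, and where the design was genuinely open.

## The screening problem

An abdominal aortic aneurysm (AAA) is a focal dilation of the abdominal
aorta; the screening definition used throughout is a focal increase of
the vessel diameter of at least 50% over its normal calibre. The
pipeline answers one question per CT volume: does this scan show an AAA?
It is a binary volume classifier wrapped in enough automation that it
can run unattended over routinely acquired abdominal CTs: locate the
abdomen, cut a standardized patch, classify it, and (optionally) explain
the decision with a per-voxel relevance map.

## Pipeline

1. **Windowing.** HU values are clamped to [−200, 400] — an extended
   soft-tissue window that retains contrast between lumen, thrombus,
   muscle and fat while discarding the extremes of air and cortical
   bone — and mapped linearly onto [−1, 1].
2. **Resampling.** Volumes are resampled by trilinear interpolation to a
   common working spacing (reference: 0.9 × 0.9 × 1.5 mm, a typical
   median resolution of abdominal CT cohorts). Border samples introduced
   by interpolation are filled with air. Output dimensions are
   `round(dim · spacing / target)` per axis, so physical extent is
   preserved to within one voxel. Nearest-neighbour interpolation is
   used for label masks.
3. **Patch extraction.** A fixed-size patch (reference: 320 × 384 × 224
   voxels) is cut centred in-plane on an anchor slice — the axial
   position of the origin of the most cranial left renal artery in
   annotated data, or the output of the automatic abdomen detector.
   Out-of-volume regions are padded with normalized air (−1).
4. **Classification.** A two-class softmax 3D CNN maps the patch to an
   AAA probability; a case is called positive at a discrimination
   threshold of 0.5, with ties counted positive (screening favours
   sensitivity).

Order of operations is window → resample → (augment) → extract.

### Training-time augmentation

Each training patch is drawn with a fresh uniform sample of: an anchor
shift along the cranio-caudal axis (≤ 10 voxels at the reference
spacing), a random in-plane patch-centre offset (bounded at ±32 voxels
so the aorta, which sits in the central third of the slice, cannot be
cropped out), a rotation about the cranio-caudal axis within ±12.6°, an
isotropic in-plane scaling within ±10%, and a global density jitter
within ±3 HU applied in HU units (equivalently 2·Δ/600 in normalized
units). When rotation and scale are exactly neutral the implementation
skips interpolation entirely, so the identity draw is bit-exact equal to
plain extraction.

The shift and centre-offset bounds are *voxel* counts defined at the
reference 0.9/1.5 mm grid. On coarser grids the same voxel counts would
double the physical jitter and regularly push the aneurysm out of the
patch, so the desk-scale preset halves the anchor shift (±5 slices),
keeping its physical magnitude comparable. Rotation, scale and HU jitter
are resolution-independent and are never rescaled. The jitter is a
single scalar per draw, not per-voxel noise — CT data already carries
voxel noise, and the augmentation models calibration drift between
scanners.

At desk scale the *geometric* augmentations (rotation, scaling, and the
random in-plane centre offset) are disabled. This is an empirical design
choice: with cohorts of ~80 cases, a width-0.125 network and a few
hundred optimizer steps, training under those augmentations stalls at
chance for upwards of thirty epochs at any learning rate tried, because
the invariances they demand cost far more optimization than the compute
budget provides, whereas anchor-shift + density-jitter training descends
and generalizes within ~25 epochs. Convolutional feature maps are
already translation-equivariant, so the lost offset augmentation is the
cheapest of the three; the full-scale default configuration keeps the
complete augmentation set.

## Architectures

Three canonical image-classification topologies are built with 3D
kernels: an AlexNet-style stack (5 convolutions), VGG-16 (13
convolutions in five blocks) and an 18-layer basic-block ResNet. All
hidden activations are ReLU; the output layer is a two-way softmax.
Three deliberate adaptations keep volumetric memory in check and the
input shape flexible:

- every channel count is scaled by a configurable `width_multiplier`
  (default 0.25, desk scale 0.125);
- global average pooling precedes the classifier head, so any input
  divisible by the network's downsampling factor (16 for the AlexNet
  variant, 32 for the others) is accepted;
- dropout (0.5) is kept in the AlexNet/VGG heads and batch
  normalization in the ResNet, mirroring the source architectures.

These are canonical-topology stand-ins: channel schedules are the
standard ones under the width multiplier, and the ResNet's closing
block normalizations start at γ = 0 so each block is initially the
identity, which substantially shortens the early optimization plateau
on small cohorts.

### The numpy network engine

The networks run on a small, fully introspectable engine written on
numpy/scipy: im2col + BLAS matmul for 1³/3³ convolutions, an FFT
(circular-correlation) route for the large-kernel stem convolutions
where im2col is memory-traffic bound, manual backpropagation, Adam with
optional decoupled weight decay, and cosine learning-rate decay. The two
convolution routes agree to float32 round-off and both are covered by
finite-difference gradient tests. Every layer exposes its affine part
separately from its nonlinearity, which is what makes exact layer-wise
relevance propagation possible.

Batch-norm inference statistics are *recalibrated* after training (and
before each validation pass): with short runs and a rapidly moving
optimizer, exponential running averages trail the final weights badly
enough to invert held-out predictions. The calibration pass freezes the
weights, streams training patches through the network with per-batch
normalization, and installs exact per-channel moments as the inference
statistics. This is the precise-BN strategy; without it, train-mode and
eval-mode outputs of a freshly trained small-cohort model can disagree
grossly.

## Training and evaluation protocol

Stratified 5-fold cross-validation: five disjoint test sets covering all
cases with class proportions preserved to within one case; per fold, a
small stratified validation set (default 6 cases) is drawn from the
non-test cases and the rest trains. Training minimizes cross-entropy
with Adam; the best epoch is selected on validation loss; early stopping
is available (patience 15 by default). Optimizer settings are
configuration, not doctrine: defaults are Adam at 1e-4, batch 2 at full
scale; the desk-scale preset uses lr 1e-3 with cosine decay to 1e-4,
weight decay 1e-3, batch 8, 25 epochs.

The desk-scale recovery experiment (80 training phantoms, 40 held out,
64³ patches, width 0.125) trains on all 80 cases with no validation
split — the final cosine-annealed model is evaluated directly, since a
six-case validation set at this scale selects checkpoints close to
randomly — for 25 epochs at batch 8, lr 1e-3 → 1e-4, weight decay 1e-3.

Metrics at the fixed threshold: accuracy, precision, true-positive rate,
false-positive rate and F1, plus the ROC curve over all distinct
thresholds and its trapezoidal area (equal to the probability a random
positive outscores a random negative, ties counting one half). Ratios
with a zero denominator are reported as NaN with a warning — silent
zeros would corrupt pooled aggregation. Aggregation over folds pools the
per-case outcomes first and computes metrics once; it is not a mean of
per-fold metrics. A record type for 5-point Likert scores of relevance
maps is provided (storage and averaging only); the scoring itself is a
human reading.

## Relevance maps

Layer-wise relevance propagation seeds the target class's *pre-softmax*
score (softmax mixes the classes) and propagates it backwards:
the ε-stabilized z-rule by default,
`R_j = x_j · [Wᵀ (R / (z + ε·sign z))]_j`, with the α=1/β=0
positive-contribution rule selectable. Max-pooling routes relevance to
the winning voxel, average pooling redistributes proportionally,
residual joins split relevance in proportion to each branch's
contribution to the sum. Bias contributions are absorbed rather than
redistributed — the simplest well-defined choice — so exact conservation
holds on bias-free configurations, and the conservation tests construct
exactly those. Batch normalization is folded into the preceding
convolution before propagation, making the network a pure linear/ReLU
cascade for which the rules are defined.

Maps are standardized by dividing by their sum (an error if the sum is
numerically zero); positive values indicate evidence for the AAA class,
negative against. Overlays render positives red (high: yellow) and
negatives blue (high: light blue) over the grayscale patch. As an
automated surrogate for the human reading, the aorta relevance fraction
reports the share of total *absolute* relevance (positive and negative
counted equally) inside an aorta mask; its chance baseline is the mask's
volume fraction.

## Automatic abdomen extraction

The screening heuristic works on the raw HU volume. Per axial slice it
computes the fraction of voxels in a soft-tissue band ([−100, 200] HU)
and above a bone threshold, both smoothed with a 5-slice moving average.
The abdomen bounds are the ends of the longest contiguous run of slices
whose soft-tissue fraction exceeds τ = 0.10; the abdomen centre is the
midpoint of the low plateau of the bone profile between its caudal
(pelvic) and cranial (rib-cage) peaks — the stretch between the top of
the hip bone and the lower ribs where only the spine contributes bone.
If no two-peak structure exists the centre falls back to the midpoint of
the bounds with a warning; screening must not crash on atypical anatomy.

All four numbers are configuration defaults calibrated on phantoms. Two
deviate from the obvious first guess deliberately: the bone threshold is
400 HU rather than ~250 because contrast-filled arterial lumen (~300 HU)
would otherwise masquerade as bone along the aorta and distort the
centre detection; and the smoothing window is 5 slices rather than ~11
because per-slice fractions are already averages over tens of thousands
of voxels, and wider smoothing visibly biases the detected bounds inward
at the lung-bearing cranial end. The detectors sit behind two small
functions so alternative criteria can be swapped in.

The subvolume is centred in-plane on the image centre; whether a sharper
in-plane criterion helps is an open question. Along the body axis the
synthetic anchor is not the abdomen centre itself but sits 0.13 of the
abdominal extent cranial of it — the typical position of the renal
arteries relative to the mid-abdomen. This matters because the
classifier is trained on renal-level anchors: with the anchor at the raw
mid-abdomen the automatic pathway presents patches ~4 cm caudal of the
training distribution and its decisions diverge from the manual-anchor
pathway on roughly four cases in ten at desk scale, whereas with the
offset the two pathways agree on ≥ 90% of held-out phantoms.

## Phantoms

Clinical CT cannot be redistributed, so the package generates synthetic
abdominal volumes: an elliptical soft-tissue torso (fat rim, ~40 HU
interior) in air, paired low-HU lung regions cranially, a bone spine
along the torso with pelvic rings caudally and a rib shell cranially,
and a contrast-filled aorta (arterial ≈ 300 HU, venous ≈ 120 HU,
mirroring mixed-phase cohorts at roughly a 45/55 split) running
anterior-left of the spine with a gently swaying centerline. An
aneurysm is a fusiform bulge (squared-cosine radius profile) of
configurable apex diameter and axial extent, optionally lined by
~60 HU thrombus occupying a fraction of the cross-section — which can
make the dilation nearly isointense with surrounding soft tissue, the
hard case for any intensity-based classifier — and optionally carrying
a stent-like 2000 HU insert. Gaussian noise (default σ 12 HU) is added
last.

Ground truth is measured, not asserted: per-slice circle-equivalent
diameters of the generated vessel mask give a baseline (median) and
maximum, and the label is 1 iff max ≥ 1.5 × baseline. Corrupting the
geometry (an apex below the 50% rule) therefore flips the label. The
default dataset draws torso scale ±15%, baseline diameter 16–24 mm,
apex ratio 1.6–2.6 (capped by torso geometry), extent 50–110 mm,
thrombus fraction 0–0.6, ~8% stents, noise σ 8–18 HU, and jitters
anchors by ±2 slices to mimic annotation variance; prevalence defaults
to 100/187.

What the phantoms do **not** emulate: organs and bowel, streak/beam
artifacts, the patient table, anatomical variation beyond affine torso
scaling, and partial-volume behaviour of real scanners. Tests passing on
phantoms demonstrate that the pipeline's machinery — preprocessing,
optimization, cross-validation, relevance propagation, and the
abdomen heuristic — works end to end and that the classifier can learn
a geometric criterion from images; they say nothing about clinical
accuracy on patient data.

## Problem sizes

The reference configuration (0.9 mm grid, 320 × 384 × 224 patches,
width 0.25) is the documented full-scale setting. All tests and the
acceptance script run the desk-scale preset: phantoms on a
1.8 × 1.8 × 3.0 mm grid, 64³ patches, width 0.125 networks, cohorts of
order 100 cases — sizes chosen so a complete cross-validated experiment
runs on a single CPU. The two settings differ only in configuration.

## Known limitations

- The engine is CPU-bound numpy; full-scale patches are supported by the
  code but impractical to train without accelerator hardware.
- LRP on networks with biases is not exactly conservative (bias
  absorption); conservation is guaranteed and tested only for bias-free
  configurations.
- The phantom label rule uses in-plane equivalent diameters; a strongly
  tortuous vessel would need centerline-orthogonal measurement.
- DICOM series are not read directly; convert to NIfTI first.
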