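# Methods

## Problem setting

Tumor-region classifiers for whole-slide images are usually trained on
patches whose labels come from hand-drawn tumor outlines. Quick ("rough")
outlines differ from exact ones in two systematic ways: they swallow
non-tumor structures inside the tumor (fibrous stroma, vessels), and they
miss small scattered tumor foci outside the main region. A patch labelled by
its center's position relative to a rough outline therefore carries label
noise. The package implements a two-step remedy: (1) screen the training set
with a preliminary model's confidence, and (2) train with smoothed targets
whose weight can be predicted per patch from its surroundings.

## Patch model and losses

The classifier maps one RGB patch to a single logit z; the tumor probability
is p = 1/(1+e^{−z}). The loss is binary cross-entropy,
L = −Σ_i [t_i log p_i + (1 − t_i) log(1 − p_i)], with three target choices:

* **hard** — t = y ∈ {0,1};
* **static smooth** — t = (1 − ε)y + ε/2 with a fixed ε (default 0.2, the
  best value of the {0.1, 0.2, 0.3} grid);
* **dynamic smooth** — the same form with a per-patch weight ε′ = 0.2·ε,
  ε = σ(h(E_p(tile))) ∈ (0,1), so ε′ ∈ (0, 0.2) with analytic supremum 0.2.

The *tile* is the 3×3 assembly of the patch and its 8 spatial neighbors at
the training magnification ("feature polymer"). E_p is a six-convolution
encoder pretrained as an autoencoder (mean-squared reconstruction, mirrored
decoder with nearest-neighbor upsampling) and frozen afterwards; h is a
two-layer fully connected head ending in a sigmoid, trained jointly with the
classifier through the classification loss only. The gradient of the loss in
ε′ is −z·(1/2 − y), so a sample the classifier confidently contradicts
(z < 0, y = 1) receives a *larger* smoothing weight — the intended behavior
for probably-mislabeled patches. Tile features are cached once per dataset
(the encoder is frozen) and z-scored so the head trains at a consistent
scale.

Probabilities are clamped to [1e−7, 1−1e−7] inside the loss. Training uses
the adaptive-moment optimizer with batch size 32; the loss is averaged over
the batch for step-size stability. The checkpoint with the best validation
accuracy is kept; validation patches use curated (exact) labels, mirroring a
hand-verified validation set.

## Screening

The preliminary model is trained on the raw noisy labels of the train split
(class-balanced). Its *predicted value* for a patch is the probability
assigned to the annotated label: p if y = 1, else 1 − p.

* **Patch screening** removes patches with predicted value strictly below
  the threshold (default 0.7; a patch exactly at the threshold is retained).
* **Slide screening** computes per-slide accuracy with hard calls at
  p ≥ 0.5 (ties to tumor) and removes every patch of slides strictly below
  the accuracy threshold (default 0.7).

Decisions are taken at the screening magnification (×20 by default) and
applied to the whole co-registered patch group, since all crops of a group
share one label. Screening probabilities are averaged over the eight
dihedral views of each patch so confidence reflects content rather than
orientation. After screening, the train split is rebalanced: per-slide caps
first, then classes equalized to the smaller class by seeded subsampling.

## Inference

* **Slide call**: all grid patches on tissue are classified; the
  cancerous-patch ratio is #(p ≥ 0.5)/#patches and the slide is called tumor
  iff the ratio ≥ threshold (default 0.04, boundary inclusive). The optimal
  threshold can be recovered by an exhaustive accuracy sweep (ties toward
  the smaller threshold).
* **Pixel map**: sliding-window mean probability — each pixel's value is the
  mean over all windows containing it; blank (non-tissue) pixels are
  excluded from evaluation. Pixel accuracy thresholds the map at 0.5 and
  compares with the exact annotation mask over the evaluation mask.
* **Patch metrics**: accuracy, ROC-AUC, and F1 = 2PR/(P+R) at the 0.5 cut.

## The slide phantom

A phantom is a rendered raster plus exact geometry:

* an elliptical tissue region on a near-white background (so tissue masking
  by intensity threshold is exercised);
* blobby tumor components whose union is area-matched to
  `tumor_area_fraction` of the tissue;
* circular **inclusions** carved out of the tumor (stroma or vessel texture)
  totalling `inclusion_rate` of the gross tumor area;
* small scattered tumor **foci** outside the rough outline totalling
  `scatter_rate` of the true tumor area;
* stroma/vessel **distractor** regions in normal tissue (`distractor_rate`
  of tissue area). These carry no label noise themselves but are essential:
  without them, inclusion textures would appear *only* under tumor labels
  and the "noise" would be a consistent, learnable rule instead of noise.

The rough annotation is derived from the exact one by the same operation
offered standalone (`roughen_annotation`): holes filled, outlines dilated by
`dilation_radius_px`, small components dropped. The label-noise rate —
the probability that a uniformly placed tissue patch gets conflicting
rough/exact center labels — is the relative area of (rough XOR exact) and is
measurable (`measure_noise_rate`) as well as analytically predictable
(`PhantomSpec.nominal_noise_rate`, inclusions + dilation ring + foci over
tissue area).

Textures are band-limited Gaussian noise fields with class-specific color
statistics, grain scale and nuclear spot density; the red channel mean is
shared across all tissue classes so no class is separable by mean color
alone. Default parameters (tumor_area_fraction 0.35, inclusion_rate 0.25,
scatter_rate 0.12, dilation 6 px) give ≈15–20% patch noise and put the
preliminary screening model at ≈85% validation accuracy — the intended
operating regime. Inclusion and focus radii are sized near the patch
footprint so that a mislabeled patch is dominated by its true-class texture;
the last disk of each placement loop shrinks to the remaining area budget so
realized areas track the configured fractions.

What the phantom does **not** emulate: real H&E stain variation (stain
normalization therefore defaults to identity in synthetic mode, with
Reinhard-style LAB statistics matching available for real rasters), nucleus-
level morphology, scanner artifacts, pyramid file formats, or annotation
errors that correlate with appearance. Passing tests show the pipeline's
mechanics and the direction of its effects, not clinical performance.

## Desk-scale study conditions

The default experiment uses 12 slides of 384×384 px (4 tumor-free), 80
centers per slide with minimum distance 24 px, 64×64 patches at ×5/×20/×50
(training and screening at ×20), a 4-block strided CNN, 25 pretraining and
30 training epochs, learning rate 1e−3 (training from random initialization
needs a larger step than fine-tuning a pretrained reference backbone), and a
96×96 input to the context encoder (the 192×192 tile average-pooled 2×).
Splits are stratified by tumor presence so every split sees both slide
classes. The headline comparisons are means over five seeded replicates of
the full screening × smoothing grid; one replicate runs in under a minute on
one CPU, the five-replicate study in a few minutes.

At this scale the arm-to-arm accuracy differences are fractions of a
percentage point and individual replicates fluctuate by more than the mean
margins; the orderings (screened > raw; dynamic > static; smoothed-screened
≥ raw-hard) are directional claims about means, not per-run guarantees.

## Numerical and design choices

* Coordinates are 0-based pixels at base magnification, origin top-left,
  half-open windows; out-of-bounds crops pad with background white (245).
* Polygon boundaries count as inside for labelling; the overlap-fraction
  labelling rule (threshold 0.5) is available by configuration.
* Center sampling is greedy dart-throwing over a seeded permutation of
  tissue pixels; it is deterministic per seed and satisfies the minimum
  distance exactly.
* All randomness descends from one master seed via a seed sequence; repeated
  runs with the same configuration produce byte-identical reports.
* The layer library (`noisypath.nn`) implements im2col convolution, linear,
  ReLU/sigmoid, nearest-upsampling and average-pooling layers with manual
  backpropagation, verified against central-difference gradients in the test
  suite; model checkpoints serialize to `.npz` with a JSON sidecar.
* Degenerate inputs: zero-variance patches pass through stain normalization
  with a warning; an empty tissue mask yields no centers (warning); a
  single-class training set, an empty prediction list, and an empty
  evaluation mask raise errors; non-finite training loss aborts with a
  stage diagnostic.

## Known limitations

* No pyramidal/vendor WSI backend; rasters load fully into memory (phantom
  scale). The patching geometry is backend-agnostic, so a pyramidal reader
  could be slotted in behind `SlideImage`.
* No ResNet18-class backbone is included; only the desk-scale CNN is
  provided (pretrained reference backbones would need a framework this
  package deliberately does not depend on).
* Slide-level evaluation at desk scale uses all cohort slides (few slides
  per split) rather than a dedicated test cohort.
* The ε head receives the encoder bottleneck; whether richer pooled features
  would help is untested.
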