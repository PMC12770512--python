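# Methods

This note documents the models, conventions and design choices behind
`lungcyto`, in the spirit of the methods documentation of packages
like scanpy or statsmodels: what each stage computes, which knobs
matter, and what the synthetic data can and cannot tell you.

## The problem

Cytology images of single lung cells carry the earliest morphological
signals of the three major carcinoma subtypes: glandular lumina
(adenocarcinoma), rosette-like nuclear arrangements (neuroendocrine
carcinoma) and keratin pearls (squamous cell carcinoma). The package
implements a complete classification workflow for such images:
contrast enhancement, a bespoke feature-processing stage that
separates tissue and fluid from the near-white slide background, a
balanced split/cross-validation layer, an augmentation stack, a hybrid
two-branch convolutional classifier, and the evaluation statistics
used to report it. The clinical image collections such workflows are
developed on are generally private, so the package ships a synthetic
generator that reproduces the intensity structure the pipeline relies
on; every stage is testable end to end without any download.

## Image model and conventions

Images are 8-bit grayscale arrays in [0, 255]. Two conventions are
applied uniformly:

* **Rounding** — every float-to-intensity conversion rounds half away
  from zero. One documented rule avoids a patchwork of numpy banker's
  rounding and C-style truncation.
* **Unit rescaling** — division by 255 happens only at model-input
  time. All enhancement and feature thresholds (60, the Otsu scan,
  the 100–180 midtone band) are defined on the 0–255 scale.

RGB inputs are collapsed with BT.601 luma weights (0.299, 0.587,
0.114). Resizing is bilinear on the align-corners grid; a same-size
resize is an exact identity.

## Enhancement stages

**CLAHE.** The image is divided into a tile grid (default 8×8); each
tile's 256-bin histogram is clipped at `clip_limit × tile_pixels/256`
(default clip 2.0) with the clipped excess redistributed uniformly
over all bins, so histogram mass is conserved exactly. The per-tile
equalization mapping sends the lowest occupied intensity to 0 and the
highest to 255 through the clipped CDF; per-pixel outputs bilinearly
interpolate the mappings of the four surrounding tile centers
(clamped at borders). Single-valued tiles map identically, so
constant regions stay constant. With one tile and an unbounded clip
the operation reduces to global histogram equalization, which is how
it is cross-checked. Clip limit and grid are exposed because no
single setting suits all stain/illumination combinations; the
defaults are the de-facto standard of widely used implementations.

**Median denoising.** A 3×3 median with edge replication, delegated
to `scipy.ndimage.median_filter` and verified against a brute-force
sorted-window oracle. The window deliberately stays at 3×3: impulse
(salt-and-pepper) noise is removed — under 5% of injected impulses
survive one pass on synthetic defaults — while cell boundaries at
this image scale survive; larger windows visibly erode them.

## Feature processing

The stage runs on the enhanced image in a fixed order:

1. **Dark pre-map.** Pixels ≤ 60 (`dark_threshold`) are set to 0 and
   flagged. These are fluid pockets and dense chromatin whose
   locations must survive the later background masking.
2. **Otsu separation.** An exhaustive scan over all 256 candidate
   thresholds maximizes the between-class variance
   ω₀ω₁(μ₀−μ₁)², with class 0 = {v ≤ t}. The smallest maximizer is
   returned (deterministic tie-break, matching common reference
   implementations), and a constant image returns its own value. The
   histogram includes the pre-mapped zeros (a config flag can exclude
   them for sensitivity analysis). Foreground is the at-or-below
   class: tissue and fluid are darker than the white background.
3. **Cleanup.** Connected foreground components (8-connectivity by
   default) strictly smaller than `min_object_px = 30` are removed;
   a 30-pixel component is kept. Holes are *not* filled — small
   white structures inside cells (lumina) are features, not noise.
4. **Composition.** Priority order: dark-flagged → 0, else
   non-foreground → 255, else the enhanced value. Dark must outrank
   background, otherwise the masking would erase the pre-mapped fluid
   pockets. Every output pixel is therefore exactly one of
   {0, 255, enhanced value}, which tests check exhaustively.
5. **Midtone lightening.** `v → min(255, round(1.3·v))`. 0 and 255
   are fixed points; midtones brighten (100 → 130) and light greys
   saturate into the background (≥ 197 → 255), shrinking the visual
   weight of free fluid while sharpening cell–fluid interfaces. The
   map is order-preserving.

**Quality metrics.** The enhancement effect is summarized by an SNR
proxy, |mean(fg) − mean(bg)| / std(bg), and by the standard deviation
of pixels whose input value lies in the 100–180 midtone band, each
before and after the chain. Two conventions matter. A constant
background in the *input* makes the baseline undefined and is
reported as an explicit `None`, never as 0. A constant background in
the *output* is different: composition deliberately drives the
background to pure white, which is the ideal limit of background
suppression, so a composed image with nonzero class separation
reports infinite SNR and counts as an increase. On synthetic
defaults the chain raises the proxy on 100% of images; the magnitude
of the improvement depends on definitions that have no single
standard, so only the direction is asserted anywhere.

## Splits and cross-validation

Manifests are pandas DataFrames (`path,label,split,fold`) written as
CSV. Sealing subsamples every class to a common cap (default 1500)
uniformly without replacement; operations sort by path first so
results do not depend on incoming row order, and a single seed makes
every assignment reproducible. The hold-out split marks
`round(n·train_fraction)` rows per class as training; an explicit
`train_per_class` override exists because the published workflow's
printed counts (1050 train / 450 test per class, totals 3150/1350)
correspond to a 70:30 division of the 1500 cap even though it is
described as 75:25 — the package reproduces the counts and leaves the
fraction as a free parameter. Stratified k-fold deals shuffled
per-class rows round-robin, so per-class fold sizes differ by at most
one; the cross-validation entry point defaults to a 1550-per-class
cap (4650 images, 310 per class per fold at k = 5), matching the
arithmetic of the published five-fold analysis.

## Augmentation

One affine map per training image, composed about the image center in
the order flip → zoom → shear → rotation → shift: rotation
U(−20°, 20°), per-axis shifts U(−0.3, 0.3) of the image dimension,
shear-angle U(−0.2, 0.2) rad, zoom U(0.8, 1.2), horizontal flip with
probability ½ — the semantics of the common training-generator
convention those scalar ranges come from. Warping is bilinear with
edge replication (`fill_mode="nearest"`). Augmentation is applied
on the fly to training batches only; validation and test images are
never augmented. The zero-range configuration is an exact identity,
and a 180° rotation equals index reversal, which pins the coordinate
conventions.

## The hybrid classifier

Two branches are fused by feature concatenation:

* **Residual branch** — a stem convolution, then stages of bottleneck
  blocks (1×1 reduce, 3×3, 1×1 expand, batch-normalized, ReLU, with
  identity or projection shortcuts). Stage i uses internal width
  `base_filters·2^i` and output width 4× that; global average pooling
  and dropout (0.3) produce the feature vector. The full stage plan
  (3, 4, 6, 3) is the canonical 50-layer residual network (49
  convolutions + classifier).
* **Attention branch** — an encoder/decoder with attention-gated skip
  connections. The gate is the standard additive formulation
  α = σ(ψ(ReLU(Wx·x + Wg·g))) with 1×1 convolutions, the gating
  signal upsampled to the skip's resolution; the decoder output is
  globally average-pooled (a bottleneck read-out is available behind
  a config switch). Encoder levels apply dropout 0.3.

The head is Dense-512 (ReLU, L2 weight decay 1e-4) → batch
normalization → dropout 0.25 → softmax over the three classes,
trained with Adam on categorical cross-entropy. All of it is
implemented directly in NumPy with hand-written backward passes
(verified against central-difference numerical gradients); training
is bit-reproducible for a fixed seed on a given BLAS.

**Desk scale.** The published full-scale setting (224×224 input,
plan (3,4,6,3), lr 1e-4, 25 epochs) is the config default but is not
trainable in minutes on one CPU. `desk_config()` is the package's
small-scale operating point: 64×64 input, one bottleneck per stage,
`base_filters=8`, U-Net depth 2, batch 6, 50 epochs, lr 1e-3. The
larger step size is part of the desk scaling: a small from-scratch
network on tens of images needs it, where a pretrained full-scale
model does not. No pretrained weights are downloaded; initialization
is seeded He-normal, with a hook for externally supplied weights.
On 60 separable synthetic images the desk model reaches 100%
training accuracy within 50 epochs (about two minutes on one CPU),
which is a *capacity/optimization* sanity check — not a claim about
clinical accuracy.

## Evaluation statistics

Per-class precision, recall and F1 are one-vs-rest quantities from
the K×K confusion matrix; overall accuracy is trace/total; macro
averages are plain means. Ratios with zero denominators are explicit
`None` markers. Fold summaries use the sample (n−1) standard
deviation, SE = SD/√n, CoV = SD/mean and a *normal-quantile* CI
(z = 1.96); with five folds a Student-t interval (t₄ = 2.776) would
be wider, but the z convention is what the published tables follow
and both are available through the `z` parameter. Full precision is
kept internally; rounding (2 dp for percents, 4 dp for SE) happens
only in the presentation helper. Where counts imply a metric of
exactly 1.0 the published tables print 0.999999; the module reports
true values.

## Synthetic data: what it does and does not emulate

The generator renders, per image: a constant background drawn from
[230, 255]; 5–7 mid-grey fluid discs whose intensities cluster
(±8) around a per-image base drawn from the lower 40% of the
100–180 fluid band — tissue-level homogeneity that places per-image
Otsu thresholds in the low-to-mid 100s, the band reported for real
denoised cytology material; one subtype motif drawn as hard discs
and annuli with nucleus intensities in [10, 60] (ring of radius
28–34 px at 224-scale for lumina; three rosette clusters of eight
small discs; three concentric pearl shells at radii 10/18/26 over a
mid-grey core); three stray nuclei; then a linear illumination
gradient (amplitude ≤ 10) and finally salt-and-pepper impulses
(fraction 0.01, exact 0/255). Noise comes after illumination so that
impulse pixels are exact extremes — the sensor is the last element
of the acquisition chain. Motif radii scale with image size, so
64×64 desk images keep the class geometry. Generation is
bit-reproducible per seed.

The three motifs are separable by a translation-invariant radial
profile of dark pixels (a thin shell, a compact cluster, multiple
shells): a nearest-centroid classifier on that profile scores
93–98% across seeds on noiseless renders, which guarantees that the
desk-scale learning check is achievable by construction.

What the generator does **not** emulate: staining variability and
color, anti-aliased or textured structure boundaries, overlapping
cells, debris, focus gradients, or any pixel statistics of the
private clinical collections beyond the Otsu band. Green tests on
synthetic data therefore demonstrate that the pipeline's mechanics
and statistics are correct — not that the reported clinical
accuracies transfer.

## Problem sizes and numerical choices

Default test and acceptance runs use 60–100 synthetic images at
224×224 for pipeline statistics and 60 images at 64×64 for training,
sizes chosen so the whole suite runs in a few minutes on one CPU.
Degenerate inputs are defined, not special-cased ad hoc: constant
images pass through CLAHE and Otsu with documented conventions;
empty masks, empty manifests and 0/0 metric cells all have explicit
behavior. Known limitations: CLAHE tile edges use clamped (not
reflected) interpolation; the attention branch's bottleneck read-out
is inference-only; `MaxPool2` requires even spatial dimensions, so
input sizes must be divisible by each branch's downsampling factor.
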