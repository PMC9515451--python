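# Methods

## Problem setting and model

A whole-slide image (WSI) is a multi-resolution pyramid of an H&E-stained
tissue section, up to ~10⁵ px per side at the base magnification.  Dense
pixel-level inference at full resolution is infeasible, and tumor
annotations exist only slide-wise, so the package uses a two-stage
cascade:

- **Stage 1 (detection).**  A classifier scores non-overlapping 256 px
  patches at ×100 magnification as tumor / non-tumor; the tumor softmax
  probabilities form a patch-grid heatmap.  Non-overlapping stride is a
  deliberate efficiency choice — no overlapping inference or ensembling —
  accepting a blocky heatmap that stage 2 will repair.
- **Stage 2 (refinement).**  A U-Net-style convolutional autoencoder maps
  the concatenation of the low-resolution RGB plane and the heatmap
  (4 input channels) to a per-pixel 2-class softmax.  It sees global
  context the patch classifier cannot, and learns to align the coarse
  heatmap with actual tissue boundaries.

## Coordinate and pyramid conventions

All origins are level-0 pixels, (x rightward, y downward, 0-based,
half-open); region extents are in target-level pixels.  Written pyramids
downsample by 2× box-mean with round-half-up — documented so tests can
predict downsampled values exactly.  Magnification resolution picks the
stored level with the smallest magnification ≥ the target, then resizes
bilinearly to the exact target dimensions; upsampling beyond the base
plane is refused.  Missing magnification metadata may be supplied by the
cohort manifest.

## Preprocessing rules

Tissue: ×1.25 plane → HSV → saturation (0–255 scale) > 20 → closing with a
5×5 then a 3×3 square kernel.  Patch labeling: tissue fraction must exceed
25% (strict); tumor label requires tumor fraction > 25% (strict);
non-tumor requires exactly zero tumor; the (0, 25%] band is discarded as
ambiguous.  Fractions are computed on the coarse mask grids (tissue at the
×1.25 downsample, annotation at downsample 4) restricted to the patch
footprint with equal per-pixel weights; cell boundaries are rounded to the
nearest mask pixel edge.  The grid starts at (0,0) with stride = patch
size, and partial edge cells are discarded.  Grid origin, edge handling
and the fraction resolution are package conventions; coarse-grid counting
is the only reading that scales to gigapixel slides.

## Hierarchical sampling

Sampling is with replacement down the grade → WSI → class → patch tree,
uniform at each stage; an epoch is a fixed number of batches.  Branches
with no members (a tumor-free slide, an unused grade) are pruned rather
than raising, preserving equal probability among outcomes that exist.
Pixel reads may fan out over worker threads behind a bounded prefetch
queue; random draws stay serial, so parallel and serial execution produce
bitwise-identical batches and seeded runs are reproducible.  Full-scale
defaults are 500 train / 200 validation batches of 64 per epoch
(32 000 / 12 800 samples).

## Cluster guiding

Feature extraction → per-feature z-score → PCA keeping the minimal
component count whose cumulative explained variance reaches 95% → k-means
with k = 10 (k-means++ init, 10 restarts, 300-iteration cap, fixed seed).
The fitted statistics are frozen and reapplied verbatim at training time
(fit-set mean/std are reused at assignment; nearest centroid in squared
Euclidean distance, ties to the lowest index), so training-time
assignments reproduce fit-time assignments bitwise.  Zero-variance
features get std replaced by 1 instead of erroring, since synthetic
fixtures can produce them.  The default extractor is a fixed-seed
random-projection CNN (d = 512) so the package works fully offline;
pretrained ImageNet-style extractors can be registered as alternatives.

## The CWCE loss

The loss is the macro average over clusters represented in the batch of
the per-cluster *mean* cross-entropy.  The mean-then-macro reading is
deliberate: a per-cluster sum would scale with batch size and would not be
a macro average; the equivalent statement as a weighted sum uses per-sample
weights `1/(K_b · n_cluster(i))`, which is also how the training gradient
is formed.  Cluster assignments are hard; probabilities are clipped at
1e-7 before the log so a confident wrong prediction yields a large finite
loss, never NaN.  With all samples in one cluster the loss and gradient
coincide exactly with plain mean categorical cross-entropy, which is the
no-clustering code path.

## Networks and training

No deep-learning framework ships with the package; the two networks and
their training loops run on a small float32 NumPy layer library
(convolutions via shifted matmuls, batch norm, max/avg pooling,
nearest-neighbour upsampling, dense, dropout, Adam).  Max-pool ties route
gradient to every tied input — a deterministic rule, which is what makes
the gradient-accumulation equivalence exact and testable.

- **Classifier**: pluggable backbone + fixed head (global average pool →
  dense 100 → dropout 0.5 → ReLU → batch norm → dense softmax).  The
  default `builtin_small` backbone (4× average-pool stem, four conv
  blocks) trains in minutes on a CPU; heavier backbones register without
  changing the head.  Adam, lr 1e-4; best epoch by validation loss.
- **Refiner**: symmetric encoder/decoder with
  (conv–batch norm–ReLU)×2 + max-pool blocks and skip connections;
  full-scale spec is depth 9, filters (8, 16, 32, 64, 128, 128, 256, 256,
  512) at 1024² input; reduced specs (e.g. depth 7 at 256²) are
  first-class for desk-scale work.  Adam, lr 1e-3, batch 4 with gradient
  accumulation (effective batch 24 at full scale), early stopping on
  validation loss.  The refiner's training loss is not uniquely dictated
  by the design, so the package defaults to per-sample soft Dice on the
  tumor channel (decomposable over samples, hence exact under
  accumulation), configurable to cross-entropy.

Augmentation (each operator applied independently with probability 0.5):
flips, lossless 90° rotations, per-channel HSV shifts (integers in
[−20, 20] on the 8-bit scale), multiplicative brightness [0.8, 1.2] for
the classifier; flips, rotations, zoom [0.8, 1.2] and Macenko stain
augmentation (σ₁ = σ₂ = 0.1) for the refiner, with geometric transforms
shared across image/heatmap/mask (bilinear for continuous channels,
nearest for masks; zoom-out pads image with white, heatmap/mask with 0).
The Macenko step estimates two stain vectors from optical-density extreme
angles (OD = −log₁₀, β = 0.15, α = 1st percentile) and perturbs each
stain's concentration by scale 1 + U(−σ₁, σ₁) and offset U(−σ₂, σ₂);
the two-stain fit residual is kept, so zero-σ augmentation is an identity
up to the OD round-trip, and background-only images pass through
unchanged.

## Inference conventions

Unvisited (non-tissue) heatmap cells are probability 0 — conservative,
since only tissue patches are ever classified.  Binary masks use the
≥ 0.5 tie rule.  The refiner consumes the smallest stored plane with both
dimensions ≥ its input size, normalized to [0, 1]; the channel order
(R, G, B, heatmap) is fixed and recorded with saved models.  The Otsu
baseline thresholds the saturation image of the low-resolution plane with
the 256-bin between-class-variance rule; a constant image yields an empty
mask.

## Evaluation

Recall, precision and DSC per slide, with ground truth resampled to the
prediction geometry by nearest neighbour (evaluation is fixed at the
annotation resolution, downsample 4, and recorded in the report).
Aggregation is the unweighted mean and population (ddof 0) SD, overall and
per grade.  Degenerate conventions for synthetic tests: empty ground truth
and empty prediction score 1 everywhere; empty ground truth with a
non-empty prediction scores recall 1, precision 0, DSC 0.

## Synthetic cohorts

The generator emulates the properties the pipeline depends on, not
photorealistic histology: near-white background, smooth tissue blobs with
eosin-pink stroma texture, hematoxylin-purple nuclear speckles (denser
inside the tumor, increasing with grade), sparse low-saturation fat
vacuoles, and a contiguous tumor sub-blob.  Tissue and tumor area
fractions are enforced by quantile-thresholding smooth Gaussian random
fields, so the configured ranges hold by construction and the ground
truth is exact.  Defaults: 2048² base at ×100 magnification (so ×100
patches read directly from level 0), 4 pyramid levels, tissue fraction
0.30–0.55 of the slide, tumor 0.25–0.55 of tissue, annotations exported at
downsample 4 by per-block majority vote (ties → foreground, approximately
area-conserving).  Everything is a pure function of the seed.

What passing on synthetic data does **not** show: robustness to scanner
and stain batch effects, tissue-type diversity (necrosis, in-situ lesions,
mucin), annotation noise, or true gigapixel scale.  The synthetic cohort
validates the machinery — geometry, sampling law, losses, training
mechanics, design ordering — not clinical performance.

## Desk-scale study conditions

The end-to-end experiment uses 16 slides (12 train / 4 held-out), a
5-epoch × 20-batch × 32 classifier schedule, and a depth-7 / 256² refiner
with filters (4, 8, 16, 16, 32, 32, 64) trained up to 60 epochs with
patience 10 — sizes chosen so the whole study runs in minutes on one CPU
while still reproducing the qualitative ordering refined > patch-wise >
tissue-baseline.  Absolute Dice values at this scale are not comparable to
a full-scale clinical study.

## Known limitations

- The NumPy networks are CPU-bound and desk-scale; the architecture
  contracts (not throughput) are the point.
- `read_region` decodes whole stored levels lazily rather than individual
  tiles; exact and thread-safe, but not suited to true gigapixel slides.
- Tukey-type significance testing across designs is out of scope; the
  report keeps per-WSI metrics so external tools can run it.
- The stored level set of real converted TIFFs varies by converter; the
  smallest-finer-level-then-resize rule makes patch extraction exact
  regardless, but is a package convention.
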