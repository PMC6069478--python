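# Methods

`weedmap` implements a semantic-labeling pipeline for early-season weed
mapping in paddy fields: every pixel of an RGB tile is assigned to one of
three classes — *others* (soil/water), *rice*, *weeds* — so that a herbicide
applicator can be dosed only where weeds occur. The pipeline is
network → bilinear upsampling → fully connected CRF, with a pixel-based SVM
and an FCN-8s-style skip network as comparison baselines.

## Segmentation networks

The trunk is a residual (bottleneck) or VGG-style image classifier adapted
to dense prediction. A classification trunk downsamples by 32; upsampling a
1/32 score map back to full resolution destroys spatial detail. The adapted
trunks therefore set the strides of the last two downsampling layers to 1,
giving an output stride of 8 (a 1000 × 1000 tile yields a 125 × 125 score
map), and replace the standard convolutions of the affected stages with
*atrous* (dilated) convolutions — rate 2 in the fourth stage, rate 4 in the
fifth — so each filter keeps the field of view it had before the strides
were removed. A K × K kernel at rate r covers (K − 1)(r − 1) + K pixels per
side while its parameter count and multiply count are unchanged.

The classifier head is replaced by a score head of one or more parallel
dilated 3 × 3 convolutions mapping the final features directly to 3 class
channels ("ASPP" head; presets: single rate-1 branch, single rate-12
branch, small rates {2, 4, 8, 12}, large rates {6, 12, 18, 24}). Branch
outputs are fused by elementwise sum, which preserves the class
dimensionality and makes the single-branch case an ordinary score layer.
No nonlinearity follows the head: it is a linear score layer, and no 1 × 1
convolutions are appended after it. The coarse score map is restored to
full resolution by parameter-free bilinear interpolation (half-pixel
centers, i.e. align-corners disabled — fixed so results are
bit-reproducible) and per-pixel softmax yields the class probabilities.

Spatial sizing uses a "same, ceil-mode" convention: a stride-s layer maps a
side of n pixels to ⌈n/s⌉, so 1000 → 500 → 250 → 125 exactly and odd sizes
round up. Two knobs — `width_scale` (channel multiplier) and `block_counts`
(stage depths) — let the full topology run at desk scale; neither affects
spatial behaviour, and the defaults reproduce the full-width 101-layer
layout (stage depths 3, 4, 23, 3).

The networks run on a small CPU tensor-network engine (`weedmap.nn`):
im2col-based dilated convolution, max pooling, ReLU, bilinear resampling
and softmax/cross-entropy, each with an explicit backward pass verified by
finite differences. Exact direct-summation convolution
(`dfcn.atrous_convolve`) serves as the independent reference for the
layer-level convolution in tests.

### Training

Training minimizes mean per-pixel cross-entropy. By default the loss is
computed at full resolution — score maps are bilinearly upsampled and
compared to the ground truth, matching the inference path; a faster
`loss_resolution="score"` mode compares against nearest-pixel-downsampled
labels instead. Optimizers: momentum SGD (default, lr 1e-3, momentum 0.9 —
conventional fine-tuning values, recorded in `TrainConfig`) and Adam. No
data augmentation and no class weighting are applied by default; the scene
generator controls class balance instead. Checkpoints are flat
name → tensor maps; `load_weights(strict=False)` copies matching tensors
and reports skipped/missing ones, which is the warm-start (transfer)
interface for initializing a model from weights trained on a different
distribution or with a different head.

## Fully connected CRF

Striding and pooling blur spatial detail; the CRF restores it. Every pixel
pair (a, b) interacts through

    k(a,b) = w1·exp(−‖p_a−p_b‖²/2σ_α² − ‖I_a−I_b‖²/2σ_β²)
           + w2·exp(−‖p_a−p_b‖²/2σ_γ²)

with positions p in 0-based pixel units and colors I in raw RGB 0–255
(pinned so the bandwidths are meaningful). The appearance kernel pulls
nearby similar-colored pixels toward one label; the smoothness kernel
removes isolated noise. The energy of a labeling x is

    E(x) = Σ_a θ_a(x_a) + Σ_{b<a} μ(x_a, x_b)·k(a,b),   θ_a = −log P(x_a)

with Potts compatibility μ = 1 iff the labels differ, so disagreement
between similar pixels is penalized under energy minimization. Unaries
clamp probabilities at 1e-8 before the log (−log 0 is undefined). The Gibbs
normalizer is never computed: all algorithms compare energies only.

Inference is mean-field: a factorized Q initialized at softmax(−θ) is
iterated (default 10 times) with the Potts-reduced message
m_a(l) = Σ_{b≠a} k(a,b)(1 − Q_b(l)) and update Q_a ∝ exp(−θ_a − m_a).
Updates are synchronous by default; a sequential raster-order sweep (the
variant whose KL objective is monotone) is available. Pair sums are exact
and dense, O(N²) — a correctness-first choice; a size cap (default
128 × 128 pixels) raises an explicit error directing larger inputs to
tiling. Defaults w2 = σ_γ = 1 follow the standard dense-CRF setup; w1, σ_α,
σ_β are searched per dataset by `grid_search_crf` (default grid
w1 ∈ {1,2,5,10}, σ_α ∈ {3,10,30}, σ_β ∈ {3,10,30}), exhaustively scoring
refined labelings on labeled training tiles with ties to the first
candidate in grid order.

A brute-force enumerator (`exact_map_bruteforce`, ≤ 10⁶ states,
lexicographic tie-break) provides the exact MAP for tiny instances; tests
check that energies match full enumeration and that mean-field argmax
recovers the exact MAP in ≥ 95/100 random 2 × 2 strong-smoothing problems
and stays within a few percent of the optimal energy at moderate pairwise
strength (mean-field is a local method: under very strong coupling it can
settle in labelings a few percent above the optimum, which is why the
energy-gap check uses moderate weights while the MAP-agreement check uses
strong smoothing).

## Metrics and baselines

All metrics pool pixels into a single ground-truth-by-predicted confusion
matrix over the evaluated set (not per-image averages). Per-class
IU = TP/(TP+FP+FN); mean IU averages over classes present in the ground
truth (absent classes are excluded and flagged, avoiding 0/0); overall
accuracy is the diagonal fraction; kappa is Cohen's chance-corrected
agreement. The pixel baseline is an RBF-kernel C-SVC on raw RGB triples:
pixels from the training tiles are pooled, stratified-subsampled (default
50 000 — full-pixel SVM training is computationally prohibitive and the
subsample saturates accuracy on color-separable data), and C is selected by
3-fold cross-validated grid search. `compare_methods` tabulates pooled
metrics for named predictors plus informational per-image wall time.

## Synthetic scenes

The generator emulates the statistical structure the pipeline assumes in
UAV imagery of a sown paddy field at early tillering: vertical crop rows
with smooth lateral jitter (sown-row geometry), weed patches as unions of
2–5 random ellipses morphologically closed into irregular blobs, placed
uniformly so they fall both between and inside rows and overwrite rice
where they do; per-class mean colors with overlapping rice/weed greens;
low-frequency Gaussian-filtered texture plus white sensor noise. The label
map is exact by construction, and every patch's ellipse primitives are
logged so tests can re-rasterize and count placements independently.

Defaults (chosen once as a realistic desk-scale condition): 256 × 256
tiles; row period 42 px and row width 16 px (50 cm row spacing at ~1.2
cm/px, a 4× coarsening of a 0.3 cm/px survey); 6–14 patches of radius 2–18
px — the 2 px minimum keeps very small patches, the hardest detection case,
in every dataset; mean weed cover ≈ 6 % with tile-to-tile spread
~2–10 %, a moderate natural infestation; color noise sd 8 of 255 with
texture scale 6 px. All randomness derives from the config seed; identical
configs are bit-identical. What the scenes do *not* model: perspective and
orthomosaic seams, leaf-level texture, shadows, illumination gradients,
growth-stage variation. Passing tests therefore demonstrate that the
pipeline's machinery is correct and recoverable on data with the assumed
structure, not field-level accuracy on real imagery.

## Problem sizes in the test suite

Tests run the full topology at reduced width/depth: 256 px default tiles
(1000 px paths covered by shape tests), a width-scale-1/8, depth-(1,1,2,1)
network for the 4-tile 128 × 128 overfit-recovery check (150 Adam epochs,
lr 2e-3), 48 px tiles for CRF refinement fixtures, and ≤ 2 × 3 grids for
exact-enumeration oracles. These sizes were chosen so the whole suite runs
comfortably on one CPU while still exercising every code path at the
survey-scale geometry where shape arithmetic matters (1000 → 125).

## Known limitations

- The dense CRF is exact but O(N²); refining full 1000 × 1000 tiles
  requires tiling (the cap enforces this). No lattice/bilateral-grid
  acceleration is provided.
- The FCN-8s skip variant supports inference and evaluation only; its
  training path is not implemented.
- The engine is float64 NumPy on one CPU: correct and reproducible, not
  fast. Full-width 101-layer training is out of reach by design; the
  architecture is validated structurally and at scaled width.
- The exact dilation rates for the adapted VGG stages are a configuration
  choice (rate 2 in the fifth stage) rather than a published constant, and
  are recorded in the spec object, not hard-coded.
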