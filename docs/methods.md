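# Methods

`histoseg` segments grey matter (GM), white matter (WM) and slide
background in RGB histology images and stratifies amyloid-deposit counts
by the resulting compartments.  This note records the models, the
numerical choices, and what the synthetic test-bench does and does not
establish.

## Patch-based segmentation

Pixel-wise segmentation of very large slide scans is recast as patch
classification: a 256×256 RGB patch is labeled with the class of its
**central pixel** in the ground-truth mask, a residual CNN maps the patch
to three class scores, and a sliding window at stride *s* paints each
window's predicted class onto the central *s*×*s* block, which tile the
image exactly.  Smaller strides trace boundaries more finely at
proportionally higher inference cost; *s* = 128 is the segmentation
default, and deposit heatmaps use *s* = 16.  Windows are centered at
`k·s + s/2`; the image is reflection-padded so every window is fully
defined, and `ceil(dim/s)` windows cover each axis.

Class imbalance is handled with inverse-frequency weights on the
cross-entropy loss, normalized so the smallest weight is 1 (a corpus of
roughly 310k GM / 100k WM / 300k background patches yields weights that
round to 1:3:1 for GM:WM:background).  Training uses Adam at learning
rate 1e-3, batch size 16, random flips/right-angle rotations, and keeps
the per-epoch checkpoint with the best validation accuracy.

### Backbone

The environment provides no GPU deep-learning stack, so the network and
its training loop run on an in-repo reverse-mode autodiff engine over
numpy arrays (`histoseg.nn`): im2col convolutions, average pooling,
linear layers, weighted cross-entropy and Adam, all gradient-checked
against finite differences in the test suite.

The default backbone is deliberately tiny: a parameter-free 8× average-
pool stem (256→32 px), a 3×3 conv, two residual stages (8 and 16
channels) whose skip connections are 1×1-convolution projections, and a
linear 3-way head.  The patch **embedding** — the descriptor the CRF
layer consumes — concatenates the global average pool of the last stage
with a 2×2 center pool of the same activations (embedding length 32).
The center component exists because the label is defined by the *center*
pixel: a purely global descriptor is location-blind, and near GM/WM
boundaries it cannot tell which side the center falls on; with it,
held-out accuracy on the default synthetic textures saturates near 1.0
instead of ~0.91–0.95.  The stage count/widths are configurable; nothing
in the pipeline assumes the tiny scale.

## CRF spatial smoothing

Sliding-window labels are independent across windows, so isolated
misclassifications produce speckle.  The smoothed variant places a
conditional random field over a g×g grid of windows (default 3×3, g odd).
With labels x_i ∈ {background, GM, WM} and embeddings I_i, the Gibbs
energy is

    E(x | I) = Σ_i ψ_u(x_i | I_i) + Σ_{i<j} ψ_p(x_i, x_j | I_i, I_j)
    ψ_u = −log softmax(classifier logits)
    ψ_p = H(x_i = x_j) · w_ij · (1 − cos(I_i, I_j))

with w_ij ≥ 0 a symmetric coupling matrix (default: 1 on 4-neighbor
pairs, 0 elsewhere).  As printed, the indicator fires on label
*agreement*: agreeing on dissimilar patches costs, disagreement is free.
Under that convention certain neighbors *repel* agreement on dissimilar
patches but never penalize disagreement, which is not a smoothing prior;
the complementary convention (`indicator_mode="different"`, cost for
disagreeing on similar patches) is the standard smoothing form.  Both are
implemented; the printed form is the default, and the property tests
exercise each where its qualitative behavior is well defined.

Marginals are approximated by mean field: Q(X) = Π_i Q_i(x_i) minimizing
KL(Q‖P), initialized at the decoupled softmax (exact when w ≡ 0) and
iterated by sequential coordinate updates

    log Q_i(x_i) ∝ −ψ_u(x_i) − Σ_{j≠i} w_ij (1 − cos(I_i,I_j)) Q_j(x_i)

until the largest row change falls below 1e-6 or 10 sweeps elapse.  Each
sequential update is the exact coordinate minimizer, so KL(Q‖P) is
non-increasing; the suite verifies this against a brute-force enumeration
of the Gibbs joint on all grids with N ≤ 9 (the enumeration oracle
refuses larger grids).  A parallel update schedule is available for speed
but carries no monotonicity guarantee (it is, however, exactly
permutation-equivariant, which the suite uses).  A window's final label
is the argmax of the central patch's marginal over its g×g neighborhood
(edge windows reflect their neighbor indices); with w ≡ 0 this reduces
bit-for-bit to the plain argmax.  An unrolled autodiff variant of the
sweeps exposes gradients of the marginal cross-entropy with respect to
the logits (finite-difference-checked), so the layer is trainable end to
end.  The number of sweeps is not externally prescribed; 10 with tol 1e-6
converges on every grid the bench generates.

## Morphological refinement

The plain pipeline cleans its masks by: 4× per-axis nearest-neighbor
downsampling; area openings on the GM then the WM layer removing
8-connected components with area < 20,000 downsampled px; an area closing
assigning background islands < 12,500 px to the largest adjacent tissue
component; removal of tissue components smaller than 5% of the raster
area (detached fragments and residues); a disk opening of radius 8 on
each tissue layer; nearest-neighbor upsampling back.  All thresholds are
strict inequalities and are probed at ±1 px in the tests.  The absolute
area values are calibrated to full slide scans (~50,000×60,000 px); they
are implicit area *fractions*, so `scaled_params()` rescales them for
desk-scale rasters (areas with raster area, disk radius with linear
size).  "5% of the slide area" is read as the full raster area, not the
tissue area; a switch selects the alternative.  Connectivity is
8-connected throughout and configurable.

## Annotation export

Mask boundaries are exported per connected component as outer polygons
(marching squares at the 0.5 level on the padded binary layer, orientation
normalized counter-clockwise in the image frame, coordinates scaled to
level 0) and written in the de-facto ImageScope XML schema
(Annotations/Annotation/Regions/Region/Vertices/Vertex with integer X/Y).
GM is drawn cyan, WM yellow.  Boundary "downsampling by 50×" is
implemented as vertex decimation (keep every 50th vertex, first vertex
always kept, minimum 3); write→parse is the identity on regions, classes
and (rounded) vertices.  Holes are not exported — outer contours only.

## Deposit quantification

A pluggable deposit classifier maps a 256×256 patch to three independent
confidences in [0,1] (cored, diffuse, CAA — multi-label).  Sliding it at
stride 16 yields three heatmaps at 1/16 resolution, thresholded per type
(default 0.5 each, configurable; values at the threshold count as
detections) and blob-labeled with 8-connectivity.  Counting is
stratified by the segmentation at the same stride, which keeps the two
rasters shape-congruent:

* **blob mode** (headline): one count per blob, assigned to the GM/WM
  label under the blob centroid; centroids on background are dropped and
  logged.  An alternative assigns by majority vote over blob pixels.
* **patch mode**: the literal per-window accumulator — every
  supra-threshold window adds a one-hot increment.  On overlapping
  detections patch mode counts windows, not deposits; the discrepancy is
  intentional and documented here.

The result is a 1×6 vector (type × region) plus a provenance table.  No
trained deposit model ships with the package: the contract is exercised
by a synthetic oracle backed by the generator's ground truth, and any
classifier satisfying the contract can be plugged in.  Large slides can
be streamed in 1536×1536 tiles with stride-aligned overlap.

## Saliency maps

Grad-CAM on the patch classifier: the gradient of a class score w.r.t. a
convolutional block's activations (default the last; `layer` selects
others) gives channel weights; the rectified weighted activation sum is
normalized to [0,1] (all-zero maps short-circuit the normalization) and
bilinearly upsampled to patch size.

## Synthetic test-bench

The generator renders a desk-scale analogue of a cortical section:
background margins, a GM ribbon over a WM band with a gently curved
boundary (target GM:WM area ratio 2:1 by default, within the 3:1–1:1
range of real sections), textures chosen so class identity is carried by
texture — near-white low-noise background; darker GM base with dense
isotropic cell speckle; lighter WM base with oriented fiber striations —
with median local variance ordered background < WM < GM by construction.
Deposits are planted with Poisson counts per (type, region) (defaults:
cored 6/1, diffuse 8/1, CAA 2/0.5 in GM/WM), radii 6–14 px, drawn as
dense brown disks (cored), larger faint blotches (diffuse) and annuli
(CAA), entirely inside their region by erosion of the candidate area.
Artifacts (detached fragments, speckles) are grown as connected
tissue-colored components of exact pixel area on background only.
Everything is deterministic given the layout and texture seeds.

What the bench does **not** establish: real staining variability, scanner
pyramids, stain deconvolution, tissue folds with partial transparency, or
realistic deposit morphology.  Passing the bench shows the *pipeline
contracts* hold (reconstruction exactness, threshold boundaries, count
recovery, CRF correctness), and that the textures are learnable — not
that the tiny backbone would segment real tissue.

A specific consequence: the qualitative claim that a well-trained model's
saliency ignores deposits and concentrates on texture does not
reliably transfer to this bench.  With default rates deposits sit mostly
in GM, so they are legitimately class-informative; even with rates
equalized across regions, the tiny backbone's CAM cells (32 px) exceed
deposit radii and a dark blob always perturbs the activations it covers
(measured mean matched-control-minus-deposit saliency differences
straddle zero across seeds).  The suite therefore verifies saliency
mechanics (range, degenerate inputs, localization with a constructed
single-filter model, layer selection) and leaves the texture-dominance
claim as a statement about real tissue models only.

## Problem sizes and determinism

The bench runs at sizes a laptop CPU handles in minutes: 640²–1024²
slides, 1,500 training patches, ≤ 10–12 epochs, 5 slides for
reconstruction/quantification/export checks, 20 random CRF instances,
3 training seeds with majority voting for the stochastic end-to-end
check (held-out accuracy ≥ 0.95, refined mean IoU ≥ 0.85).  One integer
seed drives every RNG (layout, textures, sampling, initialization,
shuffling, augmentation); identical seeds give byte-identical synthetic
data and training trajectories.

## Known limitations

* The printed pairwise indicator does not implement a smoothing prior
  (see above); smoothing behavior requires `indicator_mode="different"`.
* Patch mode over-counts deposits that fire in several windows; blob
  mode under-counts deposits merged into one blob (separation below
  2× stride).
* Area-threshold semantics are stated in downsampled pixels; masks whose
  downsample factor differs from 4 need `areas_at_full_resolution`.
* The tiny backbone is a contract-scale model; real-tissue use calls for
  a deeper backbone and a real training corpus, plugged in through the
  same interfaces.
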