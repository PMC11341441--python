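# Methods

## Problem and model

Yellow sticky traps photographed in the field carry mostly *tiny* insect
pests: in the survey this package follows, 80.4% of labelled objects had
both sides ≤ 32 px ("tiny") and 28.7% had both sides ≤ 16 px ("very
tiny"), with no object exceeding 40 px per side.  Standard single-stage
detectors lose these objects because repeated down-sampling strips the few
pixels of evidence they carry.  The detector implemented here counters
that with two backbone modifications:

1. **FM-SR (feature-map super-resolution).**  The deepest pyramid map P5
   (stride 32) is reconstructed to the spatial size of P3 (stride 8), a
   fixed ×4 magnification.  The module is an SPPCSPC front-end (parallel
   stride-1 max-pools with kernels 1/5/9/13 in a cross-stage-partial
   block), a stack of SRResNet-style residual units (5 by default:
   conv–BN–PReLU–conv–BN plus identity), a long skip that adds the body's
   input back onto its output, and two sub-pixel (depth-to-space) ×2
   stages followed by a 1×1 projection to P3's channel width.  There is no
   super-resolution-specific objective or pretraining; gradients arrive
   only from the detection loss.

2. **BiFormerAF (gated attention fusion).**  The reconstructed map SRP5
   is fused with P3 without increasing channel count:

       Y     = C2f(P3)
       X0    = BiFormer(C2f(SRP5))
       X1    = sigmoid(BatchNorm(X0))
       NewP3 = Y + X0 ⊙ X1

   The BiFormer stage is a single block — depth-wise 3×3 positional
   convolution, then pre-norm residual **bi-level routing attention**
   (BRA), then a pre-norm residual MLP (expansion 3).  BRA partitions the
   map into S×S regions, computes a region-to-region affinity from the
   per-region mean query and key (`Ar = Qr·Krᵀ`), keeps the top-k regions
   per row, gathers their key/value tokens and runs ordinary scaled
   dot-product multi-head attention of each query over only the gathered
   tokens, adding a local-context term: a depth-wise 5×5 convolution of
   the value tensor.  With k = S² this reduces exactly to dense attention,
   which is the main correctness oracle in the tests.

The fused NewP3 re-enters the unchanged stride-16 and stride-32 backbone
stages to produce NewP4/NewP5, which replace P4/P5.  A PAN-style neck and
an anchor-free decoupled head (per-cell sigmoid class scores and softplus
left/top/right/bottom distances in stride units) finish the network.  Box
regression uses the complete-IoU loss

    L = 1 − IoU + ρ²(b, b_gt)/c² + αv,
    v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²,  α = v/((1 − IoU) + v),

with α treated as a constant under backpropagation.  Classification is
binary cross-entropy per cell and class; both terms are normalised by the
number of positive cells.  Positive cells are those whose centre falls
inside a ground-truth box (nearest box centre on ties); a box too small
to contain any cell centre is assigned the nearest P3 cell, so even 4-px
objects train.

## Design choices where the architecture was open

- **Tensor layout** is channel-first `(B, C, H, W)` throughout;
  region tensors are `(B, S², HW/S², C)` with row-major tokens.
- **Attention scaling** is `1/√(C/heads)`; heads default to 4 and split
  the channel axis.  Region counts that do not divide the map size are a
  hard error — no silent padding.
- **Routing means** are taken over Q and K (the coarse affinity is a
  query–key product; there is no meaningful key-side role for V).
- **Skip placement in FM-SR** follows the SRResNet convention: a trailing
  conv–BN after the residual stack, then the long skip, then upsampling.
  Sub-pixel upsampling was preferred over transposed convolution to avoid
  checkerboard artefacts.
- **Fusion depth**: one BiFormer block; the two C2f branches do not share
  weights.  The gate's batch norm uses learnable affine parameters
  (momentum 0.1), since its purpose is to stabilise the distribution fed
  to the sigmoid.
- **Head/assigner**: distribution-focal-loss and task-aligned assignment
  are deliberately out of scope; the centre-prior assigner with CIoU+BCE
  is sufficient at this scale and is fully testable.
- **NewP4/NewP5 weights**: the original stride-16/32 stage modules are
  re-applied on the NewP3 path (no fresh copies); the pyramid used for
  detection is NewP3/NewP4/NewP5.
- **NMS** is per-class greedy, IoU 0.5, confidence threshold 0.25.
- **Evaluation** is mAP@0.5 with all-point (monotone-envelope)
  precision–recall interpolation, pooled over images.  0/0 precision and
  recall are defined as 0; classes without ground truth are excluded from
  the mAP mean.  Size-stratified evaluation keeps ground truths of one
  size class; detections matched to out-of-class objects are ignored, and
  unmatched detections count in the stratum of their own predicted size,
  so the three strata exactly partition the unstratified counts.

## Numerical substrate

No deep-learning framework is used.  `srnetyolo.nn` is a small
reverse-mode autodiff library over NumPy: convolution via im2col and BLAS
matmul (grouped, covering the depth-wise case), stride-1 same-padded max
pooling for the SPP block, batch/layer norm, sub-pixel rearrangement, and
SGD with momentum 0.937, weight decay 5e-4 and cosine learning-rate decay
from lr0 to lr0·lrf.  All gradients are verified against central finite
differences in float64 in the test suite.  Training and inference are
deterministic for a fixed seed on CPU.

## Synthetic scenes

The real trap dataset is not public, so a seeded generator emulates its
statistical structure: a yellow textured background (base RGB ≈ (212,
180, 40), Gaussian texture noise σ=8, a random-direction illumination
gradient), two pest classes rendered as anti-aliased dark ellipses — an
elongated brown thrips-like shape and a rounder dark-green aphid-like
shape — and unlabeled grey distractor specks (Poisson mean 10 per 640-px
scene) so that precision is non-trivially exercised.  Pest counts are
Poisson (mean 12 per 640-px scene); box sizes follow the surveyed
mixture — 28.7% very tiny, 51.7% tiny-but-not-very-tiny, 19.6% larger —
with a hard 40-px cap and a 4-px floor.  Boxes never overlap (real pests
stuck to a trap rarely do) and ground truth is exact by construction.
Layout and texture come from independent child streams of the seed, so
annotation statistics can be computed without rendering.

What the generator does **not** model: photographic blur and exposure
variation, insect appendages/pose, partially decayed specimens, trap
borders and grid lines, occlusion.  Passing tests therefore demonstrate
that the architecture, losses, data pipeline and evaluator are correct
and that the detector learns the synthetic task end to end — not that
field-accuracy numbers transfer to real traps.

## Data pipeline conventions

Internal boxes are 0-based half-open pixel rectangles; Pascal-VOC XML
(1-based inclusive corners, LabelImg-style) is converted only at the file
boundary, and YOLO txt rows are centre/size normalised to [0, 1].  Size
classes use the both-sides rule with inclusive boundaries: very tiny iff
w ≤ 16 and h ≤ 16; tiny iff w ≤ 32 and h ≤ 32.  Tiling cuts 640-px tiles
at stride 600 (40-px overlap, matching the 40-px object cap), clamping
the last origin to the image edge; boxes straddling a tile boundary are
dropped from that tile rather than clipped — the overlap guarantees every
box survives whole in some tile, and duplicates across overlapping tiles
are retained as independent samples.  Size-stratified test sets keep
tiles whose every box is tiny (test B) or very tiny (test C), giving
C ⊆ B ⊆ A.  Down-scaling uses area-averaging (box-filter) resampling with
boxes rounded outward (a 130-px box at scale 31/130 becomes exactly
31 px).

## Problem sizes used in the checked runs

Full-scale defaults (640-px images, 1000 epochs, batch 32, lr0 0.001)
describe the intended production run and remain the documented defaults.
The verified desk-scale runs that the test suite and
`scripts/acceptance.py` execute use: 160-px scenes (Poisson mean 6
pests), width multiplier 0.125, depth multiplier 0.33, S=4, k=4, 2 heads;
64 training / 24 held-out images, 25 epochs, batch 8, lr0 0.01 with
cosine decay to 5%, 10 warm-up steps.  The ablation comparison uses
96-px very-tiny-only scenes, 24/12 images, 14 epochs, three seeds.
These sizes are the package's chosen reference configuration for
single-CPU reproducibility; mAP on the held-out synthetic split reaches
roughly 0.55–0.7 depending on seed, and the full model beats the plain
backbone on the very-tiny split in the checked seeds.

## Known limitations

- The NumPy engine is single-threaded-BLAS bound; full-scale (640 px,
  width 0.25) training is out of reach on one CPU.
- The assigner is deliberately simple; crowded scenes with heavily
  overlapping objects would benefit from task-aligned assignment.
- Whole-image inference over tiled mosaics (stitching detections across
  tiles with cross-tile NMS) is not implemented.
- Absolute metric values on the real dataset are not reproducible here —
  the dataset is private and the original evaluator's IoU threshold and
  interpolation rule are unspecified.
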