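# Methods

This note documents the models implemented in `maizedet`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Detection model

The detector is a two-stage (Faster R-CNN-style) network with two
non-standard components.

**Deformable convolution** (`maizedet.backbone`).  For output location ℓ₀
and kernel tap set Ω (a 3×3 grid unless configured otherwise),

    y(ℓ₀) = Σ_{ℓₙ∈Ω} w(ℓₙ) · x(ℓ₀ + ℓₙ + Δℓₙ),

with one learned 2-D offset pair Δℓₙ per tap, shared across input channels
(no per-tap modulation scalar — that belongs to a different extension of
the idea, deliberately out of scope).  Fractional positions are evaluated
with the separable bilinear tent kernel

    G(k, ℓ) = max(0, 1 − |kₓ − ℓₓ|) · max(0, 1 − |k_y − ℓ_y|),

with pixels outside the grid contributing zero (the kernel's own support
makes this zero padding).  Offsets come from an ordinary 3×3, stride-1,
pad-1, dilation-1 convolution over the same input, so the offset field has
exactly the spatial size of its input.  Gradients flow to the weights, the
input, *and* the sampling locations; the tent kernel is piecewise linear,
so the location gradient is the difference of neighbouring pixel values.
The finite-difference checks in the test suite avoid integer-valued
sampling locations, where the kernel has corners and the two one-sided
derivatives differ (training is unaffected: exact integer hits after a
gradient step have measure zero, and at the zero-offset initialisation the
subgradient the implementation returns is a valid descent direction).

Offset convolutions are **zero-initialised**: a freshly built deformable
network is numerically identical to its regular counterpart, which both
stabilises early optimisation and gives the test suite an exact
equivalence to assert.  Which residual stages are deformable is
configurable; the default is C3–C5, the common practice for deformable
residual networks.  The backbone registry offers `tiny` (used in all
desk-scale experiments), `resnet18` and `resnet50` layouts; residual
blocks are two 3×3 convolutions with a projection shortcut where shape
changes, without batch normalisation (training here is single-image, where
batch statistics are meaningless; weights use He initialisation instead).

**Attention-weighted pyramid** (`maizedet.pyramid`).  Backbone stages
C2–C5 (strides 4–32) are projected to a common width d by 1×1
convolutions; levels fuse top-down as

    Pᵢ = Bᵢ(Xᵢ) + α ⊙ F_up(Pᵢ₊₁),

where F_up is 2× nearest-neighbour upsampling and α is generated from the
upsampled map by 1×1 conv → ReLU → 3×3 conv → sigmoid.  Each fused level
passes a final 3×3 smoothing convolution (anti-aliasing), and P6 is a
stride-2 max-subsampling of P5, giving five outputs P2–P6.  Open points
and the choices made:

- *Is α a scalar or a map?*  "Weight maps" suggests spatial; the default
  is a single-channel per-pixel map broadcast over channels, with a
  per-channel (d-channel) variant behind `attention_channels=d`.
- *Pyramid inputs.*  The source description is ambiguous between laterals
  from five stages and "P5 and P6 obtained by twice subsampling".  The
  default is the standard FPN layout (laterals C2–C5, P6 subsampled from
  P5); `literal_subsample_variant=True` gives the literal reading
  (laterals C2–C4, P5 and P6 both subsampled).
- *Generator width.*  Unspecified; default d/4 between the two
  convolutions.
- Since the sigmoid is strictly inside (0, 1), exact plain-FPN behaviour
  (α = 1) is unreachable by the generator; the `alpha_bypass` flag forces
  α ≡ 1, and the equivalence against an independently coded plain FPN is
  asserted to < 1e-5 max-abs in the tests.

**Assembly** (`maizedet.detector`).  An RPN head (3×3 conv, then 1×1
objectness and 1×1 box-delta convolutions, shared across levels) scores
anchors of size `scale × stride` at configurable aspect ratios.  Proposals
decode standard (dx, dy, dw, dh) log-space deltas (dw, dh clipped at ±4),
are clipped to the image, filtered to ≥ 1 px, merged by greedy NMS at 0.7
and capped at `max_proposals`.  RoIs pool from the pyramid level chosen by
the usual scale heuristic k = ⌊k₀ + log₂(√(wh)/s₀)⌋ via RoI-Align (one
bilinear sample per output bin), and a two-FC head emits exactly c+1 class
scores and 4c class-specific deltas.  Training follows the standard
recipe: binary cross-entropy over a 256-anchor sample (positives ≥ 0.7 IoU
or best-per-ground-truth; negatives < 0.3), smooth-L1 (β = 1/9) on positive
anchors, cross-entropy and smooth-L1 (β = 1) over a sampled RoI batch in
which the ground-truth boxes are always included (this stabilises the
region head before the RPN produces usable proposals).  The four losses
are summed unweighted.  Optimisation is SGD with momentum 0.9 and
global-norm gradient clipping at 10.

One integer seed controls parameter initialisation, data order and target
sampling; per-epoch RNG streams are keyed by (seed, epoch) and checkpoints
carry the momentum buffers, so resumed runs continue bit-exactly.

## Evaluation protocol (`maizedet.metrics`)

Boxes are center-form (cx, cy, w, h, class, score) and converted to
half-open corner form in continuous pixel coordinates for area arithmetic
(this removes the ±1 px ambiguity of inclusive pixel coordinates).
Matching is greedy in descending confidence, ties broken by input order;
each ground truth is consumed at most once; a detection is a true positive
iff its best IoU against a still-free ground truth is **strictly greater
than** 0.5.  The strict inequality follows the stated definition of the
protocol this package implements; most public tooling uses ≥, and a flag
(`inclusive=True`) provides that.  AP integrates the monotone-envelope
precision/recall curve at every recall change (the VOC2010 "all-point"
convention) — the interpolation variant is not fixed by the protocol's
prose, and all-point is the closer reading of "area under the curve"; the
11-point variant is selectable.  Reported per-class recall is the final
point of the PR sweep (every detection accepted), which is how recall/AP
pairs are conventionally tabulated.  mAP is the unweighted class mean.

## Data handling (`maizedet.voc`)

VOC XML corners are treated as continuous positions: a box with
xmin=10, xmax=30 has width 20 and center 20.  (The 1-based-inclusive
reading would give width 21; the continuous reading keeps integer files
byte-losslessly round-trippable and matches the center-form annotation
convention this toolkit uses in memory.)  `split_dataset` draws a seeded
permutation and takes ⌊f·N⌋ training items — for N = 7392 and f = 0.9 that
is 6652 + 740; note that a 6653/740 split of 7392 images is arithmetically
impossible, so the floor rule is applied uniformly.  "Relative size" is
the box-to-image **area** ratio by default (a `linear` √-area option
exists), since the term is used without definition in the field tables
this mirrors.

## Synthetic scenes (`maizedet.scenes`)

The generator renders class-keyed superellipse blobs with colour jitter
and speckle on a textured background.  It emulates, by construction, the
*statistical* failure modes that matter to the detector: relative box
areas sampled log-uniformly per class (the `imbalanced-table1` preset uses
per-class ranges [m/2, 2m] around published per-class mean relative sizes
spanning 0.007–0.306, and mixture weights proportional to the published
instance counts), occlusion via an IoU-capped placement rule applied with
a configurable probability, and density via the instances-per-image range.
Object placement uses bounded rejection sampling (40 tries; unplaceable
objects are skipped with a log entry).  Every annotation is recomputed
from the rasterised mask, so boxes are tight to the drawn pixels within
one pixel.  One RNG stream is spawned per image from the dataset seed, so
datasets are bitwise reproducible and single images can be regenerated.

What the generator does **not** emulate: real pest appearance, pose and
articulation, leaf self-similarity and camouflage, lighting, focus blur,
or annotation noise.  Passing the end-to-end test therefore shows that
the architecture, losses, matching and bookkeeping are implemented
correctly and can be optimised — it says nothing about accuracy on real
field imagery.

## Problem sizes and schedules

All experiments are sized for a single CPU core.  The end-to-end check
trains the `tiny` configuration (stage widths 16/24/32/32, pyramid width
32, 4×4 RoI pooling, 128-unit head, one deformable stage C3) on 200 easy
64×64 scenes (9:1 split) for 5 epochs of single-image SGD at lr 0.01 —
about half a minute — and requires the epoch-mean loss to fall and
held-out mAP@0.5 to reach at least 0.5 (3-seed median; in practice it
reaches ≈ 100%).  Oracle comparisons use 100–200 random draws
(convolution equivalence at 1×8×16×16, pyramid equivalence at width 6),
10,000 sampling locations, and 500–1000 random PR fixtures against a
20,000-point grid integration.  These sizes are stated here as the
package's own experimental design.

## Known limitations

- Single-image batches only; no batch normalisation or data augmentation.
- The autodiff engine is float64 and CPU-bound: the `resnet50` layout is
  constructible and correct but not practical to train here.
- The RPN shares one head across levels with per-level anchor sizes fixed
  by `scale × stride`; anchor-free heads, cascaded heads and modulated
  (v2) deformable convolution are out of scope.
- Greedy NMS and greedy matching are O(n²) in candidates — fine at these
  proposal counts.
- mAP is reported at IoU 0.5 only (no COCO-style threshold sweep),
  matching the protocol this package targets.
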