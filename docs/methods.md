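# Methods

## Model and assumptions

The package implements sample-positive (SP) contrastive pretraining for
patch-based histopathology.  Its single substantive assumption is the
*spatial-adjacency prior*: in non-diffuse cancers, tissue of one
histological type forms contiguous regions much larger than an analysis
patch, so two small patches sampled from the same large patch almost surely
share a tissue type.  The method therefore treats small patches from one
large patch as mutual positives and everything from other large patches as
negatives, and optimises the supervised-contrastive (SupCon) objective over
these pseudo-labels.  Where the prior fails — at region boundaries, or in
diffuse disease — positives are mislabelled and the method is expected to
degrade; the boundary-mixed ablation measures exactly this and is part of
the test surface.

For anchor i with candidate set A(i) = I \ {i} and positive set P(i):

    L = Σ_i (−1/|P(i)|) Σ_{p∈P(i)} log [ exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ) ]

`supcon_loss` evaluates this with a row-wise stabilised log-sum-exp and
defaults to the equation's sum over anchors (`reduction="sum"`); the
training loop uses the mean so that the learning rate is batch-size
invariant.  Embeddings are L2-normalised inside the projection path and the
loss entry point re-checks unit norm to 1e−5.  Two closed-form anchors pin
the implementation down: with a single positive pair and no negatives every
term is −log 1 = 0, and with all embeddings identical every dual-branch
per-anchor term is log(2MN−1).  The vectorized loss is tested against an
independent double-loop oracle and, for singleton positives, against a
separate InfoNCE implementation.

### Pair structure

For N large patches and M small patches each: dual-branch batches hold
2MN views with 2M−1 positives and 2M(N−1) negatives per anchor; the
single-branch variant holds MN views with M−1 and M(N−1).  `PairIndex` is
built purely from group ids, so these counts are combinatorial identities
and are tested exhaustively for M ∈ 2..6, N ∈ 2..8.

### Framework variants

* **spsimclr** — one encoder+projector embeds all views; SupCon over the
  full pair index.
* **spmoco_v3** — an exponential-moving-average target network embeds each
  augmentation set; the loss is a symmetrised cross-branch SupCon (online
  set-1 anchors against target set-2 candidates and vice versa), gradients
  blocked through the target, `θ_t ← m·θ_t + (1−m)·θ_o` after each step
  with m = 0.99 constant.  Implemented queue-free: negatives are in-batch.
* **spsimsiam** — a predictor head on the online branch regresses
  stop-gradient embeddings; the loss is the mean negative cosine over *all*
  SP positive pairs (the most literal extension of "more positives" to a
  distillation method — a genuinely open design point, since distillation
  with many positives risks representation collapse, and the variant is
  expected to underperform the contrastive ones).
* **sinclr** — single branch: one augmentation per crop, SupCon over the
  single-branch pair index.  Halves the augmentation and encoding cost per
  batch relative to dual-branch training.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| τ (temperature) | 0.1 | SupCon-family convention; smaller sharpens hard-negative weighting |
| M (crops per large patch) | 4 | ≥ 2 needed for sampled positives; 4 gives 3 within-group positives per single-branch anchor at modest cost |
| N (large patches per batch) | 8 | 28 single-branch negatives per anchor at desk scale |
| sampling mode | overlapping | uniform boxes; `nonoverlapping` adds pairwise disjointness via per-box rejection (≤ 100 retries), feasible only if M·s² ≤ L² and reliable only well below that bound |
| momentum m | 0.99 | EMA coefficient of the MoCo-style target |
| optimizer | Adam, lr 3e−3 | for the tiny CNN at desk scale; full-scale convention (SGD + cosine) is configurable |
| linear-eval protocol | Adam lr 0.05, ≤ 60 epochs, patience 8 on val macro-F1 | frozen encoder, single linear head, best checkpoint restored |

Augmentation defaults follow the SimCLR-family stack adapted to histology
(random resized crop, horizontal *and* vertical flips — tissue has no
canonical orientation — colour jitter, random grayscale, Gaussian blur).
The desk-scale pipeline uses a milder jitter/blur setting, appropriate for
32 px views of subtly coloured textures under a small encoder.  Views are
float32 in [0, 1]; per-channel statistics computed once from the
pretraining patches normalise the network input and are stored with the
encoder.

## Numerical core

No deep-learning framework is a dependency: the package carries a compact
reverse-mode automatic-differentiation engine over float64 numpy arrays
(elementwise ops, matmul, reductions, relu/exp/log, an im2col strided
convolution, `detach` as the stop-gradient primitive) plus conv/linear/
batch-norm layers and Adam/SGD.  All gradients are finite-difference
checked in the test suite, and the SupCon gradient is additionally checked
against finite differences of the independent double-loop oracle.  The
encoder is a 4-block stride-2 conv/BN/ReLU stack (widths 16/32/64/128)
with global average pooling; the projector is a 2-layer MLP (128→128→128),
the SimSiam predictor a bottleneck MLP (128→64→128).

Otsu thresholding is computed in closed form over the 256-bin histogram;
when the between-class variance is flat across a plateau of thresholds
(e.g. a two-delta histogram) the plateau midpoint is returned, so the
threshold sits between the modes.  Tissue is the darker side (H&E on a
white background), with an `invert` flag for the opposite polarity.
Tiling uses 0-based, half-open boxes, row-major scan, partial edge tiles
discarded, tissue fractions via a summed-area table (exact), and a default
tissue cutoff of 0.5.

## The synthetic generator

Real slides for this problem are not publicly available, so the generator
emulates the one property the method depends on: contiguous single-class
regions.  A slide is a Voronoi partition of seed points (minimum separation
3 texture scales, guaranteeing every region comfortably exceeds a patch in
area) with one class per region, every class present, rendered with a
per-class base colour and texture (blob / stripe / speckle / smooth) plus
i.i.d. Gaussian pixel noise (sd 12) and an optional white border so Otsu
masking is exercised.  Colours sit in a narrow, stain-like luminance band,
and classes come in *colour-twin pairs* — two classes share a base colour
and differ only in texture.  This is deliberate: with four chromatically
distinct classes a linear probe on pooled features of *any* encoder,
including a random-init one, saturates at F1 = 1.0 and the experiments can
no longer distinguish a good representation from a trivial one.  Twin
pairs cap what colour statistics alone can achieve while leaving the task
solvable from texture, which mirrors real histology, where chromatic cues
are weak and morphology carries the signal.

What the generator does *not* emulate: stain variation and deconvolution
structure, scanner artefacts, pyramidal resolution levels, nuclear-scale
morphology, or class-imbalanced tissue composition.  Passing tests
therefore show that the machinery is correct and that the method behaves
as predicted *when its prior holds*; they do not certify performance on
real WSIs.

## Desk-scale study conditions

The reference experiment (`spcl.pipeline`) uses problem sizes chosen once
for a single-CPU run: 8 slides of 640 px (48 px white border, 8 regions,
4 classes), 64 px large patches from a non-overlapping sliding window at
tissue fraction ≥ 0.9, 32 px views, M = 4, N = 8, 8 epochs (~190 large
patches, ~190 steps), linear evaluation on 160 labelled patches per class
split 100/20/40 across slide-disjoint train/val/test (5:1:2 slides).  The
full-scale conditions (512/128 px tiles at 20×/0.5 μm px⁻¹, ResNet-18-class
backbone, batch 128, 200 epochs) are expressible through the same configs
but are not part of the test surface; the `tiny_cnn` backbone is the only
one built in.

One deviation from a uniform recipe: the sample-positive versus
degenerate-group (plain SimCLR) comparison pretrains for 16 epochs instead
of 8.  The baseline's specific pathology — repelling same-tissue crops as
false negatives — is cumulative, and at 8 epochs both arms sit at the
probe's ceiling; the longer schedule lets the difference the comparison is
about express itself.  The comparison is paired (identical slides and
labelled sets per seed) and read as a median over five seeds, direction
only.

## Known limitations

* Rejection sampling for non-overlapping boxes dead-ends at high packing
  density (the per-box retry cannot backtrack); exact packings such as
  M·s² = L² are unreachable under pixel-granularity uniform placement.
* SPSimSiam's coupling of SP groups to the prediction loss is one of
  several defensible designs; it is declared, not canonical.
* The MoCo variant keeps no negative queue; at desk-scale batch sizes this
  is standard practice, but it departs from queue-based descriptions.
* UMAP determinism holds for a fixed `random_state` (single-threaded
  layout), not across library versions.
* Fine-tuning shares one optimizer and learning rate across head and
  backbone; per-group learning rates are not implemented.
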