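# Methods

## Overview

`neurofuse` classifies neuron types from digital reconstructions by fusing
two complementary descriptions of a neuron's morphology:

1. **Hand-crafted morphometrics** — a fixed, ordered vector of 43 scalar
   descriptors of the reconstruction's geometry and topology, processed by a
   fully connected network (FCN).
2. **Projection images** — the skeleton rendered onto the x-y, y-z and x-z
   planes after PCA pose normalization, stacked as a 3-channel image and
   processed by a CNN.

The two branches do not run independently: after CNN stages 2–4 a
*multi-level fusion module* (MLFM) lets them exchange information. Each MLFM
applies channel attention within each branch (feature enhancement, FEM) and
scaled dot-product cross attention between branches (feature interaction,
FIM). The final branch features are merged — element-wise sum by default —
and classified by a two-layer head.

## SWC model

A reconstruction is a rooted tree of sample points (`id type x y z radius
parent`, micrometers). Reading accepts arbitrary positive ids in any order,
`#` comments, and scientific notation. Extra roots of type 1 (soma-contour
dialect) are re-attached to the first soma root; any other multi-root file
is rejected, as are duplicate ids, dangling parents and cycles. Writing
renumbers ids contiguously (1-based, parent-first) and renders coordinates
with full round-trip precision.

## The 43-metric registry

Each metric reduces to one scalar per neuron: counts and totals for
count/extent/size-like quantities, means for per-node, per-branch and
per-bifurcation quantities. A *branch* is the path between consecutive
topological events (soma or bifurcation → next bifurcation or tip),
including its starting event node, so branch paths partition the edges.
Branch order is centrifugal (stems = 1).

Definitions that needed pinning down (the toolbox tradition leaves them
loose); all are exercised against independent brute-force oracles in the
test suite:

- **Soma_Surface**: 4πr² of the root node.
- **Diameter / Diameter_pow / SectionArea / Type**: means over non-root
  nodes (the soma's blob radius would otherwise dominate); `Diameter_pow`
  uses exponent 1.5.
- **Surface / Volume**: per-segment frustum lateral surface π(r₁+r₂)L and
  volume π(r₁²+r₁r₂+r₂²)L/3, summed.
- **Taper_1 / Taper_2**: per branch, (d_start − d_end)/path-length and
  (d_start − d_end)/d_start, where d_start is the first node past the
  branching point.
- **TerminalSegment / Diam_threshold**: mean path length, and mean initial
  diameter, of terminal branches.
- **Rall_Power**: per bifurcation, the exponent n solving d₁ⁿ + d₂ⁿ = dpⁿ
  by bisection on [0, 5] to 1e-6; undefined when no sign change exists
  (e.g. a daughter at least as thick as the parent). **Pk** re-evaluates the
  ratio (d₁ⁿ + d₂ⁿ)/dpⁿ at the tree-mean fitted exponent (the per-bifurcation
  exponent would make it identically 1); **Pk_classic** and **Pk_2** use
  n = 1.5 and 2.
- **Bif_tilt**: mean angle between the incoming parent direction and the two
  daughter directions; local variants use adjacent nodes, remote variants
  use branch endpoints and the branch start.
- **Bif_torque**: angle in [0°, 90°] between a bifurcation's daughter plane
  and its nearest ancestor bifurcation's plane (via plane normals).
- **Hillman_threshold**: 0.5·dp + 0.25·(d₁+d₂) over bifurcations whose
  daughter branches are both terminal.
- **Helix**: normalized triple product of three consecutive segment vectors,
  averaged over 4-node windows within branches — a dimensionless, signed
  chirality measure (approximate by construction).
- **Fractal_Dim**: box-counting slope over five dyadic scales of the node
  cloud, computed in the PCA-canonical frame so the estimate is independent
  of the laboratory frame (a fixed-grid box count is not rotation invariant
  otherwise; approximate by construction).

Metrics undefined on a tree (angle metrics without bifurcations, contraction
of a zero-length branch, an unsolvable Rall exponent) are reported as 0 with
a cleared companion mask — the feature vector is always finite, which the
FCN requires.

Every metric carries a declared scaling dimension (0, 1, 1.5, 2 or 3);
uniform scaling of coordinates and radii by s multiplies the metric by
s^dim, and all metrics except the bounding extents Width/Height/Depth are
invariant to rigid motions. Both properties are tested.

## Projection

Pose normalization centers coordinates on the centroid and rotates onto the
principal axes in descending-variance order. The eigenvector sign ambiguity
is fixed per axis by requiring non-negative skewness of the projected
coordinates, falling back to a non-negative coordinate for the point
farthest from the centroid when skewness vanishes; this makes the canonical
pose deterministic, so a rotated/translated copy of a neuron renders to the
same image.

Rendering draws each parent–child segment as a 1-pixel anti-aliased line
(no radius information — that already lives in the morphometrics branch)
into three square views. One isotropic scale, shared by all views, maps the
largest coordinate extent to (1 − 2·pad)·(side − 1) pixels (pad = 0.05
default), preserving relative arbor proportions across views. Overlapping
strokes combine by maximum, keeping intensities in [0, 1]; background is 0.
A single-node tree renders as one centered dot. Default resolution is
224×224 for the ResNet/VGG backbones and 32×32 for the desk-scale `tiny`
backbone.

## Synthetic morphology generator

Class-labeled trees are grown by stochastic recursive elongation: per step,
the direction is jittered inside a cone (angular SD = `tortuosity`), the
step length is Gaussian, and a bifurcation occurs with probability
`bifurcation_prob`, splitting into daughters separated by a sampled angle
(mean 60°) and shrinking the diameter by `taper_rate`. Growth stops at
`max_nodes` (trees therefore share a node budget; class identity is carried
by branching density, segment length, tortuosity and stem count, not by node
count). Each neuron's randomness derives from (seed, class, index), so
datasets are reproducible and order-independent.

The generator emulates what the pipeline needs from real reconstructions —
SWC validity, non-degenerate values for all 43 metrics, class-dependent
statistics — and nothing more. It is not a biophysical growth model: it has
no tissue boundaries, no resource competition, no reconstruction noise or
missing branches, and its classes are cleaner than real neuron types.
Passing desk-scale tests therefore demonstrates that the pipeline learns and
fuses morphological signal correctly, not that it reaches any particular
accuracy on repository data.

Default experiment conditions: 3 classes × 50 neurons. The classes differ
about twofold in segment length and branching probability (with consistent
changes in tortuosity and stem count) — separable but not trivially so at
32×32 image resolution.

## Network

**FCN branch.** Four blocks, paired one-to-one with the CNN stages. Each
block is three FC layers with BatchNorm+ReLU after the first two; hidden
widths are half then a quarter of the block input (floored, minimum 4), and
the output width equals the paired CNN stage's channel count, enabling
channel-wise exchange.

**CNN branch.** Any of `tiny` (4 conv stages, 16/32/64/128 channels, for
32×32 inputs), ResNet-18/34/50/101 or VGG-16/19 (the first VGG conv block
acts as the stem so four stages remain). `pretrained` weights are loaded
only if a checkpoint is supplied; they are never trained here.

**FEM.** Channel weights W_f = σ(fc₂(ReLU(BN(fc₁(F))))) with hidden width
C/2; enhanced feature F_e = W_f ⊙ BN(F). In parallel F is split into
N_s = 3 channel groups (first C mod N_s groups one channel larger), each
refined by fc–BN–fc; the concatenation [F_e, F_s1] is reduced back to width
C by one FC layer. The spatial variant pools the map to a channel vector,
applies the vector FEM, modulates the map channel-wise with the result and
restores the channel count with a 1×1 convolution.

**FIM.** Both branch features are reduced to equal-length vectors (global
average pooling on the CNN side), reshaped into T = 4 tokens of width d =
C/T, and attended: Q_e = softmax(QKᵀ/√d)V with Q from the own branch and
K, V from the other. The single-token reading would make attention
degenerate (Q_e ≡ V); tokenization keeps the softmax informative. No
learned Q/K/V projections by default (a flag enables them). The interacted
feature is F″ = BN(fc(BN(F′) + Q_e)) + F′ — with zeroed fc and BN affine
terms the module is exactly the identity, which the tests pin down.

**MLFM.** At stages 2–4: enhance (F′, C′), interact (F″, C″), then each
branch concatenates its enhanced and interacted features and reduces back to
the input shape — FC on the vector side, 1×1 convolution on the spatial side
with C″ broadcast over space. Disabled submodules pass their inputs through,
so ablation configurations keep identical wiring. Stage 1 is excluded: its
features are too low-level to exchange.

All concat-reduction layers (FEM reduce, MLFM vector and 1×1-conv reduce,
and the FEMSpatial 1×1 convolution) are initialized as identity-on-the-first
-part plus zero-on-the-second plus small noise. At initialization each MLFM
is therefore approximately a pass-through and the cross-branch mixing is
learned gradually — the same rationale as zero-initializing residual
branches; with random reduction weights the fusion modules scramble both
streams early in training and the fused model failed to match its own
single branches.

**Fusion and head.** The FCN feature is projected by one FC layer to the
final stage width D, then merged with the pooled CNN feature by element-wise
sum (default; concatenation and averaging are selectable — summation is the
better performer and keeps D fixed). The classifier is two FC layers
(D → D → n_classes) with dropout 0.5 after the hidden layer. Dropout is not
applied after the output layer: dropping logits directly adds label-free
noise to the loss and measurably stalls optimization.

**Loss.** Multi-class cross entropy L = −(1/N) Σᵢ Σⱼ yᵢⱼ log pᵢⱼ, with
probabilities clamped at 1e-12 so a zero probability at the true class stays
finite.

## Training protocol

Adam, initial learning rate 1e-3 with cosine decay to zero, mini-batch 16,
100 epochs by default (desk-scale experiments use 50). The image branch is
augmented with random horizontal/vertical flips and integer shifts of up to
2 pixels. Morphometric inputs are z-scored with statistics computed on each
training fold only. Early stopping is off by default and available as a
flag. All randomness (weight init, shuffling, dropout, augmentation) derives
from one integer seed; runs are bit-reproducible on one machine.

Numerics: the network runs on a small in-repo reverse-mode autodiff engine
over float64 numpy arrays (convolution by im2col, max-pooling with saved
argmax, batch statistics with running-average eval estimates, momentum 0.1,
eps 1e-5). Gradients of every operator are verified against central finite
differences in the test suite.

## Evaluation

Stratified k-fold cross-validation (10-fold by default, 2-fold at desk
scale), per fold: accuracy, per-class and macro precision/recall/F1,
one-vs-rest ROC-AUC per class, and the confusion matrix. Macro averaging is
used because the reference experiments are class-balanced. Aggregates are
means and standard deviations over folds.

## Desk-scale problem sizes

The repository's own experiments (test suite and the acceptance script) use:
150 synthetic neurons (3 classes × 50), 32×32 projections, the `tiny`
backbone, 2-fold cross-validation, 50 epochs, and three training seeds.
Under these conditions the fused model reaches ≈0.93 mean test accuracy and
exceeds both the FCN-only (≈0.82) and CNN-only (≈0.82) baselines — the same
ordering the full-scale reference experiments report, at a size a single CPU
handles in minutes. Larger backbones (ResNet-50 at 224×224) are exercised
for architectural contracts (shapes, module wiring), not trained.

## Known limitations

- The morphometric registry pins loose toolbox definitions (documented
  above); absolute values of Helix, Fractal_Dim and the tilt/torque angles
  are therefore implementation-specific, though all are deterministic,
  invariance-tested and oracle-tested.
- Box-count fractal dimension from node points depends on the
  reconstruction's sampling density.
- The generator's classes are cleaner than real neuron types; desk-scale
  accuracies do not transfer to repository data.
- Multifurcations are handled (first two daughters define bifurcation
  metrics) but the generator never produces them.
- Training is CPU-bound float64; it is meant for desk-scale experiments,
  not for training ResNet-50 at full resolution.
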