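# Methods

## The model

`sectnet` implements a dual-decoder encoder–decoder segmentation
network for 2-D grayscale CT-like slices. The encoder is five levels
deep with channel plan `base_width × (1, 2, 4, 8, 16)` (default
`base_width = 32`): an initial DoubleConv (two 3×3 conv + BN + ReLU
layers), three downsampling stages that each apply 2×2 max pooling, a
channel-doubling pointwise convolution and an SE-convolution
Transformer module (SECTM), and a bottleneck max-pool + DoubleConv.

**SECTM.** A square feature map `x ∈ R^{B×C×S×S}` feeds three parallel
branches. A stack of two 3×3 conv+BN+ReLU layers extracts local
detail; an SE-ASPP block supplies multi-scale context; their sum is the
value tensor `V`. A residual gives `V' = V + x`. The third branch is a
bilinear attention module (BAM): 1×1 query/key projections to a single
channel, flattening to `S²`, fully connected reduction to `S`, an
`(S,1)×(1,S)` outer product forming an `S×S` second-order correlation
matrix, a 1×1 convolution and a sigmoid. The gate `A ∈ [0,1]^{B×1×S×S}`
broadcasts over channels (hence the square-map requirement), and
`F = A ⊙ V' + V'`. Two parallel 3×3 conv+BN+ReLU refinements of `F` are
summed into the output. The block is channel- and size-preserving, and
with all parameters zeroed it has an exact closed form
(`V = 0`, `V' = x`, `A ≡ 0.5`, `F = 1.5x`, output `0`) that the test
suite asserts bit-exactly.

**SE-ASPP.** Five parallel branches: a 1×1 convolution and three 3×3
depthwise convolutions at dilation rates 6/12/18 (padding = dilation,
each followed by a pointwise mix), each emitting `C/4` channels, plus a
squeeze-and-excitation branch emitting `C`. The `2C` concatenation is
restored to `C` by a final pointwise convolution. The `C/4` branch
budget and the restoring projection are this package's choice; they are
forced by the element-wise fusion inside SECTM, which requires
C-in/C-out behaviour.

**DFCM.** The bottleneck feature map is routed into four branches;
branch `i` upsamples bilinearly ×2 `i` times, applies a channel
attention gate (CBAM-style shared two-layer bottleneck over max- and
average-pooled descriptors, reduction 16) then a spatial attention gate
(channel-max plus channel-mean map, 7×7 convolution, sigmoid), adds the
upsampled tensor back as a residual, and compresses with a 1×1
convolution to the encoder width at the matching resolution. Branches
own independent attention weights; nothing suggests sharing, and
independent weights keep the ablation parameter accounting clean.

**Dual decoders.** Decoder1 is a classical U-Net decoder
(transposed-convolution ×2 upsampling halving channels, skip
concatenation, DoubleConv) ending in a 1×1 conv + sigmoid head that
emits the coarse mask. Decoder2 runs afterwards: at each stage the
upsampled feature is combined with the coarse mask resized to the stage
resolution through the residual mask interaction
`add_n = up ⊙ mask + up`, then concatenated with the DFCM guidance map
and the encoder skip before a DoubleConv. Gradient flow from Decoder2
back through the coarse mask into Decoder1 is deliberately *not*
blocked: the two decoders train jointly. The training objective is
`L(coarse) + L(refined)` with equal weights — the coarse mask needs
direct supervision to be a meaningful guide — and the refined mask is
the reported prediction.

### Design choices where the design was open

- **Decoder2's deepest input** is the raw bottleneck feature; DFCM
  output enters only through the concatenated branch features.
- **Feature upsampling** is a learned kernel-2 stride-2 transposed
  convolution; **mask resizing** is parameter-free bilinear
  interpolation (masks are probabilities, and convex interpolation
  keeps them in [0, 1]).
- **Guidance ablation**: `guidance="decoder1_features"` replaces the
  mask interaction with `add_n = up + d1_feat`, the direct
  stage-feature transfer variant; `guidance="none"` drops the
  interaction; `dual_decoder=False` yields a plain single-decoder
  U-Net whose refined output aliases the coarse one.
- **SECTM removal** substitutes a max-pool + DoubleConv stage with the
  same channel plan, so parameter deltas isolate the module.
- **BAM geometry**: the fully connected layers have fixed shape
  `(S², S)`, binding each SECTM instance to its configured feature-map
  side; changing input resolution means rebuilding the model.
  Non-square feature maps are rejected with an explicit error rather
  than silently reinterpreted.
- **Attention order**: the bilinear gate multiplies the
  residual-augmented value `V'`, and the refinement is two parallel
  3×3 stages summed (not sequential refinement).

## Numerical substrate

No deep-learning framework is used; the package ships a small
reverse-mode autodiff engine on numpy float32 arrays
(`sectnet.autodiff`, `sectnet.nn`). Convolutions are evaluated by
unfolding kernel-position slices and contracting with BLAS matmuls;
transposed convolution, 2×2 max pooling (ties share gradient equally),
separable bilinear interpolation (half-pixel-center convention),
training-mode batch normalization (biased batch variance for
normalization, unbiased for the running buffers, momentum 0.1,
eps 1e-5) and linear layers complete the vocabulary. Every structured
operation is validated against central-difference gradients in the test
suite. Weights are He-initialized (Xavier for fully connected layers)
from a generator seeded by `ModelConfig.seed`, so two builds with equal
seeds are bit-identical; all biases start at zero, which makes every
untrained sigmoid gate start at the neutral value 0.5. The squeeze
bottlenecks of the SE and channel-attention gates use a leaky rectifier
(slope 0.01) instead of a hard ReLU: those bottlenecks can be a single
unit wide, and a dead unit there would disconnect the whole gate from
the gradient graph, violating the no-dead-branch contract the tests
enforce.

## Losses and metrics

- **Dice loss** `1 − 2Σyp / (Σy² + Σp² + ε)` with ε = 1e-6 (the
  smoothing term guards empty masks; note this squared form has zero
  gradient on an image whose target is entirely empty). Default
  objective.
- **Tversky loss** with defaults α = 0.7, β = 0.3 (α, β were not
  dictated by anything; these are the conventional
  false-positive-heavy defaults). At α = β = 0.5 it coincides with
  Dice on binary predictions.
- **BCE** mean-reduced with probabilities clamped to [1e-7, 1−1e-7].
- **Hausdorff surrogate**: mean squared prediction error weighted by
  `dt(target)² + dt(binarized pred)²`, where `dt` is the Euclidean
  distance to the respective foreground (scipy EDT, treated as a
  constant weight). An empty foreground is assigned the image diagonal
  as its distance so that an empty prediction against a nonempty
  target is penalized. Zero when prediction equals target.
- **Metrics** are computed per image from confusion counts at threshold
  0.5: Dice `2TP/(2TP+FN+FP)`, Jaccard `TP/(TP+FN+FP)`, Mcc
  `(TP·TN−FP·FN)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP))`. Conventions: empty
  target and empty prediction give Dice = Jaccard = 1 and Mcc = 0; any
  zero Mcc denominator gives 0. Reported spreads are per-image standard
  deviations over the evaluated split.

## Synthetic phantoms

The generator emulates the difficulty factors of contrast-enhanced CT
tumor slices at the 256×256 working resolution (tests and the
acceptance script use 64×64 with proportionally scaled lesions):

- a jittered, rotated elliptical "liver" (intensity 0.45) on a dark
  background (0.15) with a low-frequency multiplicative texture
  (amplitude 0.04, kept below half the minimum lesion contrast);
- 1–3 lesions per slice as star-convex polygons — 12 angular spokes
  with radii scattered ±30% around a base radius of 6–40 px —
  hypodense by a contrast offset of 0.1–0.4 and filled with a smooth
  heterogeneity field in [0.7, 1.0] of the offset;
- Gaussian boundary blur (σ = 1–4 px) applied to the image only, and
  additive Gaussian noise (σ = 0.03). The mask is the un-blurred
  lesion union, clipped to the organ.

Because heterogeneity never drops below 0.7 of the contrast and the
liver texture stays below contrast/2, thresholding a noise- and
blur-free phantom inside the organ at `0.45 − contrast/2` recovers the
mask exactly; the test suite uses this as a reconstruction oracle.
Slices of one synthetic patient share the organ pose and a base lesion
configuration with per-slice jitter, so slices within a patient are
strongly correlated and the patient-level split is a genuine leakage
constraint. Partition sizes floor the requested fractions, with the
amendment that every nonzero fraction receives at least one patient.

What the phantoms do *not* model: Hounsfield calibration, vessels and
neighboring organs, acquisition artifacts, 3-D continuity between
slices, and inter-scanner variation. Passing tests therefore
demonstrate that the architecture, losses and pipeline are implemented
correctly and can learn this class of appearance, not that the model
reaches clinical-grade accuracy on real CT.

## Problem sizes and budgets

The default test and acceptance configuration is the reduced model
(input side 64, `base_width = 8`, ≈ 0.97 M parameters) trained with the
default protocol — Adam, learning rate 0.001, Dice loss, batch ≤ 16
(8 at the reduced size) — for at most 200 optimization steps; the full
256-side architecture contracts are exercised at `base_width = 4`.
These sizes were chosen so the entire suite runs on a single CPU in
minutes while leaving every architectural mechanism (mask guidance,
SECTM, DFCM, both heads) live. The default training length of 200 is
counted in epochs, matching how epoch-axis learning curves are usually
reported.

## Known limitations

- The BAM binds each SECTM to one feature-map side; multi-resolution
  inference requires rebuilding (and reinitializing the FC layers).
- No canonical per-stage channel widths are fixed; `base_width` is
  exposed instead, and parameter counts are tested only for
  monotonicity in the architecture toggles.
- Training is full-precision, single-device, single-threaded numpy;
  it is adequate for the reduced problem sizes above, not for
  2000-slice clinical datasets.
- The evaluation suite reports region-overlap metrics only; surface
  distances (HD95, ASSD) are out of scope.
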