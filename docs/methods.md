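# Methods

## Problem and model

The package segments the choroid — the vascular band between the bright
retinal pigment epithelium (RPE) line and the sclera — in 8-bit grayscale
OCT B-scans, as a binary per-pixel classification (channel 0 background,
channel 1 choroid).  The difficulty is the choroid–scleral interface (CSI):
its intensity contrast can approach zero, so purely local operators tend to
over- or under-segment the inferior boundary.  The network therefore mixes
global self-attention with multiscale convolutional attention at every
stage, fuses adjacent pyramid levels, and re-weights the fused features
along channel, spatial and point dimensions before decoding.

### Encoder

Four stages produce features at strides 4/8/16/32 with channels
`[C, 2C, 4C, 8C]`.  Downsampling is a Patch Merging unit: 3×3 depthwise
convolution with stride 2, a 1×1 projection to the stage width, and batch
normalisation (inference uses running statistics, so evaluation is
deterministic).  The stride-4 stem is two such stride-2 units.  A mixed
block applies, in series,

    y   = x + MHSA(LN(x))
    z   = PSCA(y)                  # carries its own residual
    out = z + FFN(LN(z))

with layer normalisation over channels, a position-wise FFN with expansion
4 and exact (erf) GELU, and multi-head self-attention whose keys/values are
optionally downsampled by a strided convolution with per-stage
spatial-reduction ratios (default `[8, 4, 2, 1]`).  Ratio 1 recovers exact
attention and is the configuration the oracle tests exercise.  The serial
MHSA→PSCA order reflects the design intent of enhancing local extraction on
top of global modelling; a parallel coupling would be a reasonable
alternative but is not implemented.

### PSCA

Three parallel depthwise paths — 1×1 (point), 3×3 (channel), and two 7×7 in
series (spatial) — are concatenated and fused by a 1×1 convolution to the
input width; a sigmoid turns the fusion into a gate and a residual keeps
the identity path: `out = x + σ(z) ⊙ x`.  The two 7×7 depthwise
convolutions cannot change the channel count, so the compression ratio
ρ=16 is realised by 1×1 reduce/expand convolutions bracketing the second
7×7; the channel count entering the fuse layer is then exactly 3C.
Reduced widths are `⌈C/ρ⌉`, floored at one channel so narrow test
configurations stay valid.

### ACB

The asymmetric convolution block evaluates k×k, 1×k and k×1 branches and
sums them.  The asymmetric kernels are array views of the square kernel's
central row and column: the block has exactly the parameter count of one
k×k convolution (`C_out·C_in·k² + C_out`), and gradients from all three
branches accumulate into the shared kernel.  Summation (rather than
concatenation) is what keeps both the output width and the zero-parameter
property; it also matches the original asymmetric-convolution literature.
The bias is added once, after the three branches.

### ASFF

Level i is fused with its neighbours after dimension matching: the coarser
level passes a 1×1 convolution that halves its channels and bilinear ×2
upsampling (half-pixel-centre convention, exact output size); the finer
level passes a 3×3 stride-2 depthwise convolution then a 1×1 channel
doubling.  The fused map is

    Concat( DML(F_{i−1}) ⊙ F_i ,  F_i + ACB(F_i) ,  F_i ⊙ DML(F_{i+1}) )

— the neighbour terms multiply the *raw* current-level features (the
equation-level definition), while the enhanced `F_i + ACB(F_i)` occupies
the middle slot.  Interior levels emit 3·C_i channels, boundary levels
(which lack one neighbour) 2·C_i.  With all weights zero the module reduces
to `Concat(0, F_i, 0)`, a property the tests pin down.

### DFSM

Channel attention is squeeze-and-excitation shaped: global average pooling,
a two-layer MLP with reduction r=16 and a ReLU between the layers, then a
sigmoid, broadcast over space.  Spatial attention applies two 7×7 ACBs to
the channel-weighted features, mapping `C → ⌈C/r⌉ → 1`, giving a
single-channel map broadcast over channels.  Point attention is a sigmoid
1×1 convolution of the raw input.  The combination is

    out = Conv1×1( A_S ⊙ (A_C ⊙ F)  +  A_P ⊙ F )

with the output projection restoring the encoder stage width, so the
decoder sees the standard `[C, 2C, 4C, 8C]` pyramid.

### Decoder and prediction

Each refined level is embedded per-position to `decoder_dim`, bilinearly
upsampled to the stride-4 grid, concatenated, fused and classified by 1×1
(per-position linear) layers, and the two-channel logits are upsampled ×4
to the input resolution.  Predicted labels are the channel argmax with ties
resolved to background — the conservative choice for a clinical
segmentation.

## Autodiff engine

No deep-learning framework is used: `choroidseg.nn` is a reverse-mode
automatic-differentiation tape over numpy arrays with the operations the
model needs (grouped/depthwise/dense convolution with exact adjoints,
separable bilinear resampling, batched matmul, softmax/log-softmax,
layer/batch norm, sigmoid/ReLU/GELU, slicing with gradient scatter — which
is what makes the ACB's shared-kernel views differentiate correctly — and
Adam).  Gradients of every primitive are tested against central finite
differences.  Tensors are float64 by default; a float32 mode exists but the
shipped configuration does not need it.

## Synthetic B-scans

The simulator renders what the segmentation task actually depends on: a
dark vitreous, a retinal band, a thin bright RPE line, a textured choroid
band and a sclera separated by a low-contrast CSI.  Geometry: three
per-column boundary curves (ILM, RPE-bottom, CSI), each a mean depth plus
`n_harmonics = 3` random-amplitude, random-phase sinusoids.  Defaults, in
pixels at height H = 256: mean ILM depth H/4, retina thickness H/8, RPE
thickness 3, choroid thickness H/5, harmonic amplitude budget H/20.  The
amplitude budget is validated at construction against the layer gaps so
curves can never cross or leave the frame (H/20 rather than the looser
H/16 bound, because the default retina thickness leaves less than
2·(H/16) of clearance).  Intensities (relative units): vitreous 0.08,
retina 0.45, RPE 0.90, choroid 0.50; the sclera is `choroid − csi_contrast`
with `csi_contrast = 0.2` by default — at 0 the CSI is invisible in the
image while the label is unchanged, which is exactly the fuzzy-boundary
regime the real task struggles with.  Dark elliptical vessel lumina are
scattered in the choroid at density 0.15, and multiplicative Gaussian
speckle (σ = 0.08; a gamma variant is available) degrades the image.
Labels are computed from the noise-free curves (`rpe_bottom < y ≤ csi`),
so noise parameters cannot leak into the masks, and the foreground area
has a closed form from the curves that the tests check exactly.

Datasets mix a `normal` and a `lesioned` condition (thicker choroid,
halved CSI contrast) at a 68/32 ratio, mirroring a typical
normal-to-diabetic-retinopathy case mix, and are split 8:1:1 with the split
sizes fixed at the dataset level and apportioned across conditions by
largest remainder.

What the simulator does *not* emulate: realistic OCT speckle statistics and
point-spread function, vessel shadowing, motion artefacts, pathology-
specific morphology (drusen, oedema), or annotation noise.  Passing tests
on synthetic data therefore demonstrate that the architecture, optimisation
and bookkeeping are correct and that the model can fit OCT-like layered
geometry; they say nothing quantitative about accuracy on clinical scans.

## Training protocol

Adam (β = 0.9/0.999), constant learning rate 5·10⁻⁴, batch size 4, and
per-pixel cross-entropy over the softmaxed two-channel logits — for one-hot
binary targets this is identical to binary cross-entropy; a single-logit
sigmoid BCE is available behind a flag.  Augmentation applies, jointly to
image and mask: a horizontal flip with probability 0.5, a rotation uniform
in ±10°, and a contrast rescale `c·(x−x̄)+x̄` with `c ~ U(0.8, 1.25)` —
rotation and contrast magnitudes are configurable choices.  Validation
metrics are computed every `eval_interval` iterations and the best-mDice
weights are retained; an optional `stop_at_fg_dice` threshold ends training
early once the monitored foreground Dice is reached (the retained-best
semantics make this equivalent to training on, for workloads whose metric
has already saturated).  All randomness — initialisation, shuffling,
augmentation — derives from one seed, and seed replay reproduces the loss
curve exactly.

Evaluation is deterministic (inference mode, no augmentation); inputs whose
size is not a multiple of 32 are edge-padded and scored on the unpadded
region.  Cross-validation stratifies folds by condition tag with a
round-robin that continues across tags (keeping fold sizes balanced),
trains each fold on the remainder with ~10% held out for checkpoint
monitoring, and reports per-fold scores plus mean ± standard deviation.

## Metrics

For each class treated as positive, `IoU = TP/(TP+FP+FN)`,
`Dice = 2TP/(2TP+FP+FN)`, `Acc = (TP+TN)/total`; `m`-scores average the two
classes.  Counts are pooled over the evaluated split before forming ratios
(the convention of mainstream segmentation tooling); per-image averaging is
available behind a flag and differs whenever image difficulty varies.  A
class absent from both prediction and truth scores Dice = IoU = 1 with a
warning, keeping split means defined on degenerate crops.  Two identities
are enforced by tests: `Dice = 2·IoU/(1+IoU)`, and for the two-class case
`mAcc` equals plain pixel accuracy (swapping the positive class exchanges
TP↔TN and FP↔FN).

## Problem sizes and defaults

The default ("desk") configuration is deliberately small —
channels `[8, 16, 32, 64]`, one mixed block per stage, heads `[1, 2, 4, 8]`,
256×256 inputs — chosen so that full training runs, the overfit probe and
cross-validation execute comfortably on a single CPU core with the numpy
engine; at these widths the probe reaches foreground Dice ≥ 0.9 on eight
synthetic scans within a few hundred iterations.  Wider presets with the
same four-stage doubling layout are provided (`ModelConfig.base()` with
`[32, 64, 128, 256]`, and `ModelConfig.paper_scale()` with
`[64, 128, 256, 512]`, depths `[2, 2, 6, 2]`, 512×512 inputs); they are
configuration presets, not tested paths.  Stage widths, depths, head
counts, the FFN expansion, and the spatial-reduction ratios are all free
parameters of the architecture family rather than published constants.

## Numerical choices and edge cases

* Bilinear resampling uses the half-pixel-centre (align_corners=false)
  convention with edge clamping, forced to the exact target size.
* Softmax and log-softmax subtract the row maximum before exponentiation.
* Batch norm tracks running statistics with momentum 0.1 (biased variance).
* Initialisation: He-normal for convolutions, `1/√fan_in` normal for linear
  maps, zero biases, unit norm scales; all from the construction seed.
* Argmax ties in prediction go to background.
* `⌈C/ratio⌉` reductions floor at one channel.
* Training aborts with a diagnostic on a non-finite loss.
* Odd spatial sizes reaching a stride-2 unit are edge-padded, never
  resized; the encoder itself requires multiples of 32 and says so.

## Known limitations

* CPU-only, single-process; wide presets train slowly in this engine.
* The synthetic domain is much easier than clinical OCT; reported synthetic
  scores are not clinical performance estimates.
* No pretrained backbones, no learning-rate schedule, no mixed precision,
  no boundary-distance metrics (Hausdorff, CSI position error).
* The spatial-reduction attention is an approximation of full MHSA at the
  two finest stages (exact attention is available by setting the ratios
  to 1).
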