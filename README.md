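# choroidseg

Automatic delineation of the **choroid** — the vascular layer between the
retina and the sclera — in optical coherence tomography (OCT) B-scans.
Choroidal thickness and vascularity are biomarkers for glaucoma, diabetic
retinopathy and age-related macular degeneration, but the choroid's inferior
boundary, the choroid–scleral interface (CSI), is low-contrast and fuzzy,
which makes manual tracing slow and plain convolutional segmenters
unreliable.

The package implements a hybrid convolution/self-attention semantic
segmentation network for this task, together with a seeded synthetic B-scan
simulator and a complete training / evaluation / cross-validation harness,
so every component is testable without clinical data.  The network and its
training loop run on a small reverse-mode automatic-differentiation engine
over numpy (`choroidseg.nn`) — there is no deep-learning framework
dependency.

## Architecture

An input B-scan `x ∈ [0,1]^{H×W}` passes through:

1. **Local-enhanced hierarchical encoder** — four stages at strides
   4/8/16/32 with a doubling channel schedule `[C, 2C, 4C, 8C]`.  Each stage
   is a Patch Merging downsampler (3×3 depthwise stride-2 convolution → 1×1
   projection → batch norm) followed by *mixed blocks*:

       y = x + MHSA(LN(x)),   z = PSCA(y),   out = z + FFN(LN(z))

   **PSCA** (parallel multiscale convolutional attention) gates each
   position with `out = x + σ(z) ⊙ x`, where `z` fuses a 1×1 depthwise
   point path, a 3×3 depthwise channel path and a spatial path of two 7×7
   depthwise convolutions bracketed by 1×1 reduce/expand at compression
   ratio ρ=16.
2. **Adjacent multiscale feature fusion (ASFF)** — each level F_i is
   enhanced by an asymmetric convolution block, `F_i^T = F_i + ACB(F_i)`,
   and concatenated with products of dimension-matched neighbours:

       ASFF_i = Concat( DML(F_{i−1}) ⊙ F_i ,  F_i^T ,  F_i ⊙ DML(F_{i+1}) )

   The **ACB** runs k×k, 1×k and k×1 branches whose asymmetric kernels are
   *views* of the square kernel's central row/column (zero extra
   parameters); branch outputs are summed.
3. **Dynamic feature selection (DFSM)** — channel attention
   `A_C = σ(MLP(GAP(F)))`, spatial attention `A_S = σ(ACB(ACB(F_C)))` (a
   single-channel map from two large-kernel ACBs), and point attention
   `A_P = σ(Conv1×1(F))`, combined as
   `out = Conv1×1(A_S ⊙ A_C ⊙ F + A_P ⊙ F)`, restoring the stage width.
4. **All-MLP decoder** — per-level linear embeddings, bilinear upsampling to
   the stride-4 grid, linear fusion and a linear two-class pixel classifier,
   upsampled to full resolution.

Training follows the protocol: Adam at learning rate 5·10⁻⁴, batch size 4,
per-pixel binary cross-entropy, horizontal-flip / rotation / contrast
augmentation, periodic validation with best-mDice checkpointing, and
stratified k-fold cross-validation.  Reported metrics are per-class Dice,
IoU and accuracy from pooled pixel confusion counts, with `m`-prefixed
scores the unweighted background/choroid mean.

## Worked example

```python
import numpy as np
from choroidseg import (ChoroidSegModel, ModelConfig, TrainConfig,
                        SegDataset, SyntheticSpec, generate_bscan)

spec = SyntheticSpec()                      # 256x256 layered B-scans
pairs = [generate_bscan(spec, 100 + i) for i in range(8)]
imgs, msks = [p[0] for p in pairs], [p[1] for p in pairs]
ds = SegDataset(imgs + imgs, msks + msks,
                splits=["train"] * 8 + ["val"] * 8)

model = ChoroidSegModel(ds, ModelConfig(),
                        TrainConfig(max_iters=500, eval_interval=50,
                                    stop_at_fg_dice=0.90))
res = model.fit(seed=0)
print(res.summary())
```

prints (abridged):

```
Choroid segmentation fit
================================================
channels        : (8, 16, 32, 64)
depths          : (1, 1, 1, 1)
parameters      : 303118
seed            : 0
best iteration  : 100
best val mDice  : 95.07
final val       : mDice 95.07  mIoU 90.76  mAcc 96.94
final loss      : 0.0828
```

i.e. after ~100 optimisation steps the desk-scale network overfits the
eight clean synthetic scans to a mean Dice of 95 (background + choroid
average, ×100 scale); the choroid class alone reaches Dice ≥ 0.90, which is
the package's capacity sanity check.  On held-out synthetic data, or on real
scans, scores are established with `evaluate` or the `cv` command instead.

The same workflow is available from the shell:

```sh
choroidseg simulate --n 100 --seed 0 --out data/
choroidseg train    --config cfg.yaml --data data/ --out run/
choroidseg eval     --ckpt run/checkpoint.npz --data data/ --split test --report report.json
choroidseg predict  --ckpt run/checkpoint.npz --image scan.png --out mask.png
choroidseg cv       --k 5 --config cfg.yaml --data data/
```

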