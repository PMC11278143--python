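# carotidseg

Weakly supervised 2.5D self-training segmentation of the internal carotid
arteries in volumetric T1-weighted brain MR images.

## The problem

Pixel-accurate vessel masks are expensive: the carotids are a few voxels
wide, and delineating them slice by slice needs radiologist time. Drawing an
axis-aligned **bounding box** around each carotid per axial slice is far
cheaper — but boxes are noisy labels that contain many background pixels.
This package implements a pipeline that starts from those boxes and
iteratively refines them into pixel-level masks:

1. **2.5D pseudo-RGB input** — each axial slice is stacked with its two
   neighbours into an H×W×3 image (R = slice below, G = target, B = slice
   above), giving a 2D network limited through-plane context.
2. **Preprocessing** — isotropic 1 mm³ resampling, 16→8-bit quantization,
   division by 255.
3. **Area-stratified augmentation** — slices are split at the mean + 1 SD of
   mask area; the scarce big-area subset is inflated 7×, the rest 1.3×,
   using rotations (≤15°, p=0.9), flips (p=0.5), contrast (p=0.8), gamma
   (p=0.5), 3×3 blur (p=0.05), noise (p=0.05) and shift/zoom (p=0.5), with
   nearest-neighbour mask interpolation.
4. **Res-Unet** — a 5-level U-net (two padded 3×3 convolutions per level,
   batch norm, PReLU, additive residual shortcut per block, 2×2 average
   pooling, 1000-filter bottleneck at reference scale, dropout 0.6) trained
   with the soft Dice loss, `L = 1 − (2Σpt + 1)/(Σp + Σt + 1)`, Adam at
   lr 1e-4 with continuous exponential decay (rate 0.96 per 253 steps),
   early stopping on validation mean IoU (patience 10).
5. **Recursive self-training** — a 5-fold cross-validation ensemble (mean of
   the five probability maps, threshold 0.5) re-segments every training
   slice; the prediction is eroded by a radius-1 disk (first four rounds
   only), gated per carotid (left/right half must reach IoU ≥ 0.5 against
   its box, else revert), clipped to the boxes, and used as the next round's
   labels — for seven rounds.

The network, its backpropagation and the Adam optimizer are implemented in
numpy inside the package (`carotidseg.nn`), so the pipeline runs anywhere
scientific Python runs. A synthetic phantom generator (two dark wobbling
tubes with a bright perivascular rim, plus loose jittered boxes) makes the
whole pipeline testable end to end without any imaging data.

## Worked example

```python
from carotidseg.study import run_scaled_study

res = run_scaled_study(master_seed=1)
print(f"weak-box baseline IoU : {res.bbox_iou:.3f}")
print(f"refined-mask IoU      : {res.refined_iou:.3f}")
print(f"held-out IoU per round: "
      + " ".join(f"{v:.3f}" for v in res.eval_iou_per_round))
```

This runs the desk-scale study — 6 training phantoms and 3 held-out
phantoms of 16 slices at 32×32, a 64-filter-bottleneck Res-Unet, 3
self-training rounds — and prints (about 4 minutes on one CPU):

```
weak-box baseline IoU : 0.221
refined-mask IoU      : 0.346
held-out IoU per round: 0.210 0.321 0.328
```

The refined training masks (IoU 0.35 against the hidden tube ground truth)
are substantially closer to the true vessels than the bounding boxes they
started from (IoU 0.22), and the ensemble's accuracy on unseen phantoms
rises across rounds — the self-training refinement loop is doing its job.

The same pipeline runs from the shell:

```bash
carotidseg phantom --n 6 --seed 1 --out data/           # synthetic dataset
carotidseg selftrain --data data/ --run-dir runs/demo   # recursive training
carotidseg predict --weights runs/demo/round_2 \
                   --volume data/phantom_000_image.nii.gz --out pred.nii.gz
carotidseg evaluate --pred-dir preds/ --gt-dir gts/ --out report
```

## Layout

| module | role |
| --- | --- |
| `carotidseg.volume_io` | NIfTI I/O, isotropic resampling, quantization, normalization |
| `carotidseg.synthetic` | two-tube phantom volumes + weak boxes + hidden ground truth |
| `carotidseg.pseudo_rgb` | 2.5D pseudo-RGB slice stacking, slice dataset assembly |
| `carotidseg.augmentation` | area-stratified augmentation policy |
| `carotidseg.nn` / `carotidseg.model` | numpy layer library and the Res-Unet |
| `carotidseg.training` | Dice loss, lr schedule, folds, early stopping |
| `carotidseg.self_training` | ensemble prediction, erosion, IoU gate, clipping, rounds |
| `carotidseg.metrics` | IoU / DSC and mean ± SD reports |
| `carotidseg.study` | the fixed desk-scale phantom study |
| `carotidseg.config` / `carotidseg.cli` | YAML configuration and the `carotidseg` command |

See `docs/methods.md` for the modelling choices, defaults and limitations.
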