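# Methods

## Model and procedure

The pipeline treats per-slice bounding boxes around the two internal carotid
arteries as noisy segmentation labels and refines them by recursive
self-training. One round consists of: (i) training a 5-fold
cross-validation ensemble of residual U-nets on the current labels with the
soft Dice loss; (ii) re-segmenting every training slice with the ensemble
mean probability, thresholded at 0.5; (iii) post-processing the prediction —
morphological erosion by the radius-1 digital disk (the 5-pixel cross)
during the early rounds, then a per-carotid acceptance test (split the image
at the vertical midline; each half keeps the prediction only if its IoU
against that half's bounding box is ≥ 0.5, otherwise it reverts to the box),
then clipping to the boxes; (iv) using the result as the next round's
labels. The fold partition is computed once, at volume level, and reused by
every round, so a volume's slices never leak across the train/validation
boundary of its fold's model.

Two structural assumptions matter. First, the carotids are bilateral and
roughly symmetric about the midline, which is what justifies the fixed
left/right split of the acceptance test (the split column is configurable).
Second, the boxes are assumed to *contain* the vessels: clipping guarantees
refined masks can never grow outside the weak labels, and the acceptance
test guarantees a degenerate ensemble (e.g. all-background) can never lose
them — the pipeline's worst case is the initial boxes themselves.

## Network

Five levels; per level two padded 3×3 stride-1 convolutions, each followed
by batch normalization and PReLU, with an additive shortcut across the pair
(identity when input and output channel counts match, a 1×1 projection
otherwise), then channel dropout. Downsampling is 2×2 average pooling;
channels double as resolution halves; the bottleneck width is set directly
(1000 at the reference 240×240 scale — only the bottleneck width is fixed by
the protocol, so earlier widths follow the doubling rule from a configurable
base width, default 64). The decoder upsamples by nearest-neighbour 2×
(transposed convolutions were avoided for their checkerboard artifacts),
concatenates the matching encoder features, and applies the same block. A
1×1 convolution and sigmoid give per-pixel probabilities.

The layers, backpropagation and Adam are implemented in numpy (`nn.py`),
in float64, with convolutions via im2col. Correctness is established by a
finite-difference gradient check over every parameter tensor of a small
instance (`tests/test_model.py`); pure-numpy execution also makes every
result bit-reproducible for a fixed seed.

## Defaults

| parameter | default | notes |
| --- | --- | --- |
| learning rate | 1e-4 | Adam; continuous exponential decay, rate 0.96 per 253 steps |
| epochs / patience | 100 / 10 | early stopping on validation mean IoU, best weights kept |
| folds | 5 | volume-level round-robin after a seeded shuffle |
| Dice smooth | 1.0 | makes the empty/empty case lossless |
| dropout | 0.6 | channel dropout after each block |
| threshold | 0.5 | probability binarization, ≥ convention |
| rounds / erosion rounds | 7 / 4 | erosion in rounds 0–3 |
| IoU gate | 0.5 | per carotid, ≥ convention; both-empty halves count as accepted |
| multipliers | 7× big / 1.3× small | split at mean + 1·(population) SD of mask area |

Augmentation probabilities are listed in the README; the amplitude ranges
that have no prescribed value are contrast factor U(0.8, 1.2), gamma
U(0.8, 1.2), noise σ = 0.01, shift ≤ 10% of extent, zoom U(0.9, 1.1), all
exposed in the YAML config. Fractional copy counts round half-up, so 1.3×
of 10 slices is exactly 13.

## Synthetic phantoms

The generator emulates the axial appearance of the carotids in T1-weighted
scans: two dark tubes (low lumen signal) in a brighter background, each with
a 1–2 px brighter rim (perivascular fat), per-volume lumen contrast drawn
uniformly from a configurable range, i.i.d. Gaussian noise, and per-slice
weak boxes built by dilating each tube's tight box by a margin (default
2 px) and jittering it by up to ±1 px (jitter is capped at the margin so the
ground truth always stays inside the boxes). Tube centerlines wobble
sinusoidally in-plane; a localized Gaussian "bulge" band elongates the
cross-section over a minority of slices, reproducing the real dichotomy
between small round sections and larger oblique ones — and hence a
right-skewed per-slice mask-area distribution, which is what the
area stratification acts on. Not emulated: bifurcations, MR bias fields,
partial-volume effects, plaque, and any real anatomy beyond "two thin dark
tubes" — passing phantom tests therefore demonstrates the *mechanics* of the
pipeline (label refinement beats the boxes when the object is darker than
its surround), not clinical accuracy.

With zero noise the tubes are exactly recoverable by intensity
thresholding, which several tests use as an oracle.

## The desk-scale study

The reference protocol (42 clinical volumes at 240×240, 1000-filter
bottleneck, 7 rounds) is beyond a desk CPU, so the shipped study
(`carotidseg.study`) fixes one scaled configuration: 6 training + 3
held-out phantoms, 16 slices at 32×32, base width 4 (64-filter bottleneck),
3 rounds, replicated over 3 derived master seeds. Two parameters are
rescaled with the problem size rather than copied from the reference
protocol:

* **Erosion in round 0 only.** Scaling 4-of-7 erosion rounds to a 3-round
  study gives ~1.7; beyond that, consecutive erosions of the tiny phantom
  tubes (box area ≈ 6× tube area) over-shrink the predictions below the 50%
  gate and every slice reverts, making rounds oscillate between refined and
  box states rather than converge.
* **lr 1e-3, 10 epochs, patience 4.** An epoch here is ~17 Adam steps
  against the reference protocol's 253, so the reference lr/epoch pairing
  would leave the network barely past initialization; at this scale 1e-3
  converges within the training budget. Both remain ordinary `TrainConfig`
  fields; the full-scale defaults are untouched.
* **Dropout 0.1.** Channel dropout at 0.6 is calibrated for hundreds of
  channels per block; with a base width of 4 it zeroes most of a block's
  feature maps and the tiny network cannot fit at all.

The study reports the weak-box baseline IoU against the hidden tube ground
truth (~0.22 under the default margins), the refined-mask IoU after the
final round, and the held-out ensemble IoU/DSC per round. The interesting
scientific claim at this scale is *relative*: refined masks beat the boxes,
and held-out accuracy does not degrade across rounds.

## Numerical conventions and edge cases

* IoU and DSC of two empty masks are defined as 1 (a correct empty
  prediction is not an error); `evaluate` can instead drop both-empty items.
  The identity DSC = 2·IoU/(1+IoU) implies IoU ≤ DSC for any mask pair, so a
  report in which the DSC mean falls below the IoU mean over the same items
  is arithmetically impossible under these definitions; this package always
  reports both from the same item set.
* Aggregation is per-slice mean ± population SD (ddof = 0) by default.
* Thresholds use the inclusive (≥) convention everywhere: probability
  binarization at 0.5, the 50% acceptance gate, and the mean-plus-SD area
  split (ties go to the small stratum).
* Quantization is per-volume min–max onto 0..255 with round-half-up; a
  constant volume maps to 0. The alternative fixed-range convention (÷257)
  would tie the output to the input's nominal bit depth instead of its
  dynamic range.
* Resampled shapes are round(extent/target); masks resample
  nearest-neighbour and remain binary. Bias-field and spatial normalization
  are deliberately not applied.
* Pseudo-RGB boundary slices replicate the edge slice rather than zero-fill,
  which would inject an intensity cue absent from interior slices.
* Slices with empty weak masks are excluded from training (the annotation
  regime labels carotid-bearing slices); whether carotid-free slices would
  help as pure-background examples is untested here.

## Known limitations

* The acceptance gate compares against the *initial* boxes, so when boxes
  are much larger than the structure (as with the default phantom margins),
  a prediction that approached the true vessel exactly would be *rejected*
  (its IoU against the box falls below 0.5) — the steady state of the
  refinement is then roughly the eroded box, biased toward dark pixels, not
  the exact vessel. This is a property of the scheme, visible at phantom
  scale; with clinically tight boxes the gate binds differently.
* Left/right separation is a fixed vertical split, not a detection step.
* Training is single-CPU numpy: practical at phantom scale, not at clinical
  resolution; the architecture and training loop are nonetheless the full
  specified ones, parameterized by width and input size.
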