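"""Area-stratified data augmentation.

Carotid cross-sections are small in most axial slices and only occasionally
large/oblique, so uniform augmentation would bias training toward the common
small shapes.  The dataset is therefore split at the mean + 1 SD of the
per-slice mask area: the scarce big-area subset is inflated 7×, the abundant
small-area subset 1.3×.  Augmented copies apply each random transform
independently with its configured probability; geometric transforms are
applied to image and mask with identical parameters, the mask with
nearest-neighbour interpolation so it stays binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import ndimage

from .pseudo_rgb import PseudoRGBSlice, SlicePair
from .records import MaskRecord

__all__ = [
    "AugmentationPolicy",
    "AreaStratification",
    "stratify_by_area",
    "augment_pair",
    "augment_subset",
    "augment_dataset",
]


@dataclass
class AugmentationPolicy:
    """Random transforms and their application probabilities.

    The probabilities are the pipeline defaults: rotation up to ±15° with
    p = 0.9, horizontal/vertical flips p = 0.5 each, contrast p = 0.8,
    gamma p = 0.5, 3×3 blur p = 0.05, Gaussian noise p = 0.05 and
    shift/zoom p = 0.5.  Amplitude ranges for contrast/gamma/noise/shift/zoom
    are configurable (they only have stated probabilities, not ranges).
    """

    rotation_max_deg: float = 15.0
    rotation_p: float = 0.9
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    contrast_p: float = 0.8
    contrast_range: tuple = (0.8, 1.2)
    gamma_p: float = 0.5
    gamma_range: tuple = (0.8, 1.2)
    blur_p: float = 0.05
    blur_kernel: int = 3
    noise_p: float = 0.05
    noise_sigma: float = 0.01
    shift_zoom_p: float = 0.5
    shift_max_frac: float = 0.1
    zoom_range: tuple = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_p", "hflip_p", "vflip_p", "contrast_p",
                     "gamma_p", "blur_p", "noise_p", "shift_zoom_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.rotation_max_deg <= 0:
            raise ValueError("rotation_max_deg must be > 0")


@dataclass
class AreaStratification:
    """Dataset split at threshold = mean + 1·(population SD) of mask areas."""

    threshold: float
    small_ids: list = field(default_factory=list)
    big_ids: list = field(default_factory=list)
    multiplier_small: float = 1.3
    multiplier_big: float = 7.0


def stratify_by_area(pairs, multiplier_small: float = 1.3,
                     multiplier_big: float = 7.0) -> AreaStratification:
    """Split pair indices into small/big-area strata.

    Threshold = mean + population SD of the per-slice mask pixel counts;
    ties (area == threshold) go to the small stratum.
    """
    if not pairs:
        raise ValueError("cannot stratify an empty dataset")
    areas = np.array([int(p.mask.mask.sum()) for p in pairs], dtype=float)
    threshold = float(areas.mean() + areas.std())  # population SD
    small = [i for i, a in enumerate(areas) if a <= threshold]
    big = [i for i, a in enumerate(areas) if a > threshold]
    return AreaStratification(threshold=threshold, small_ids=small, big_ids=big,
                              multiplier_small=multiplier_small,
                              multiplier_big=multiplier_big)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def augment_pair(pair: SlicePair, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> SlicePair:
    """Apply one random draw of the policy's transforms to a pair.

    Geometric transforms (rotation, flips, shift, zoom) act on image and mask
    with the same parameters; the mask uses nearest-neighbour interpolation
    (order 0) and zero padding, so it remains binary.  Intensity transforms
    (contrast, gamma, blur, noise) act on the image only, clipped to [0, 1].
    """
    img = pair.image.data.copy()
    mask = pair.mask.mask.astype(np.float64)

    if rng.random() < policy.rotation_p:
        angle = rng.uniform(-policy.rotation_max_deg, policy.rotation_max_deg)
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=1,
                             mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False, order=0,
                              mode="constant", cval=0.0)
    if rng.random() < policy.hflip_p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < policy.vflip_p:
        img, mask = img[::-1, :], mask[::-1, :]
    if rng.random() < policy.shift_zoom_p:
        h, w = mask.shape
        dy = rng.uniform(-policy.shift_max_frac, policy.shift_max_frac) * h
        dx = rng.uniform(-policy.shift_max_frac, policy.shift_max_frac) * w
        zoom = rng.uniform(*policy.zoom_range)
        # affine about the image centre: scale by 1/zoom then translate
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        matrix = np.eye(2) / zoom
        offset = centre - matrix @ centre - np.array([dy, dx])
        img = np.stack(
            [ndimage.affine_transform(img[..., c], matrix, offset=offset,
                                      order=1, mode="constant", cval=0.0)
             for c in range(3)], axis=-1)
        mask = ndimage.affine_transform(mask, matrix, offset=offset, order=0,
                                        mode="constant", cval=0.0)
    if rng.random() < policy.contrast_p:
        factor = rng.uniform(*policy.contrast_range)
        mean = img.mean()
        img = (img - mean) * factor + mean
    if rng.random() < policy.gamma_p:
        gamma = rng.uniform(*policy.gamma_range)
        img = np.clip(img, 0.0, 1.0) ** gamma
    if rng.random() < policy.blur_p:
        k = policy.blur_kernel
        img = np.stack([ndimage.uniform_filter(img[..., c], size=k, mode="nearest")
                        for c in range(3)], axis=-1)
    if rng.random() < policy.noise_p:
        img = img + rng.normal(0.0, policy.noise_sigma, size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    mask = (mask > 0.5).astype(np.uint8)
    return SlicePair(
        image=PseudoRGBSlice(data=img, slice_index=pair.image.slice_index),
        mask=dc_replace(pair.mask, mask=mask),
        volume_id=pair.volume_id,
    )


def augment_subset(pairs, policy: AugmentationPolicy, multiplier: float,
                   rng: np.random.Generator = None) -> list:
    """Inflate a subset to round(multiplier × n) pairs.

    Output = all originals + round((multiplier − 1) × n) augmented copies,
    with source pairs picked round-robin; rounding is half-up so a 1.3×
    multiplier yields 13 pairs from 10.
    """
    if multiplier < 1:
        raise ValueError(f"multiplier must be >= 1, got {multiplier}")
    pairs = list(pairs)
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    n_extra = _round_half_up((multiplier - 1.0) * len(pairs))
    out = list(pairs)
    for i in range(n_extra):
        out.append(augment_pair(pairs[i % len(pairs)], policy, rng))
    return out


def augment_dataset(pairs, strat: AreaStratification,
                    policy: AugmentationPolicy) -> list:
    """Full stratified augmentation: 1.3× the small stratum, 7× the big one.

    Re-executed fresh (new random draws) for every training round; pass a
    policy with a round-specific seed to vary the draws between rounds.
    """
    rng = np.random.default_rng(policy.seed)
    small = [pairs[i] for i in strat.small_ids]
    big = [pairs[i] for i in strat.big_ids]
    out = []
    if small:
        out.extend(augment_subset(small, policy, strat.multiplier_small, rng))
    if big:
        out.extend(augment_subset(big, policy, strat.multiplier_big, rng))
    return out
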