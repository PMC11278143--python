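"""2.5D pseudo-RGB construction.

Each axial slice is segmented with limited through-plane context by stacking
it with its two neighbours into a 3-channel image: R = the slice below the
target, G = the target slice itself, B = the slice above.  At the volume
boundaries the missing neighbour is replaced by the edge slice itself (edge
replication), so no artificial zero channel is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import MaskRecord

__all__ = ["PseudoRGBSlice", "SlicePair", "stack_neighbors", "build_slice_dataset"]


@dataclass
class PseudoRGBSlice:
    """An H×W×3 stack of (below, target, above) axial slices in [0, 1]."""

    data: np.ndarray
    slice_index: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"expected H×W×3 data, got shape {self.data.shape}")

    @property
    def target(self) -> np.ndarray:
        """The G channel, i.e. the slice being segmented."""
        return self.data[..., 1]


@dataclass
class SlicePair:
    """A pseudo-RGB slice together with its current training mask."""

    image: PseudoRGBSlice
    mask: MaskRecord
    volume_id: str = ""

    def __post_init__(self):
        if self.image.data.shape[:2] != self.mask.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.data.shape[:2]} vs "
                f"{self.mask.mask.shape} (volume {self.volume_id!r})"
            )

    @property
    def slice_index(self) -> int:
        return self.image.slice_index


def stack_neighbors(v, k: int) -> PseudoRGBSlice:
    """Build the pseudo-RGB image for slice ``k`` of a volume.

    Channels are (slice k−1, slice k, slice k+1); missing neighbours at the
    first/last slice are replaced by the edge slice (edge replication).
    """
    data = np.asarray(v.data)
    n = data.shape[0]
    if not 0 <= k < n:
        raise IndexError(f"slice index {k} out of range for {n} slices")
    below = data[max(k - 1, 0)]
    above = data[min(k + 1, n - 1)]
    stacked = np.stack([below, data[k], above], axis=-1)
    return PseudoRGBSlice(data=stacked, slice_index=k)


def build_slice_dataset(samples) -> list:
    """Turn (Volume, MaskVolume) pairs into the per-slice training dataset.

    One :class:`SlicePair` is produced per axial slice whose weak mask is
    non-empty; carotid-free slices are excluded from training.

    Parameters
    ----------
    samples
        Iterable of ``(volume, mask_volume)`` or ``(volume, mask_volume, id)``
        tuples, with volumes already preprocessed to unit-float.
    """
    pairs = []
    for sample_idx, item in enumerate(samples):
        if len(item) == 3:
            vol, mask, vol_id = item
        else:
            (vol, mask), vol_id = item, f"vol{sample_idx}"
        if vol.data.shape != mask.data.shape:
            raise ValueError(
                f"volume/mask shape mismatch for {vol_id!r}: "
                f"{vol.data.shape} vs {mask.data.shape}"
            )
        for k in range(vol.data.shape[0]):
            m = mask.data[k]
            if not m.any():
                continue
            pairs.append(
                SlicePair(
                    image=stack_neighbors(vol, k),
                    mask=MaskRecord(mask=m, provenance="bbox", round=0),
                    volume_id=str(vol_id),
                )
            )
    return pairs
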