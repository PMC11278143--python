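"""Shared per-slice label record used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaskRecord"]


@dataclass
class MaskRecord:
    """A per-slice binary label with its provenance.

    ``provenance`` is ``"bbox"`` for the initial weak bounding boxes or
    ``"refined"`` for a self-training round's output; ``round`` is the round
    index that produced the mask (0 for the initial boxes).  ``side_accept``
    records, for the (left, right) image halves, whether the round's
    prediction passed the per-carotid IoU gate or was reverted to the box.
    """

    mask: np.ndarray
    provenance: str = "bbox"
    round: int = 0
    side_accept: tuple = (True, True)

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError(f"MaskRecord mask must be 2D, got ndim={self.mask.ndim}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("MaskRecord mask must be binary")
        self.mask = self.mask.astype(np.uint8)
        if self.round < 0:
            raise ValueError("round must be >= 0")
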