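"""Synthetic two-tube phantom volumes with weak bounding-box annotations.

The generator emulates the data regime the pipeline is designed for: axial
T1-weighted slices in which the two internal carotid arteries appear as small
dark discs (low signal) inside a brighter background, each surrounded by a
1–2 px even brighter rim (perivascular fat).  Per volume it produces

* the image (unit-float ``Volume``),
* the hidden pixel-level ground truth (evaluation only), and
* loose per-slice bounding boxes around each tube — the weak labels that
  start self-training.

Geometry: two roughly vertical tubes whose centerlines wobble sinusoidally
in-plane, with a localized "bulge" band along the slice axis in which the
cross-section is elongated.  The bulge emulates the larger, oblique sections
the arteries present at some heights, and makes the per-slice mask-area
distribution right-skewed (many small sections, a tail of large ones) — the
same dichotomy the area-stratified augmentation is built to counteract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .volume_io import Volume, MaskVolume, write_volume

__all__ = ["PhantomSpec", "PhantomSample", "generate_phantom", "generate_dataset",
           "write_dataset"]


class GeometryError(ValueError):
    """Raised when the requested tube geometry leaves the field of view."""


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic two-tube volume.

    Intensities are on the unit scale and must satisfy
    ``tube_intensity < background_intensity < fat_ring_intensity``
    (dark vessel lumen in a brighter surround with a bright fat rim).
    ``tube_radius_px`` in [1.5, 3.5] models 4–6 mm vessel diameters at
    1 px = 1 mm.  ``bbox_margin_px``/``bbox_jitter_px`` control how loose the
    weak boxes are; jitter may not exceed the margin so that the ground truth
    always stays inside the weak mask.
    """

    shape: tuple = (16, 32, 32)  # (slices, rows, cols)
    tube_radius_px: float = 2.0
    tube_separation_px: float = 16.0
    centerline_wobble_amp: float = 1.5
    centerline_wobble_period: float = 12.0
    bulge_elongation: float = 2.2   # max cross-section stretch factor
    bulge_sigma_px: float = 2.0     # axial extent (SD) of the bulge band
    tube_intensity: float = 0.15
    background_intensity: float = 0.55
    fat_ring_intensity: float = 0.85
    ring_width_px: float = 1.5
    noise_sigma: float = 0.05
    bbox_margin_px: int = 2
    bbox_jitter_px: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (self.tube_intensity < self.background_intensity < self.fat_ring_intensity):
            raise ValueError(
                "intensity ordering must be tube < background < fat ring, got "
                f"{self.tube_intensity}, {self.background_intensity}, {self.fat_ring_intensity}"
            )
        if self.bbox_margin_px < 0 or self.bbox_jitter_px < 0:
            raise ValueError("bbox margin/jitter must be non-negative")
        if self.bbox_jitter_px > self.bbox_margin_px:
            raise ValueError(
                "bbox_jitter_px must not exceed bbox_margin_px, otherwise the "
                "weak boxes may not contain the ground truth"
            )
        if self.tube_radius_px <= 0:
            raise ValueError("tube_radius_px must be positive")


@dataclass
class PhantomSample:
    """One generated phantom: image, hidden ground truth, weak boxes, spec."""

    volume: Volume
    gt: MaskVolume
    weak: MaskVolume
    spec: PhantomSpec


def _tube_params(spec: PhantomSpec, rng: np.random.Generator):
    """Per-tube centerline phases, bulge centre/orientation."""
    s, h, w = spec.shape
    cols0 = (w / 2.0 - spec.tube_separation_px / 2.0,
             w / 2.0 + spec.tube_separation_px / 2.0)
    params = []
    for col0 in cols0:
        params.append({
            "row0": h / 2.0,
            "col0": col0,
            "phase_r": rng.uniform(0, 2 * np.pi),
            "phase_c": rng.uniform(0, 2 * np.pi),
            "bulge_z": rng.uniform(0, s - 1),
            "bulge_theta": rng.uniform(0, np.pi),
        })
    return params


def _section_geometry(spec: PhantomSpec, tube: dict, z: int):
    """Centre, semi-axes and orientation of a tube's cross-section at slice z."""
    wob = spec.centerline_wobble_amp
    per = max(spec.centerline_wobble_period, 1e-6)
    row = tube["row0"] + wob * np.sin(2 * np.pi * z / per + tube["phase_r"])
    col = tube["col0"] + wob * np.sin(2 * np.pi * z / per + tube["phase_c"])
    elong = 1.0 + (spec.bulge_elongation - 1.0) * np.exp(
        -((z - tube["bulge_z"]) ** 2) / (2.0 * spec.bulge_sigma_px ** 2)
    )
    a = spec.tube_radius_px * elong  # semi-axis along the bulge direction
    b = spec.tube_radius_px
    return row, col, a, b, tube["bulge_theta"]


def _elliptical_rho(rows, cols, row, col, a, b, theta):
    """Normalized elliptical radius: 1.0 on the section boundary."""
    dr, dc = rows - row, cols - col
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Rasterize one phantom volume from its spec (fully seed-deterministic)."""
    s, h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    tubes = _tube_params(spec, rng)

    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((s, h, w), spec.background_intensity, dtype=np.float64)
    gt = np.zeros((s, h, w), dtype=np.uint8)
    tube_masks = np.zeros((2, s, h, w), dtype=bool)

    for ti, tube in enumerate(tubes):
        for z in range(s):
            row, col, a, b, theta = _section_geometry(spec, tube, z)
            if not (a <= row <= h - 1 - a and a <= col <= w - 1 - a):
                raise GeometryError(
                    f"tube {ti} leaves the field of view at slice {z} "
                    f"(centre ({row:.1f},{col:.1f}), semi-axis {a:.1f})"
                )
            rho = _elliptical_rho(rows, cols, row, col, a, b, theta)
            disk = rho <= 1.0
            # normalized rho rescaled by the minor radius approximates the
            # radial distance; ring = 1-2 px brighter rim around the lumen
            ring = (rho > 1.0) & (rho * b <= b + spec.ring_width_px)
            img[z][ring] = spec.fat_ring_intensity
            img[z][disk] = spec.tube_intensity
            tube_masks[ti, z] |= disk
            gt[z][disk] = 1

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    weak = np.zeros((s, h, w), dtype=np.uint8)
    m, j = spec.bbox_margin_px, spec.bbox_jitter_px
    for ti in range(2):
        for z in range(s):
            fg = tube_masks[ti, z]
            if not fg.any():
                continue
            rr, cc = np.nonzero(fg)
            r0, r1 = rr.min() - m, rr.max() + m
            c0, c1 = cc.min() - m, cc.max() + m
            if j > 0:
                dr, dc = rng.integers(-j, j + 1, size=2)
                r0, r1, c0, c1 = r0 + dr, r1 + dr, c0 + dc, c1 + dc
            weak[z, max(r0, 0):r1 + 1, max(c0, 0):c1 + 1] = 1

    volume = Volume(data=img, spacing=(1.0, 1.0, 1.0), dtype_tag="unit-float")
    return PhantomSample(
        volume=volume,
        gt=MaskVolume(data=gt, provenance="ground-truth"),
        weak=MaskVolume(data=weak, provenance="weak-bbox"),
        spec=spec,
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based child seed derivation (stable across platforms)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def generate_dataset(n_volumes: int, spec_template: PhantomSpec = None,
                     contrast_range=(0.05, 0.30), seed: int = 0) -> list:
    """Generate a reproducible list of phantoms with per-volume contrast.

    Each volume's ``tube_intensity`` is drawn uniformly from
    ``contrast_range``, emulating the contrast differences between scans;
    all per-volume seeds derive deterministically from ``seed``.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    lo, hi = contrast_range
    if lo > hi:
        raise ValueError(f"empty contrast range {contrast_range}")
    if spec_template is None:
        spec_template = PhantomSpec()
    rng = np.random.default_rng(derive_seed(seed, 0xC0))
    samples = []
    for i in range(n_volumes):
        spec = replace(
            spec_template,
            tube_intensity=float(rng.uniform(lo, hi)),
            seed=derive_seed(seed, i),
        )
        samples.append(generate_phantom(spec))
    return samples


def write_dataset(samples, out_dir) -> Path:
    """Write NIfTI (volume, gt, weak) triplets plus a JSON spec manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(samples):
        stem = f"phantom_{i:03d}"
        write_volume(s.volume, out_dir / f"{stem}_image.nii.gz")
        write_volume(s.gt, out_dir / f"{stem}_gt.nii.gz")
        write_volume(s.weak, out_dir / f"{stem}_weak.nii.gz")
        entry = asdict(s.spec)
        entry["shape"] = list(s.spec.shape)
        entry["id"] = stem
        manifest.append(entry)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
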