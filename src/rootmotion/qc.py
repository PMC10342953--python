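"""Registration-quality check: overlap of fixed vs. warped segmentations.

After deformable registration, the warped systolic segmentation should sit
on top of the fixed diastolic one; visual dual-channel overlays are the
usual check.  This module provides the scalar surrogate — the Dice
coefficient 2|A ∩ B| / (|A| + |B|) — globally and per axial slice, for
binary masks on identical voxel grids.  NIfTI masks are read via nibabel
with spacing/origin honored from the header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BinaryMask", "dice_overlap", "overlap_report", "OverlapReport", "read_mask"]

DEFAULT_WARN_THRESHOLD = 0.95
_GEOM_TOL = 1e-6


@dataclass(frozen=True)
class BinaryMask:
    """Boolean voxel grid with physical spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=bool)
        if d.ndim != 3 or d.size == 0:
            raise ValueError("mask must be a nonempty 3D grid")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive values")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.data.shape != b.data.shape or any(
        abs(x - y) > _GEOM_TOL for x, y in zip(a.spacing + a.origin, b.spacing + b.origin)
    ):
        raise ValueError(
            "mask grids differ: "
            f"A(shape={a.data.shape}, spacing={a.spacing}, origin={a.origin}) vs "
            f"B(shape={b.data.shape}, spacing={b.spacing}, origin={b.origin})"
        )


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; Dice defined as 1 (vacuous agreement)")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_overlap(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient in [0, 1]; both-empty scores 1 with a warning."""
    _check_same_grid(a, b)
    return _dice(a.data, b.data)


@dataclass(frozen=True)
class OverlapReport:
    global_dice: float
    slice_dice: np.ndarray        # nan where both slices empty
    mismatch_voxels: int
    empty_slice_pairs: np.ndarray  # boolean flags per axial slice

    def below(self, threshold: float = DEFAULT_WARN_THRESHOLD) -> bool:
        return self.global_dice < threshold


def overlap_report(a: BinaryMask, b: BinaryMask, axis: int = 2) -> OverlapReport:
    """Global Dice plus a per-slice profile along ``axis``.

    Slice pairs where both masks are empty are flagged and excluded from
    the profile (NaN) rather than scored.
    """
    _check_same_grid(a, b)
    da = np.moveaxis(a.data, axis, 0)
    db = np.moveaxis(b.data, axis, 0)
    nslices = da.shape[0]
    profile = np.full(nslices, np.nan)
    empty = np.zeros(nslices, dtype=bool)
    for k in range(nslices):
        sa, sb = da[k], db[k]
        if not sa.any() and not sb.any():
            empty[k] = True
            continue
        profile[k] = 2.0 * int((sa & sb).sum()) / (int(sa.sum()) + int(sb.sum()))
    return OverlapReport(
        global_dice=_dice(a.data, b.data),
        slice_dice=profile,
        mismatch_voxels=int((a.data ^ b.data).sum()),
        empty_slice_pairs=empty,
    )


def read_mask(path, threshold: float = 0.5) -> BinaryMask:
    """Load a NIfTI volume as a binary mask (voxels > threshold)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return BinaryMask(data=data > threshold, spacing=spacing, origin=origin)
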