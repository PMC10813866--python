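"""Tissue masking and patch extraction for histology images.

Implements the standard whole-slide pre-processing chain — grayscale,
Otsu threshold (tissue = darker than glass), dilation, hole filling,
small-object removal — followed by exhaustive non-overlapping 512-px
tiling with a >=80 % tissue filter and a >=15 % nucleus-percentage
filter on each tile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, remove_small_holes, remove_small_objects

from .density import nucleus_pixel_mask

__all__ = [
    "TissueMask",
    "TilePatch",
    "compute_tissue_mask",
    "extract_patches",
    "nucleus_score",
    "filter_patches",
    "patch_manifest",
]


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, same H x W as source

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class TilePatch:
    """One tile: origin (row, col) is 0-based, top-left, half-open extent."""

    patient_id: str | None
    row: int
    col: int
    size: int
    image: np.ndarray
    tissue_fraction: float
    nucleus_score: float | None = None


def _luminance(image: np.ndarray) -> np.ndarray:
    # ITU-R 601 weights
    img = image.astype(float)
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def compute_tissue_mask(
    image: np.ndarray,
    dilation_radius: int = 2,
    min_hole_area: int = 256,
    min_object_area: int = 1024,
    glass_min_brightness: float = 245.0,
) -> TissueMask:
    """Segment tissue from glass background.

    Pipeline, in order: ITU-R 601 luminance -> Otsu threshold with tissue
    on the darker side -> binary dilation (disk ``dilation_radius``) ->
    fill holes smaller than ``min_hole_area`` -> remove connected
    components smaller than ``min_object_area``.

    Slide glass scans near-saturated white.  If Otsu's brighter class is
    not near-white (mean below ``glass_min_brightness``) the frame
    contains no glass at all — e.g. a tile entirely inside tissue — and
    the whole frame is tissue; plain darker-side Otsu would otherwise
    keep only the nuclei of such a tile.  A fully uniform image (Otsu
    undefined) yields an empty mask with a warning.
    """
    if image.size == 0:
        raise ValueError("empty image")
    gray = _luminance(image)
    if float(gray.max() - gray.min()) == 0.0:
        warnings.warn("uniform image: Otsu threshold undefined, returning empty tissue mask")
        return TissueMask(np.zeros(gray.shape, dtype=bool))
    th = threshold_otsu(gray)
    upper_mean = float(gray[gray > th].mean()) if (gray > th).any() else 255.0
    if upper_mean < glass_min_brightness:
        mask = np.ones(gray.shape, dtype=bool)
    else:
        mask = gray < th
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius))
    if min_hole_area > 0 and mask.any():
        mask = remove_small_holes(mask, max_size=min_hole_area - 1)
    if min_object_area > 0 and mask.any():
        mask = remove_small_objects(mask, max_size=min_object_area - 1)
    return TissueMask(mask)


def extract_patches(
    image: np.ndarray,
    mask: TissueMask,
    patch_size: int = 512,
    tissue_threshold: float = 0.8,
    patient_id: str | None = None,
) -> list[TilePatch]:
    """Non-overlapping grid tiling from (0, 0); partial edge tiles dropped.

    Returns, in row-major order, exactly the grid tiles whose within-tile
    tissue-mask mean is >= ``tissue_threshold``.
    """
    if not 0.0 <= tissue_threshold <= 1.0:
        raise ValueError("tissue_threshold must be in [0, 1]")
    h, w = image.shape[:2]
    if mask.mask.shape != (h, w):
        raise ValueError("mask shape does not match image")
    if h < patch_size or w < patch_size:
        warnings.warn("image smaller than patch_size: no patches extracted")
        return []
    patches = []
    for r in range(0, h - patch_size + 1, patch_size):
        for c in range(0, w - patch_size + 1, patch_size):
            frac = float(mask.mask[r:r + patch_size, c:c + patch_size].mean())
            if frac >= tissue_threshold:
                patches.append(TilePatch(
                    patient_id=patient_id, row=r, col=c, size=patch_size,
                    image=image[r:r + patch_size, c:c + patch_size],
                    tissue_fraction=frac,
                ))
    return patches


def nucleus_score(patch: TilePatch | np.ndarray) -> float:
    """Fraction of patch pixels classified as nucleus.

    Uses the same hematoxylin-channel classifier that seeds the watershed
    foreground, so the patch filter and the segmentation agree on what a
    nucleus pixel is.  When given a TilePatch the score is also stored on
    the patch.
    """
    image = patch.image if isinstance(patch, TilePatch) else patch
    score = float(nucleus_pixel_mask(image).mean())
    if isinstance(patch, TilePatch):
        patch.nucleus_score = score
    return score


def filter_patches(patches: Sequence[TilePatch], min_score: float = 0.15) -> list[TilePatch]:
    """Retain patches with nucleus_score >= min_score (inclusive), order preserved."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    kept = []
    for p in patches:
        if p.nucleus_score is None:
            nucleus_score(p)
        if p.nucleus_score >= min_score:
            kept.append(p)
    if patches and not kept:
        warnings.warn("no patches passed the nucleus-score filter; slide will be excluded")
    return kept


def patch_manifest(patches: Sequence[TilePatch], kept: Sequence[TilePatch]) -> pd.DataFrame:
    """Tabulate all candidate patches with their scores and kept flag."""
    kept_keys = {(p.patient_id, p.row, p.col) for p in kept}
    rows = []
    for p in patches:
        rows.append({
            "patient_id": p.patient_id,
            "row": p.row,
            "col": p.col,
            "tissue_fraction": p.tissue_fraction,
            "nucleus_score": p.nucleus_score,
            "kept": (p.patient_id, p.row, p.col) in kept_keys,
        })
    return pd.DataFrame(rows)
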