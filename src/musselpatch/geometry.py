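"""Patch morphometry from binary cover masks.

Mussel cover in each cage photograph is reduced to a binary mask; mussels in
physical contact belong to the same patch, so patches are the 8-connected
components of the mask.  The shape statistic of interest is the
perimeter-to-area ratio (PtoA, mm^-1), computed on totals across all patches
in a cage: large coalesced patches have low PtoA, small fragmented ones high
PtoA.

Perimeter estimation
--------------------
Counting pixel edges overestimates smooth boundaries by up to ~27%, so the
perimeter is measured on the marching-squares boundary polygon with weighted
segment lengths: straight (axis-aligned, 1 px) segments weighted 0.985 and
diagonal corner segments weighted 0.665.  The weights were calibrated by
least squares against analytic discs, axis-aligned squares and rotated
squares; the estimator is within ~2.6% of the true perimeter for discs
(r >= 16 px) and axis-aligned squares (side >= 32 px), and within ~6% for
edges at exactly 45 degrees.  Hole boundaries are included by default
(``include_holes=False`` fills holes before measuring).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

# Calibrated weights of the boundary-polygon perimeter estimator.
_W_STRAIGHT = 0.985
_W_DIAGONAL = 0.665


class EmptyMaskError(ValueError):
    """Geometry is undefined for a mask with no foreground."""


@dataclass
class CoverMask:
    """A binary cover mask plus its pixel calibration."""

    pixels: np.ndarray            # 2-D bool array, True = mussel
    scale_mm_per_px: float
    provenance: str = "synthetic"  # "synthetic" | "digitized"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be > 0")


@dataclass(frozen=True)
class PatchMetrics:
    n_patches: int
    total_area_mm2: float
    total_perimeter_mm: float
    ptoa: float  # mm^-1


def calibrate_scale(reference_length_px: float,
                    reference_length_mm: float = 153.0) -> float:
    """Pixel calibration from a reference object of known length.

    The default reference is the 15.3 cm marker photographed alongside the
    mussels.
    """
    if reference_length_px <= 0:
        raise ValueError("reference_length_px must be > 0")
    if reference_length_mm <= 0:
        raise ValueError("reference_length_mm must be > 0")
    return reference_length_mm / reference_length_px


def label_patches(mask: CoverMask) -> np.ndarray:
    """Label 8-connected patches; background is 0.

    8-connectivity matches the physical-contact definition of a patch
    (diagonally touching mussels are connected).  Labels are assigned in
    row-major order of each patch's first pixel.
    """
    if mask.pixels.size == 0:
        raise ValueError("mask grid is empty")
    return measure.label(mask.pixels, connectivity=2)


def perimeter_weighted(pixels: np.ndarray) -> float:
    """Weighted boundary-polygon perimeter of a binary image, in pixels.

    See the module docstring for the estimator and its tolerances.  Interior
    hole boundaries are included.
    """
    pad = np.pad(np.asarray(pixels, dtype=float), 1)
    total = 0.0
    for contour in measure.find_contours(pad, 0.5):
        d = np.diff(contour, axis=0)
        seglen = np.hypot(d[:, 0], d[:, 1])
        straight = np.isclose(seglen, 1.0)
        total += _W_STRAIGHT * float(seglen[straight].sum())
        total += _W_DIAGONAL * float(np.count_nonzero(~straight))
    return total


def patch_metrics(mask: CoverMask, include_holes: bool = True) -> PatchMetrics:
    """Calibrated area, perimeter and PtoA, aggregated over all patches.

    PtoA is total perimeter over total area for the whole cage (one value
    per mask), not a per-patch average.
    """
    pixels = mask.pixels
    if not pixels.any():
        raise EmptyMaskError("PtoA undefined: mask has no foreground")
    if not include_holes:
        pixels = ndimage.binary_fill_holes(pixels)
    scale = mask.scale_mm_per_px
    n_patches = int(measure.label(pixels, connectivity=2).max())
    area = float(np.count_nonzero(pixels)) * scale ** 2
    perim = perimeter_weighted(pixels) * scale
    return PatchMetrics(
        n_patches=n_patches,
        total_area_mm2=area,
        total_perimeter_mm=perim,
        ptoa=perim / area,
    )


# ---------------------------------------------------------------------- #
# mask I/O: single-channel PNG/PGM (any nonzero pixel = foreground) plus
# a JSON sidecar holding the calibration
# ---------------------------------------------------------------------- #

def write_mask(mask: CoverMask, path) -> None:
    path = Path(path)
    img = Image.fromarray((mask.pixels.astype(np.uint8)) * 255, mode="L")
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"scale_mm_per_px": mask.scale_mm_per_px, "provenance": mask.provenance}
    ))


def read_mask(path) -> CoverMask:
    path = Path(path)
    img = Image.open(path).convert("L")
    pixels = np.asarray(img) > 0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        scale = float(meta["scale_mm_per_px"])
        provenance = meta.get("provenance", "digitized")
    else:
        scale, provenance = 1.0, "digitized"
    return CoverMask(pixels=pixels, scale_mm_per_px=scale, provenance=provenance)
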