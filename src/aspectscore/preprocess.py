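"""Standardization of axial head-CT slices.

A raw slice arrives as Hounsfield-Unit (HU) pixel values.  Before any region
statistics are computed the slice is standardized:

1. **HU windowing** — only parenchymal densities are kept.  Pixels outside
   10–55 HU (cerebrospinal fluid, chronic infarcts below; bone and
   calcification above) are flagged for exclusion; pixel values themselves
   are never modified.
2. **Skull stripping** — the skull is found by an intensity threshold, the
   largest closed skull contour is selected, and the brain mask is its
   interior with all above-threshold pixels removed.
3. **Crop and pad** — the brain bounding box is cropped, rescaled
   preserving aspect ratio, and centered on a square canvas of a standard
   size with 0-HU background, so that atlas registration starts from a
   comparable geometry for every patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .exceptions import SkullStripError, ValidationError

# Parenchymal HU window: inclusive bounds.
HU_WINDOW_LO = 10.0
HU_WINDOW_HI = 55.0
# Default skull threshold; cortical bone is ~1000 HU, calcifications lower.
SKULL_THRESHOLD_HU = 300.0

SliceLevel = Literal["basal_ganglia", "cortical", "unknown"]


@dataclass
class HUImage:
    """One axial slice in Hounsfield Units.

    Parameters
    ----------
    pixels
        2D float array of HU values (water = 0, air = -1000).
    spacing
        (row, col) pixel spacing in mm.
    level
        Slice level tag: ``"basal_ganglia"``, ``"cortical"`` or ``"unknown"``.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (0.5, 0.5)
    level: SliceLevel = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("HUImage requires a 2D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("HUImage pixels must be finite")
        if not (self.spacing[0] > 0 and self.spacing[1] > 0):
            raise ValidationError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BrainMask:
    """Boolean brain mask aligned to one :class:`HUImage`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def window_hu(
    img: HUImage, lo: float = HU_WINDOW_LO, hi: float = HU_WINDOW_HI
) -> np.ndarray:
    """Boolean grid of pixels retained by the parenchymal HU window.

    A pixel is retained iff ``lo <= HU <= hi`` (bounds inclusive).  The image
    itself is untouched; downstream statistics simply ignore excluded pixels.
    """
    if not lo < hi:
        raise ValidationError(f"window bounds must satisfy lo < hi, got ({lo}, {hi})")
    return (img.pixels >= lo) & (img.pixels <= hi)


def strip_skull(
    img: HUImage, skull_threshold: float = SKULL_THRESHOLD_HU
) -> BrainMask:
    """Isolate the brain as the interior of the largest closed skull contour.

    Above-threshold pixels are labeled; the largest connected component is
    taken as the skull ring; the mask is its hole-filled interior with every
    above-threshold pixel (skull and calcifications) removed.

    Raises
    ------
    SkullStripError
        If no above-threshold component exists or the ring encloses nothing.
    """
    bone = img.pixels >= skull_threshold
    if not bone.any():
        raise SkullStripError(
            f"no pixels at or above the skull threshold ({skull_threshold} HU); "
            "is this a head CT in Hounsfield Units?"
        )
    labels, n = ndimage.label(bone)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    ring = labels == largest
    interior = ndimage.binary_fill_holes(ring) & ~bone
    if not interior.any():
        raise SkullStripError(
            "largest skull component is not a closed ring (empty interior)"
        )
    return BrainMask(interior)


@dataclass
class CropPadTransform:
    """Resampling parameters shared between an image and its label maps.

    Applying the same transform to the HU slice (bilinear) and to integer
    label maps (nearest neighbor) keeps them aligned after standardization.
    """

    row_slice: tuple[int, int]
    col_slice: tuple[int, int]
    zoom: float
    out_size: int
    offset: tuple[int, int] = field(default=(0, 0))

    def apply(self, arr: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        r0, r1 = self.row_slice
        c0, c1 = self.col_slice
        crop = np.asarray(arr, dtype=np.float64 if order > 0 else arr.dtype)[
            r0:r1, c0:c1
        ]
        if order == 0:
            scaled = ndimage.zoom(crop, self.zoom, order=0, mode="grid-constant",
                                  cval=fill, grid_mode=True)
        else:
            scaled = ndimage.zoom(crop, self.zoom, order=1, mode="grid-constant",
                                  cval=fill, grid_mode=True)
        out = np.full((self.out_size, self.out_size), fill,
                      dtype=scaled.dtype)
        h, w = scaled.shape
        r_off = (self.out_size - h) // 2
        c_off = (self.out_size - w) // 2
        # Clip if rounding made the scaled crop one pixel too large.
        rs, cs = max(r_off, 0), max(c_off, 0)
        scaled = scaled[: self.out_size, : self.out_size]
        out[rs : rs + scaled.shape[0], cs : cs + scaled.shape[1]] = scaled
        object.__setattr__(self, "offset", (rs, cs))
        return out


def plan_crop_pad(mask: BrainMask, out_size: int) -> CropPadTransform:
    """Compute the crop/zoom that centers the brain on an ``out_size`` canvas."""
    if not mask.mask.any():
        raise ValidationError("cannot crop with an empty brain mask")
    rows = np.any(mask.mask, axis=1)
    cols = np.any(mask.mask, axis=0)
    r0, r1 = int(np.argmax(rows)), int(len(rows) - np.argmax(rows[::-1]))
    c0, c1 = int(np.argmax(cols)), int(len(cols) - np.argmax(cols[::-1]))
    h, w = r1 - r0, c1 - c0
    zoom = min(out_size / h, out_size / w)
    return CropPadTransform((r0, r1), (c0, c1), zoom, out_size)


def crop_and_pad(
    img: HUImage, mask: BrainMask, out_size: int
) -> tuple[HUImage, CropPadTransform]:
    """Crop to the brain, rescale preserving aspect ratio, center on a canvas.

    Pixels outside the brain mask are set to the 0-HU background before
    resampling so air (-1000 HU) and skull never bleed into the brain edge.
    The brain bounding-box centroid maps to the canvas center within one
    pixel; the zoom factor never distorts aspect ratio.

    Returns the standardized image together with the reusable
    :class:`CropPadTransform` (apply it with ``order=0`` to co-transform
    label maps).
    """
    if img.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    plan = plan_crop_pad(mask, out_size)
    masked = np.where(mask.mask, img.pixels, 0.0)
    out = plan.apply(masked, order=1, fill=0.0)
    new_spacing = (img.spacing[0] / plan.zoom, img.spacing[1] / plan.zoom)
    return HUImage(out, spacing=new_spacing, level=img.level), plan


def median_denoise(img: HUImage, size: int = 3) -> HUImage:
    """Optional median-filter denoising (off by default in the pipeline).

    Kept separate and opt-in because smoothing alters the per-region pixel
    statistics that the detectors consume.
    """
    return HUImage(
        ndimage.median_filter(img.pixels, size=size),
        spacing=img.spacing,
        level=img.level,
    )
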