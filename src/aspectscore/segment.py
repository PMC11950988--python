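"""Atlas-to-patient alignment and region-mask transfer.

The labeled two-slice atlas is aligned to each standardized patient slice
with a 2D similarity transform (rotation, isotropic scale, translation)
optimized under a Mattes mutual-information metric over a multi-resolution
pyramid, optionally refined by a coarse B-spline nonrigid step.  The ten
region labels are then resampled into the patient frame with
nearest-neighbor interpolation, and the small internal basal-ganglia
structures (C, L, IC, I) are dilated slightly to absorb residual boundary
error, with overlaps resolved deterministically by nearest original-mask
centroid.

Both images are intensity-windowed before registration so soft tissue,
CSF and skull produce a small number of well-separated intensity classes
for the mutual-information histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.morphology import disk

from .exceptions import RegistrationError, SegmentationError, ValidationError
from .phantom import BASAL_GANGLIA_REGIONS, LEVEL_OF_REGION, REGIONS, RegionAtlas
from .preprocess import HUImage

#: Mattes MI on well-overlapping structured slices typically reaches
#: values well below this; pure noise or gross misalignment stays above.
DEFAULT_METRIC_FLOOR = -0.15


@dataclass
class SimilarityTransform2D:
    """Rigid similarity transform: rotation (rad), scale, translation (px).

    ``center`` is the fixed rotation center in pixel coordinates.
    Translation follows the resampling convention: it maps points of the
    fixed (patient) image into the moving (atlas) image.
    """

    rotation: float
    scale: float
    translation: tuple[float, float]
    center: tuple[float, float] = (0.0, 0.0)
    metric: float | None = None

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError("similarity scale must be positive")

    def to_sitk(self) -> sitk.Similarity2DTransform:
        t = sitk.Similarity2DTransform()
        t.SetCenter(self.center)
        t.SetAngle(self.rotation)
        t.SetScale(self.scale)
        t.SetTranslation(self.translation)
        return t

    @classmethod
    def from_sitk(
        cls, t: sitk.Similarity2DTransform, metric: float | None = None
    ) -> "SimilarityTransform2D":
        return cls(
            rotation=float(t.GetAngle()),
            scale=float(t.GetScale()),
            translation=tuple(t.GetTranslation()),
            center=tuple(t.GetCenter()),
            metric=metric,
        )

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "SimilarityTransform2D":
        c = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
        return cls(0.0, 1.0, (0.0, 0.0), center=c)


def _to_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(img, dtype=np.float32))


def _registration_window(pixels: np.ndarray) -> np.ndarray:
    """Clip to [-20, 80] HU so tissue contrast dominates the MI histogram;
    skull saturates at the top, air at the bottom."""
    return np.clip(pixels, -20.0, 80.0)


def register_rigid(
    atlas_img: HUImage,
    patient_img: HUImage,
    bins: int = 32,
    levels: int = 3,
    *,
    metric_floor: float = DEFAULT_METRIC_FLOOR,
) -> SimilarityTransform2D:
    """Similarity registration of the atlas slice onto a patient slice.

    Mattes mutual information (``bins`` histogram bins) over a
    ``levels``-deep shrink pyramid, dense sampling (no random subsampling),
    regular-step gradient descent: deterministic for fixed inputs.

    Raises :class:`RegistrationError` (carrying the final metric) when the
    optimizer lands above ``metric_floor`` — e.g. on structureless input.
    """
    if atlas_img.shape != patient_img.shape:
        raise ValidationError("atlas and patient slices must share a standard size")
    fixed = _to_sitk(_registration_window(patient_img.pixels))
    moving = _to_sitk(_registration_window(atlas_img.pixels))

    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Similarity2DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(f // 2, 0) for f in shrink])

    try:
        result = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # pragma: no cover - ITK-internal failures
        raise RegistrationError(f"registration failed: {exc}") from exc
    result = result.Downcast() if hasattr(result, "Downcast") else result
    if isinstance(result, sitk.CompositeTransform):
        result = result.GetNthTransform(0).Downcast()
    sim = sitk.Similarity2DTransform(result)

    # The MI landscape of near-aligned images is non-convex enough that the
    # optimizer can wander off a perfect start; compare the optimized
    # transform against the initial one at full resolution and keep the
    # better of the two.
    init_sim = sitk.Similarity2DTransform(
        init.Downcast() if hasattr(init, "Downcast") else init
    )
    metric_final = _metric_value(fixed, moving, bins, sim)
    metric_init = _metric_value(fixed, moving, bins, init_sim)
    if metric_init <= metric_final:
        sim, metric = init_sim, metric_init
    else:
        metric = metric_final

    if metric > metric_floor:
        raise RegistrationError(
            f"registration did not converge: final mutual-information metric "
            f"{metric:.4f} above floor {metric_floor}",
            metric=metric,
        )
    return SimilarityTransform2D.from_sitk(sim, metric=metric)


def refine_nonrigid(
    atlas_img: HUImage,
    patient_img: HUImage,
    init: SimilarityTransform2D,
    *,
    mesh: tuple[int, int] = (8, 8),
    bins: int = 32,
    improvement_tol: float = 1e-3,
    iterations: int = 40,
) -> np.ndarray:
    """Coarse B-spline refinement after rigid alignment.

    Starts from a zero displacement on an ``mesh`` control grid, optimizes
    mutual information with L-BFGS-B, and returns the dense displacement
    field (H, W, 2) in (x, y) order.  When the metric improvement over the
    rigid result is below ``improvement_tol`` the identity (zero) field is
    returned, so this step can never make the alignment worse.
    """
    fixed = _to_sitk(_registration_window(patient_img.pixels))
    moving = _to_sitk(_registration_window(atlas_img.pixels))

    # Work on the atlas pre-warped by the rigid transform so the B-spline
    # only models residual deformation.
    pre = sitk.Resample(moving, fixed, init.to_sitk(), sitk.sitkLinear, 0.0)

    bspline = sitk.BSplineTransformInitializer(fixed, [mesh[0], mesh[1]])

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(bspline, inPlace=True)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7, numberOfIterations=iterations
    )
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1, 0])

    baseline = _metric_value(fixed, pre, bins)
    try:
        reg.Execute(fixed, pre)
        refined_metric = float(reg.GetMetricValue())
    except RuntimeError:
        refined_metric = baseline  # fall back to identity

    h, w = patient_img.shape
    # Metrics are negative; lower is better.  Require a real improvement.
    if refined_metric >= baseline - improvement_tol:
        return np.zeros((h, w, 2), dtype=np.float64)

    field_img = sitk.TransformToDisplacementField(
        bspline, sitk.sitkVectorFloat64, fixed.GetSize(),
        fixed.GetOrigin(), fixed.GetSpacing(), fixed.GetDirection(),
    )
    return sitk.GetArrayFromImage(field_img)


def _metric_value(
    fixed: sitk.Image, moving: sitk.Image, bins: int,
    transform: sitk.Transform | None = None,
) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(
        transform if transform is not None else sitk.TranslationTransform(2),
        inPlace=False,
    )
    return float(reg.MetricEvaluate(fixed, moving))


@dataclass
class RegionMaskSet:
    """Per-(region, side) boolean masks for one slice level."""

    level: str
    masks: dict[tuple[str, str], np.ndarray]
    provenance: SimilarityTransform2D | None = None
    adjusted: bool = False

    def mask(self, region: str, side: str) -> np.ndarray:
        return self.masks[(region, side)]

    def regions(self) -> list[str]:
        return sorted({r for (r, _s) in self.masks}, key=REGIONS.index)


def transfer_masks(
    atlas: RegionAtlas,
    transform: SimilarityTransform2D,
    field: np.ndarray | None = None,
    *,
    level: str,
    reference_shape: tuple[int, int] | None = None,
    label_map: np.ndarray | None = None,
    table: dict[int, tuple[str, str]] | None = None,
) -> RegionMaskSet:
    """Resample the atlas label map into the patient frame (nearest neighbor).

    ``label_map``/``table`` may override the atlas's native labels, e.g.
    when the atlas was co-standardized with its reference image.  Raises
    :class:`SegmentationError` naming the first region that comes out empty.
    """
    lab = atlas.labels[level] if label_map is None else label_map
    tab = atlas.table if table is None else table
    shape = reference_shape or lab.shape

    ref = sitk.Image(int(shape[1]), int(shape[0]), sitk.sitkInt16)
    lab_img = sitk.GetImageFromArray(np.ascontiguousarray(lab, dtype=np.int16))

    tx: sitk.Transform = transform.to_sitk()
    if field is not None and np.any(field):
        disp = sitk.GetImageFromArray(np.ascontiguousarray(field), isVector=True)
        disp.CopyInformation(ref)
        # CompositeTransform applies the last-added transform first: the
        # B-spline residual maps patient points into the rigidly-aligned
        # frame, then the similarity transform maps into the atlas.
        composite = sitk.CompositeTransform(2)
        composite.AddTransform(tx)
        composite.AddTransform(sitk.DisplacementFieldTransform(disp))
        tx = composite

    moved = sitk.Resample(lab_img, ref, tx, sitk.sitkNearestNeighbor, 0)
    moved_arr = sitk.GetArrayFromImage(moved)

    masks: dict[tuple[str, str], np.ndarray] = {}
    for label, (region, side) in tab.items():
        if LEVEL_OF_REGION[region] != level:
            continue
        m = moved_arr == label
        if not m.any():
            raise SegmentationError(
                f"region {region} ({side}) empty after mask transfer", region=region
            )
        masks[(region, side)] = m
    return RegionMaskSet(level=level, masks=masks, provenance=transform)


def dilate_internal(
    maskset: RegionMaskSet,
    radius: int = 1,
    brain_mask: np.ndarray | None = None,
) -> RegionMaskSet:
    """Dilate the internal basal-ganglia masks (C, L, IC, I) by ``radius``.

    Dilated masks are clipped to the brain mask and kept mutually disjoint:
    a pixel claimed by several dilated regions goes to the region whose
    original-mask centroid is nearest (ties broken by region name order).
    Cortical sectors M1–M6 are untouched.
    """
    if radius < 0:
        raise ValidationError("dilation radius must be >= 0")
    if radius == 0:
        return maskset

    internal = [
        (r, s) for (r, s) in maskset.masks if r in BASAL_GANGLIA_REGIONS
    ]
    if not internal:
        return maskset

    selem = disk(radius)
    new_masks = dict(maskset.masks)
    others = np.zeros_like(next(iter(maskset.masks.values())), dtype=bool)
    for key, m in maskset.masks.items():
        if key not in internal:
            others |= m

    dilated = {
        key: ndimage.binary_dilation(maskset.masks[key], structure=selem)
        for key in internal
    }
    centroids = {
        key: ndimage.center_of_mass(maskset.masks[key]) for key in internal
    }

    claim = np.zeros(others.shape, dtype=int)
    for key in internal:
        d = dilated[key]
        if brain_mask is not None:
            d = d & brain_mask
        d = d & ~others  # never steal from cortical sectors
        dilated[key] = d
        claim += d.astype(int)

    overlap = claim > 1
    if overlap.any():
        rr, cc = np.nonzero(overlap)
        order = sorted(internal)  # deterministic tie-break
        for r_px, c_px in zip(rr, cc):
            best = None
            best_d = np.inf
            for key in order:
                if dilated[key][r_px, c_px]:
                    cy, cx = centroids[key]
                    dist = (r_px - cy) ** 2 + (c_px - cx) ** 2
                    if dist < best_d:
                        best_d = dist
                        best = key
            for key in internal:
                if key != best:
                    dilated[key][r_px, c_px] = False

    for key in internal:
        new_masks[key] = dilated[key]
    return RegionMaskSet(
        level=maskset.level, masks=new_masks,
        provenance=maskset.provenance, adjusted=True,
    )
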