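"""Synthetic two-slice head-CT phantoms with known ASPECTS region masks.

The ASPECTS (Alberta Stroke Program Early CT Score) divides the middle
cerebral artery territory into ten regions per hemisphere: four basal
ganglia structures — caudate head (C), insular ribbon (I), internal capsule
(IC), lentiform nucleus (L) — and six cortical sectors M1–M6, split across
two axial slice levels (basal ganglia and cortical/supraganglionic).

This module builds deterministic elliptical phantoms of that geometry —
skull ring, parenchyma in the 25–50 HU range, CSF pockets below 10 HU,
bilaterally mirrored region masks — and simulates patients and cohorts with
known lesion ground truth: an ischemic lesion is a fixed HU decrement inside
one region on one hemisphere plus i.i.d. Gaussian noise.  Every downstream
stage (stripping, registration, detection, calibration, scoring) is thereby
testable without clinical data.

The M1–M3 sectors are placed on the basal-ganglia level and M4–M6 on the
cortical level, following the standard ASPECTS template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import SizingError, ValidationError
from .preprocess import HUImage

REGIONS: tuple[str, ...] = ("C", "I", "IC", "L", "M1", "M2", "M3", "M4", "M5", "M6")
BASAL_GANGLIA_REGIONS: tuple[str, ...] = ("C", "I", "IC", "L")
CORTICAL_REGIONS: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6")
SIDES: tuple[str, ...] = ("left", "right")
LEVELS: tuple[str, ...] = ("basal_ganglia", "cortical")

#: Which slice level carries each region (standard ASPECTS template;
#: configurable by rebuilding the atlas with a different mapping).
LEVEL_OF_REGION: dict[str, str] = {
    "C": "basal_ganglia",
    "I": "basal_ganglia",
    "IC": "basal_ganglia",
    "L": "basal_ganglia",
    "M1": "basal_ganglia",
    "M2": "basal_ganglia",
    "M3": "basal_ganglia",
    "M4": "cortical",
    "M5": "cortical",
    "M6": "cortical",
}

#: Nominal parenchymal HU per region.  Deep gray nuclei are slightly denser
#: than cortex; white-matter tracts (IC) are lower.  All within 25–50 HU.
DEFAULT_BASELINE_HU: dict[str, float] = {
    "parenchyma": 34.0,
    "C": 40.0,
    "I": 39.0,
    "IC": 31.0,
    "L": 41.0,
    "M1": 38.0,
    "M2": 38.0,
    "M3": 38.0,
    "M4": 38.0,
    "M5": 38.0,
    "M6": 38.0,
}

AIR_HU = -1000.0


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the synthetic head phantom."""

    image_size: int = 256
    skull_hu: float = 1000.0
    baseline_hu: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_HU)
    )
    csf_hu: float = 4.0
    noise_sd: float = 1.5
    spacing: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise SizingError("image_size must be at least 64 pixels")
        if isinstance(self.baseline_hu, (int, float)):
            v = float(self.baseline_hu)
            self.baseline_hu = {k: v for k in ("parenchyma", *REGIONS)}
        for region in REGIONS:
            hu = self.baseline_hu.get(region, self.baseline_hu["parenchyma"])
            if not 10.0 < hu < 55.0:
                raise ValidationError(
                    f"baseline HU for {region} ({hu}) outside the open (10, 55) band"
                )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.csf_hu >= 10.0:
            raise ValidationError("csf_hu must lie below the 10 HU window floor")

    def region_baseline(self, region: str) -> float:
        return float(self.baseline_hu.get(region, self.baseline_hu["parenchyma"]))


@dataclass
class RegionAtlas:
    """Two labeled slices assigning pixels to (region, patient side).

    ``labels`` maps each level to an int16 label map (0 = unlabeled) and
    ``table`` maps each nonzero label to its (region, side) pair.  The side
    is the PATIENT side, stored explicitly per component — it is never
    inferred from array orientation.
    """

    labels: dict[str, np.ndarray]
    table: dict[int, tuple[str, str]]
    brain: dict[str, np.ndarray]
    spacing: tuple[float, float] = (0.5, 0.5)

    @property
    def region_ids(self) -> tuple[str, ...]:
        return REGIONS

    @property
    def level_of_region(self) -> dict[str, str]:
        return dict(LEVEL_OF_REGION)

    def label_of(self, region: str, side: str) -> int:
        for lab, (r, s) in self.table.items():
            if r == region and s == side:
                return lab
        raise ValidationError(f"no label for region {region!r} side {side!r}")

    def mask(self, region: str, side: str) -> np.ndarray:
        """Boolean mask of a region on the patient's given side."""
        level = LEVEL_OF_REGION[region]
        return self.labels[level] == self.label_of(region, side)


def _ellipse(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _rho(shape: tuple[int, int], center: float, ry: float, rx: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.sqrt(((rr - center) / ry) ** 2 + ((cc - center) / rx) ** 2)


# Label numbering: label = 2 * region_index + side_index + 1, with side
# index 0 = the hemisphere drawn on the array-right half.  By convention the
# array-right half is the patient's LEFT hemisphere (explicit, not inferred).
_ARRAY_RIGHT_SIDE = "left"
_ARRAY_LEFT_SIDE = "right"


def build_atlas(config: PhantomConfig) -> RegionAtlas:
    """Deterministic two-level region atlas for a given image size.

    One hemisphere's masks are constructed analytically on the array-right
    half-plane and mirrored across the midline column, so left/right masks
    are exact reflections with identical pixel counts.
    """
    s = config.image_size
    shape = (s, s)
    c0 = (s - 1) / 2.0
    ry, rx = 0.42 * s, 0.36 * s
    rho = _rho(shape, c0, ry, rx)
    brain = rho <= 1.0

    rr, cc = np.mgrid[0:s, 0:s]
    right_half = cc > c0  # array-right half-plane (strict: midline excluded)

    # CSF ventricle pockets near the midline, mirrored; carved out of every
    # region so the HU window has something to exclude inside the brain.
    vent_half = _ellipse(shape, (c0 - 0.04 * s, c0 + 0.03 * s), (0.07 * s, 0.014 * s))
    vent = (vent_half & right_half) | np.fliplr(vent_half & right_half)
    vent_cort = _ellipse(shape, (c0 - 0.02 * s, c0 + 0.025 * s), (0.05 * s, 0.012 * s))
    vent_cortical = (vent_cort & right_half) | np.fliplr(vent_cort & right_half)

    # Basal-ganglia level internal structures (one hemisphere).
    half = {}
    half["C"] = _ellipse(shape, (c0 - 0.10 * s, c0 + 0.065 * s), (0.05 * s, 0.032 * s))
    half["L"] = _ellipse(shape, (c0 - 0.01 * s, c0 + 0.125 * s), (0.065 * s, 0.042 * s))
    half["IC"] = _ellipse(shape, (c0 - 0.055 * s, c0 + 0.095 * s), (0.08 * s, 0.022 * s))
    half["I"] = _ellipse(shape, (c0 + 0.0 * s, c0 + 0.21 * s), (0.085 * s, 0.018 * s))

    # Cortical rim sectors: an annular band split into anterior / lateral /
    # posterior row thirds.  M1–M3 on the basal level, M4–M6 cortical.
    band_bg = (rho > 0.72) & (rho <= 0.98) & (np.abs(cc - c0) > 0.02 * s)
    band_ct = (rho > 0.60) & (rho <= 0.98) & (np.abs(cc - c0) > 0.02 * s)
    anterior = rr < c0 - 0.13 * s
    lateral = np.abs(rr - c0) <= 0.13 * s
    posterior = rr > c0 + 0.13 * s
    half["M1"] = band_bg & anterior
    half["M2"] = band_bg & lateral
    half["M3"] = band_bg & posterior
    half["M4"] = band_ct & anterior
    half["M5"] = band_ct & lateral
    half["M6"] = band_ct & posterior

    # Precedence for overlapping structures within each slice level, then
    # clip to the brain, the half-plane, and away from the ventricles.
    order = ("C", "L", "IC", "I", "M1", "M2", "M3", "M4", "M5", "M6")
    taken = {lvl: np.zeros(shape, dtype=bool) for lvl in LEVELS}
    vent_of = {"basal_ganglia": vent, "cortical": vent_cortical}
    resolved: dict[str, np.ndarray] = {}
    for region in order:
        lvl = LEVEL_OF_REGION[region]
        m = half[region] & brain & right_half & ~vent_of[lvl] & ~taken[lvl]
        resolved[region] = m
        taken[lvl] |= m

    labels = {lvl: np.zeros(shape, dtype=np.int16) for lvl in LEVELS}
    table: dict[int, tuple[str, str]] = {}
    for idx, region in enumerate(REGIONS):
        level = LEVEL_OF_REGION[region]
        m = resolved[region]
        if not m.any():
            raise SizingError(
                f"image_size {s} too small to place region {region}"
            )
        lab_r = 2 * idx + 1
        lab_l = 2 * idx + 2
        labels[level][m] = lab_r
        labels[level][np.fliplr(m)] = lab_l
        table[lab_r] = (region, _ARRAY_RIGHT_SIDE)
        table[lab_l] = (region, _ARRAY_LEFT_SIDE)

    return RegionAtlas(
        labels=labels,
        table=table,
        brain={"basal_ganglia": brain & ~vent, "cortical": brain & ~vent_cortical},
        spacing=config.spacing,
    )


@dataclass
class LesionSpec:
    """A simulated ischemic lesion: a positive HU decrement in one region."""

    region: str
    side: str
    decrement_hu: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown ASPECTS region {self.region!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if not self.decrement_hu > 0:
            raise ValidationError("decrement_hu must be positive")


@dataclass
class CohortRecord:
    """One synthetic patient: two HU slices plus lesion ground truth."""

    patient_id: str
    category: str  # acute | hemorrhagic | subacute | chronic
    laterality: str  # side of the clinical deficit
    slices: dict[str, HUImage]
    truth: dict[str, bool]  # per-region infarct flag on the laterality side
    lesions: list[LesionSpec] = field(default_factory=list)


def _base_image(atlas: RegionAtlas, config: PhantomConfig, level: str) -> np.ndarray:
    s = config.image_size
    c0 = (s - 1) / 2.0
    rho = _rho((s, s), c0, 0.42 * s, 0.36 * s)
    img = np.full((s, s), AIR_HU)
    brain_full = rho <= 1.0
    img[brain_full] = config.region_baseline("parenchyma")
    lab = atlas.labels[level]
    for label, (region, _side) in atlas.table.items():
        m = lab == label
        if m.any():
            img[m] = config.region_baseline(region)
    img[brain_full & ~atlas.brain[level]] = config.csf_hu  # ventricles
    img[(rho > 1.0) & (rho <= 1.12)] = config.skull_hu
    return img


def atlas_reference_images(
    atlas: RegionAtlas, config: PhantomConfig
) -> dict[str, HUImage]:
    """Noise- and lesion-free HU images of the atlas, one per level.

    These serve as the moving images in atlas-to-patient registration.
    """
    return {
        level: HUImage(_base_image(atlas, config, level),
                       spacing=config.spacing, level=level)
        for level in LEVELS
    }


def synth_patient(
    atlas: RegionAtlas,
    config: PhantomConfig,
    lesions: Sequence[LesionSpec],
    seed: int,
    *,
    patient_id: str = "p000",
    category: str = "acute",
    laterality: str | None = None,
) -> CohortRecord:
    """Simulate one patient: baseline phantom, lesion decrements, noise.

    Each lesion subtracts ``decrement_hu`` uniformly inside its region mask;
    i.i.d. Gaussian noise of SD ``config.noise_sd`` is then added to the
    whole image.  Identical (atlas, config, lesions, seed) give identical
    pixel arrays.
    """
    for lesion in lesions:
        if lesion.region not in REGIONS:
            raise ValidationError(f"unknown region in LesionSpec: {lesion.region!r}")
    if laterality is None:
        laterality = lesions[0].side if lesions else "right"

    rng = np.random.default_rng(seed)
    slices: dict[str, HUImage] = {}
    for level in LEVELS:
        img = _base_image(atlas, config, level)
        for lesion in lesions:
            if LEVEL_OF_REGION[lesion.region] == level:
                img[atlas.mask(lesion.region, lesion.side)] -= lesion.decrement_hu
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        slices[level] = HUImage(img, spacing=config.spacing, level=level)

    truth = {r: False for r in REGIONS}
    for lesion in lesions:
        if lesion.side == laterality:
            truth[lesion.region] = True
    return CohortRecord(
        patient_id=patient_id,
        category=category,
        laterality=laterality,
        slices=slices,
        truth=truth,
        lesions=list(lesions),
    )


def synth_cohort(
    n: int,
    prevalence: float | Mapping[str, float],
    decrement_range: tuple[float, float],
    config: PhantomConfig,
    seed: int,
    *,
    atlas: RegionAtlas | None = None,
    decrement_relative: bool = False,
) -> list[CohortRecord]:
    """Simulate ``n`` acute patients with random lesions.

    Lesions are drawn independently per region with the given prevalence;
    decrements are uniform in ``decrement_range`` (HU, or fraction of the
    region baseline when ``decrement_relative``); laterality is a fair coin.
    Fully reproducible for a fixed seed.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    if isinstance(prevalence, Mapping):
        prev = {r: float(prevalence.get(r, 0.0)) for r in REGIONS}
    else:
        prev = {r: float(prevalence) for r in REGIONS}
    for r, p in prev.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"prevalence for {r} must be in [0, 1], got {p}")
    lo, hi = decrement_range
    if not (lo > 0 and hi >= lo):
        raise ValidationError("decrement_range must be a positive, nonempty interval")

    if atlas is None:
        atlas = build_atlas(config)
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for i in range(n):
        laterality = "left" if rng.random() < 0.5 else "right"
        lesions = []
        for region in REGIONS:
            if rng.random() < prev[region]:
                dec = rng.uniform(lo, hi)
                if decrement_relative:
                    dec *= config.region_baseline(region)
                lesions.append(LesionSpec(region, laterality, dec))
        patient_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            synth_patient(
                atlas, config, lesions, patient_seed,
                patient_id=f"p{i:04d}", laterality=laterality,
            )
        )
    return records


def apply_exclusions(manifest: Iterable[CohortRecord]) -> list[CohortRecord]:
    """Keep only acute-stroke records, preserving order.

    Hemorrhagic, subacute and chronic strokes are excluded from calibration
    and evaluation: hemorrhage is a contraindication handled upstream, and
    subacute/chronic hypodensities fall outside the acute decision problem.
    """
    kept = []
    for rec in manifest:
        if not getattr(rec, "category", None):
            raise ValidationError(
                f"record {getattr(rec, 'patient_id', '?')} has no category"
            )
        if rec.category == "acute":
            kept.append(rec)
    return kept
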