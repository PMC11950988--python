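"""End-to-end orchestration: preprocess -> segment -> detect -> score.

`run_patient` scores one patient (two standardized slices) with one or both
detectors; `run_score` drives a batch from a :class:`RunConfig`, continuing
past per-patient failures and logging them.  Reports are written with
sorted keys and no timestamps, so a rerun under the same seed and
configuration produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import __version__
from .calibrate import default_params, params_from_yaml
from .detect import DetectionParams, detect_region, region_stats
from .exceptions import AspectscoreError, ValidationError
from .phantom import (
    LEVELS,
    LEVEL_OF_REGION,
    REGIONS,
    CohortRecord,
    PhantomConfig,
    RegionAtlas,
    atlas_reference_images,
    build_atlas,
)
from .preprocess import HUImage, crop_and_pad, median_denoise, strip_skull
from .score import AspectsReport, compute_aspects, report_to_dict
from .segment import (
    RegionMaskSet,
    dilate_internal,
    refine_nonrigid,
    register_rigid,
    transfer_masks,
)

logger = logging.getLogger("aspectscore")

MethodName = Literal["DDET", "RELDIF", "both"]


@dataclass
class RunConfig:
    """Configuration of one scoring run."""

    method: MethodName = "both"
    laterality: str | None = None  # required unless exploratory mode
    params: DetectionParams | str | Path | None = None
    standard_size: int = 256
    skull_threshold_hu: float = 300.0
    denoise: bool = False
    dilation_radius: int = 1
    nonrigid: bool = False
    exploratory: bool = False  # score both hemispheres, no laterality needed
    out_dir: str | Path | None = None
    seed: int = 0
    atlas_config: PhantomConfig | None = None

    def resolve_params(self) -> DetectionParams:
        if self.params is None:
            return default_params()
        if isinstance(self.params, DetectionParams):
            return self.params
        return params_from_yaml(self.params)

    def methods(self) -> list[str]:
        if self.method == "both":
            return ["DDET", "RELDIF"]
        if self.method in ("DDET", "RELDIF"):
            return [self.method]
        raise ValidationError(f"method must be DDET, RELDIF or both")


@dataclass
class StandardizedAtlas:
    """Atlas co-standardized with its reference images."""

    atlas: RegionAtlas
    images: dict[str, HUImage]
    labels: dict[str, np.ndarray]
    brain: dict[str, np.ndarray]


def standardize_atlas(config: RunConfig) -> StandardizedAtlas:
    """Build the synthetic atlas and standardize image + labels jointly."""
    pcfg = config.atlas_config or PhantomConfig(
        image_size=config.standard_size, noise_sd=0.0
    )
    atlas = build_atlas(pcfg)
    refs = atlas_reference_images(atlas, pcfg)
    images: dict[str, HUImage] = {}
    labels: dict[str, np.ndarray] = {}
    brain: dict[str, np.ndarray] = {}
    for level in LEVELS:
        mask = strip_skull(refs[level], config.skull_threshold_hu)
        std_img, plan = crop_and_pad(refs[level], mask, config.standard_size)
        images[level] = std_img
        labels[level] = plan.apply(atlas.labels[level], order=0).astype(np.int16)
        brain[level] = plan.apply(mask.mask.astype(np.int16), order=0).astype(bool)
    return StandardizedAtlas(atlas, images, labels, brain)


def standardize_patient(
    slices: dict[str, HUImage], config: RunConfig
) -> dict[str, HUImage]:
    out = {}
    for level, img in slices.items():
        if config.denoise:
            img = median_denoise(img)
        mask = strip_skull(img, config.skull_threshold_hu)
        std, _plan = crop_and_pad(img, mask, config.standard_size)
        out[level] = std
    return out


def segment_patient(
    std_slices: dict[str, HUImage],
    std_atlas: StandardizedAtlas,
    config: RunConfig,
) -> dict[str, RegionMaskSet]:
    """Register the standardized atlas to each slice and transfer masks."""
    masksets = {}
    for level, patient_img in std_slices.items():
        transform = register_rigid(std_atlas.images[level], patient_img)
        disp = None
        if config.nonrigid:
            disp = refine_nonrigid(std_atlas.images[level], patient_img, transform)
        maskset = transfer_masks(
            std_atlas.atlas, transform, disp, level=level,
            reference_shape=patient_img.shape,
            label_map=std_atlas.labels[level], table=std_atlas.atlas.table,
        )
        brain = patient_img.pixels != 0.0  # standardized background is 0 HU
        maskset = dilate_internal(maskset, config.dilation_radius, brain_mask=brain)
        masksets[level] = maskset
    return masksets


def score_patient(
    std_slices: dict[str, HUImage],
    masksets: dict[str, RegionMaskSet],
    params: DetectionParams,
    method: str,
    laterality: str,
    patient_id: str = "",
) -> AspectsReport:
    """Detect per region on the affected hemisphere and aggregate."""
    calls = []
    for region in REGIONS:
        level = LEVEL_OF_REGION[region]
        img = std_slices[level]
        ms = masksets[level]
        left = region_stats(img, ms.mask(region, "left"), params.hu_window)
        right = region_stats(img, ms.mask(region, "right"), params.hu_window)
        calls.append(
            detect_region(method, region, left, right, params, laterality)
        )
    return compute_aspects(calls, patient_id=patient_id, method=method)


def run_patient(
    record: CohortRecord,
    std_atlas: StandardizedAtlas,
    config: RunConfig,
    params: DetectionParams | None = None,
) -> list[AspectsReport]:
    params = params or config.resolve_params()
    laterality = config.laterality or record.laterality
    if laterality is None and not config.exploratory:
        raise ValidationError(
            f"{record.patient_id}: laterality required (or enable exploratory mode)"
        )
    std = standardize_patient(record.slices, config)
    masksets = segment_patient(std, std_atlas, config)
    return [
        score_patient(std, masksets, params, m, laterality, record.patient_id)
        for m in config.methods()
    ]


def run_score(
    config: RunConfig, records: Sequence[CohortRecord]
) -> list[AspectsReport]:
    """Score a batch of patients; per-patient failures are logged and skipped.

    When ``config.out_dir`` is set, writes one JSON report per patient and
    method plus a cohort CSV, all byte-stable under a fixed seed/config.
    """
    std_atlas = standardize_atlas(config)
    params = config.resolve_params()
    reports: list[AspectsReport] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            reports.extend(run_patient(rec, std_atlas, config, params))
        except AspectscoreError as exc:
            stage = type(exc).__name__
            logger.error("patient %s failed at %s: %s", rec.patient_id, stage, exc)
            failures.append((rec.patient_id, f"{stage}: {exc}"))

    if config.out_dir is not None:
        _write_reports(reports, failures, params, config)
    return reports


def _provenance(params: DetectionParams, config: RunConfig) -> dict:
    return {
        "version": __version__,
        "seed": config.seed,
        "method": config.method,
        "alpha": params.alpha,
        "hu_window": list(params.hu_window),
        "reldif_threshold": dict(sorted(params.reldif_threshold.items())),
        "ddet_margin": dict(sorted(params.ddet_margin.items())),
    }


def _write_reports(reports, failures, params, config) -> None:
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(params, config)
    for rep in reports:
        payload = {"provenance": prov, **report_to_dict(rep)}
        path = out / f"{rep.patient_id}_{rep.method}.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    rows = [
        {
            "patient_id": r.patient_id,
            "method": r.method,
            "score": r.score,
            "dichotomized": r.dichotomized,
            "n_indeterminate": len(r.indeterminate_regions),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(out / "scores.csv", index=False)
    if failures:
        with open(out / "failures.json", "w") as fh:
            json.dump(
                [{"patient_id": p, "error": e} for p, e in failures],
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
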