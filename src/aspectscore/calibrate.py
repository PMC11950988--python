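"""Per-region parameter sweeps for the RELDIF and DDET detectors.

For each ASPECTS region the detector has one free parameter — the RELDIF
threshold Delta (percent, swept over 0.05–50 in steps of 0.05) or the DDET
equivalence margin delta_m (HU, swept over 0.05–16 in steps of 0.05).  Each
grid value is applied to every patient of a calibration cohort with known
region-level truth, giving an operating point (sensitivity, specificity).
The AUC of a single binary operating point is the trapezoid through (0,0),
(1 - spec, sens), (1,1), i.e. (sens + spec) / 2 — so maximizing AUC is
maximizing the Youden index.  The chosen parameter is the maximum-AUC grid
value among those with specificity at or above the floor (0.88); among
ties, the smallest grid value wins (highest sensitivity — the clinically
conservative choice).  If no grid value satisfies the floor, the
maximum-specificity value is returned with a warning flag.

Grids are generated from integer indices (start + k * step) so that float
accumulation can never change the grid length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .detect import DetectionParams, RegionStats, region_stats
from .exceptions import CalibrationError, ValidationError
from .phantom import LEVEL_OF_REGION, REGIONS, CohortRecord, RegionAtlas

Method = Literal["RELDIF", "DDET"]


@dataclass
class SweepGrid:
    """Inclusive arithmetic parameter grid, built from integer indices."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not self.start > 0:
            raise ValidationError("grid start must be > 0")
        if not self.stop > self.start:
            raise ValidationError("grid stop must exceed start")
        if not self.step > 0:
            raise ValidationError("grid step must be > 0")

    @property
    def values(self) -> np.ndarray:
        k = int(round((self.stop - self.start) / self.step))
        return self.start + self.step * np.arange(k + 1)

    def __len__(self) -> int:
        return self.values.size


#: Published sweep ranges: RELDIF 0.05–50 % and DDET 0.05–16 HU, step 0.05.
RELDIF_GRID = SweepGrid(0.05, 50.0, 0.05)
DDET_GRID = SweepGrid(0.05, 16.0, 0.05)


@dataclass
class CalibrationResult:
    region: str
    method: str
    grid: np.ndarray
    auc: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    chosen_value: float
    chosen_metrics: dict[str, float]
    floor_met: bool = True

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "region": self.region,
                "method": self.method,
                "value": self.grid,
                "auc": self.auc,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
            }
        )


@dataclass
class StatPair:
    """Precomputed per-patient inputs for a single region's sweep."""

    affected: RegionStats
    contra: RegionStats
    truth: bool


def cohort_stat_pairs(
    cohort: Sequence[CohortRecord],
    atlas: RegionAtlas,
    region: str,
    window: tuple[float, float] = (10.0, 55.0),
) -> list[StatPair]:
    """Affected/contralateral region statistics for every cohort record.

    Uses the atlas ground-truth masks directly, isolating detector
    calibration from segmentation error.
    """
    level = LEVEL_OF_REGION[region]
    pairs = []
    for rec in cohort:
        img = rec.slices[level]
        affected_side = rec.laterality
        contra_side = "right" if affected_side == "left" else "left"
        aff = region_stats(img, atlas.mask(region, affected_side), window)
        con = region_stats(img, atlas.mask(region, contra_side), window)
        pairs.append(StatPair(aff, con, bool(rec.truth[region])))
    return pairs


def _reldif_scores(pairs: Sequence[StatPair]) -> np.ndarray:
    deltas = np.empty(len(pairs))
    for i, p in enumerate(pairs):
        if not (p.affected.valid and p.contra.valid):
            deltas[i] = np.nan
        else:
            deltas[i] = max(
                0.0, 100.0 * (p.contra.mean - p.affected.mean) / p.contra.mean
            )
    return deltas


def _ddet_components(pairs: Sequence[StatPair], alpha: float):
    """(|I-J|, SE_diff, superiority verdict) per patient; margin-independent."""
    absdiff = np.empty(len(pairs))
    se_diff = np.empty(len(pairs))
    sup = np.zeros(len(pairs), dtype=bool)
    valid = np.ones(len(pairs), dtype=bool)
    for i, p in enumerate(pairs):
        if not (p.affected.valid and p.contra.valid):
            valid[i] = False
            continue
        d = p.affected.mean - p.contra.mean
        absdiff[i] = abs(d)
        se_diff[i] = np.hypot(p.affected.se, p.contra.se)
        hypo = p.contra.mean - p.affected.mean
        if se_diff[i] == 0.0:
            sup[i] = hypo > 0
        else:
            sup[i] = norm.sf(hypo / se_diff[i]) < alpha
    return absdiff, se_diff, sup, valid


def _metrics(calls: np.ndarray, truth: np.ndarray):
    tp = np.sum(calls & truth, axis=-1)
    fp = np.sum(calls & ~truth, axis=-1)
    fn = np.sum(~calls & truth, axis=-1)
    tn = np.sum(~calls & ~truth, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        acc = (tp + tn) / (tp + fp + tn + fn)
    return sens, spec, acc


def sweep(
    cohort_or_pairs,
    region: str,
    method: Method,
    grid: SweepGrid | None = None,
    *,
    atlas: RegionAtlas | None = None,
    alpha: float = 0.05,
    specificity_floor: float = 0.88,
    window: tuple[float, float] = (10.0, 55.0),
) -> CalibrationResult:
    """Grid sweep of one region's detector parameter on a labeled cohort.

    Accepts either a list of :class:`CohortRecord` (with ``atlas``) or a
    precomputed list of :class:`StatPair`.  Deterministic: depends only on
    the multiset of (stats, truth) pairs, never on cohort order.
    """
    if region not in REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    if method not in ("RELDIF", "DDET"):
        raise ValidationError(f"unknown method {method!r}")
    if grid is None:
        grid = RELDIF_GRID if method == "RELDIF" else DDET_GRID

    if cohort_or_pairs and isinstance(cohort_or_pairs[0], StatPair):
        pairs = list(cohort_or_pairs)
    else:
        if atlas is None:
            raise ValidationError("atlas required when passing cohort records")
        pairs = cohort_stat_pairs(cohort_or_pairs, atlas, region, window)

    truth = np.array([p.truth for p in pairs], dtype=bool)
    if truth.all() or not truth.any():
        raise CalibrationError(
            f"region {region}: calibration needs at least one positive and one "
            "negative instance"
        )

    values = grid.values
    if method == "RELDIF":
        deltas = _reldif_scores(pairs)
        ok = ~np.isnan(deltas)
        # indeterminate records count as negative calls at every threshold
        calls = np.zeros((values.size, len(pairs)), dtype=bool)
        calls[:, ok] = deltas[ok][None, :] >= values[:, None]
    else:
        absdiff, se_diff, sup, ok = _ddet_components(pairs, alpha)
        calls = np.zeros((values.size, len(pairs)), dtype=bool)
        idx = np.where(ok)[0]
        for i in idx:
            if se_diff[i] == 0.0:
                # deterministic limit: equivalence iff |I-J| < margin
                nonequiv = absdiff[i] >= values
            else:
                z = (absdiff[i] - values) / se_diff[i]
                nonequiv = norm.cdf(z) >= alpha
            calls[:, i] = nonequiv & sup[i]

    sens, spec, acc = _metrics(calls, truth[None, :])
    auc = (sens + spec) / 2.0

    feasible = spec >= specificity_floor
    if feasible.any():
        best_auc = auc[feasible].max()
        cand = np.where(feasible & np.isclose(auc, best_auc, atol=1e-12))[0]
        chosen_idx = int(cand.min())  # smallest grid value among AUC ties
        floor_met = True
    else:
        warnings.warn(
            f"region {region} ({method}): no grid value reaches specificity "
            f">= {specificity_floor}; falling back to the maximum-specificity value",
            stacklevel=2,
        )
        chosen_idx = int(np.argmax(spec))
        floor_met = False

    return CalibrationResult(
        region=region,
        method=method,
        grid=values,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        chosen_value=float(values[chosen_idx]),
        chosen_metrics={
            "auc": float(auc[chosen_idx]),
            "sensitivity": float(sens[chosen_idx]),
            "specificity": float(spec[chosen_idx]),
            "accuracy": float(acc[chosen_idx]),
        },
        floor_met=floor_met,
    )


def calibrate_cohort(
    cohort: Sequence[CohortRecord],
    atlas: RegionAtlas,
    method: Method,
    *,
    grid: SweepGrid | None = None,
    alpha: float = 0.05,
    specificity_floor: float = 0.88,
    window: tuple[float, float] = (10.0, 55.0),
) -> tuple[DetectionParams, dict[str, CalibrationResult]]:
    """Sweep every region; return DetectionParams carrying the chosen values.

    Regions whose truth is single-class keep their shipped default value.
    """
    params = default_params()
    params.alpha = alpha
    params.specificity_floor = specificity_floor
    params.hu_window = window
    results: dict[str, CalibrationResult] = {}
    for region in REGIONS:
        try:
            res = sweep(
                cohort, region, method, grid,
                atlas=atlas, alpha=alpha,
                specificity_floor=specificity_floor, window=window,
            )
        except CalibrationError:
            continue
        results[region] = res
        if method == "RELDIF":
            params.reldif_threshold[region] = res.chosen_value
        else:
            params.ddet_margin[region] = res.chosen_value
    return params, results


def default_params() -> DetectionParams:
    """Shipped per-region defaults (clinically calibrated reference values)."""
    return DetectionParams()


def params_to_yaml(params: DetectionParams, path) -> None:
    import yaml

    payload = {
        "alpha": params.alpha,
        "hu_window": list(params.hu_window),
        "specificity_floor": params.specificity_floor,
        "reldif_threshold": {k: float(v) for k, v in params.reldif_threshold.items()},
        "ddet_margin": {k: float(v) for k, v in params.ddet_margin.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def params_from_yaml(path) -> DetectionParams:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return DetectionParams(
        reldif_threshold=dict(payload["reldif_threshold"]),
        ddet_margin=dict(payload["ddet_margin"]),
        alpha=float(payload.get("alpha", 0.05)),
        hu_window=tuple(payload.get("hu_window", (10.0, 55.0))),
        specificity_floor=float(payload.get("specificity_floor", 0.88)),
    )
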