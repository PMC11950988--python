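"""Per-region ischemic-infarct detectors: RELDIF and DDET.

Early ischemia lowers CT attenuation, so an infarcted ASPECTS region is
hypodense relative to its mirror region in the contralateral hemisphere.
Both detectors compare windowed per-region HU statistics across hemispheres
on the clinically affected side (laterality is a required input, matching
how radiologists read these studies):

**RELDIF** (mean HU relative difference) computes the hypodensity of the
affected region as a percentage of the contralateral mean,

    delta_pct = 100 * (mean_contra - mean_affected) / mean_contra,

floored at zero when the affected side is denser, and calls an infarct when
``delta_pct >= threshold`` for a per-region calibrated threshold.

**DDET** (density distribution equivalence test) is a Z-test cascade on the
two region means I and J with standard errors from the pixel samples.
First an equivalence test with margin ``delta_m`` (HU):

    H0: |I - J| - delta_m = 0   vs.   H1: |I - J| - delta_m < 0,

with z = (|I - J| - delta_m) / SE_diff, SE_diff = sqrt(SE_I^2 + SE_J^2) and
p = Phi(z).  If equivalence is claimed (p < alpha) the region is negative.
Otherwise a one-sided superiority test decides which side is denser; an
infarct is called only when the affected side's mean is significantly
LOWER.  Non-significant evidence resolves to negative (no-call): the
conservative clinical default.

SE assumes independent pixels — a documented approximation, since CT noise
is spatially correlated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.stats import norm

from .exceptions import ValidationError
from .preprocess import HUImage, HU_WINDOW_LO, HU_WINDOW_HI

#: Per-region RELDIF thresholds Delta (%) shipped as defaults: the values
#: calibrated on a 65-patient set by maximizing per-region AUC subject to a
#: specificity floor of 0.88.
DEFAULT_RELDIF_THRESHOLD: dict[str, float] = {
    "C": 9.1, "I": 4.0, "IC": 4.85, "L": 4.9,
    "M1": 1.55, "M2": 1.3, "M3": 5.05, "M4": 2.3, "M5": 1.8, "M6": 3.9,
}

#: Per-region DDET equivalence margins delta_m (HU), same provenance.
DEFAULT_DDET_MARGIN: dict[str, float] = {
    "C": 3.9, "I": 2.05, "IC": 1.75, "L": 1.95,
    "M1": 0.75, "M2": 0.7, "M3": 0.95, "M4": 0.25, "M5": 0.8, "M6": 1.65,
}


@dataclass
class RegionStats:
    """Mean/SD/SE/count of windowed HU values for one region on one side.

    ``n == 0`` marks an indeterminate region (every pixel excluded by the
    HU window); its moments are NaN and any detector consuming it returns
    an indeterminate, infarct-negative call rather than raising.
    """

    mean: float
    sd: float
    se: float
    n: int

    @property
    def valid(self) -> bool:
        return self.n >= 1


INDETERMINATE_STATS = RegionStats(float("nan"), float("nan"), float("nan"), 0)


def region_stats(
    img: HUImage,
    mask: np.ndarray,
    window: tuple[float, float] = (HU_WINDOW_LO, HU_WINDOW_HI),
) -> RegionStats:
    """HU statistics over the windowed pixels of a region mask.

    Sample SD (ddof=1; 0 for a single pixel) and SE = SD / sqrt(n).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValidationError("mask shape does not match image")
    if not mask.any():
        raise ValidationError("region mask is empty")
    vals = img.pixels[mask]
    lo, hi = window
    vals = vals[(vals >= lo) & (vals <= hi)]
    n = int(vals.size)
    if n == 0:
        return INDETERMINATE_STATS
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RegionStats(mean=mean, sd=sd, se=sd / math.sqrt(n), n=n)


@dataclass
class DetectionParams:
    """Calibrated detector parameters.

    ``reldif_threshold`` is the per-region hypodensity threshold Delta in
    percent; ``ddet_margin`` the per-region equivalence margin delta_m in
    HU.  ``alpha`` is the one-sided significance level shared by DDET's
    equivalence and superiority branches.
    """

    reldif_threshold: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELDIF_THRESHOLD)
    )
    ddet_margin: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DDET_MARGIN)
    )
    alpha: float = 0.05
    hu_window: tuple[float, float] = (HU_WINDOW_LO, HU_WINDOW_HI)
    specificity_floor: float = 0.88

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        for name, d in self.reldif_threshold.items():
            if not d > 0:
                raise ValidationError(f"RELDIF threshold for {name} must be > 0")
        for name, d in self.ddet_margin.items():
            if not d > 0:
                raise ValidationError(f"DDET margin for {name} must be > 0")


@dataclass
class DetectionCall:
    """One detector's verdict for one region on the affected hemisphere."""

    region: str
    affected_side: str
    method: str  # "RELDIF" | "DDET"
    infarct: bool
    delta_pct: float | None = None
    z_equiv: float | None = None
    p_equiv: float | None = None
    z_sup: float | None = None
    p_sup: float | None = None
    indeterminate: bool = False


def reldif_call(
    affected: RegionStats,
    contra: RegionStats,
    threshold: float,
    *,
    region: str = "",
    affected_side: str = "",
) -> DetectionCall:
    """RELDIF decision: relative hypodensity vs. the contralateral mean."""
    if not (affected.valid and contra.valid):
        return DetectionCall(region, affected_side, "RELDIF",
                             infarct=False, indeterminate=True)
    if not contra.mean > 0:
        raise ValidationError("contralateral mean must be positive for RELDIF")
    delta_pct = max(0.0, 100.0 * (contra.mean - affected.mean) / contra.mean)
    return DetectionCall(
        region, affected_side, "RELDIF",
        infarct=delta_pct >= threshold, delta_pct=delta_pct,
    )


def ddet_call(
    left: RegionStats,
    right: RegionStats,
    margin: float,
    alpha: float,
    affected_side: str,
    *,
    region: str = "",
) -> DetectionCall:
    """DDET decision: equivalence test, then superiority on non-equivalence.

    Degenerate SE handling: with SE_diff = 0 the tests are deterministic —
    |I - J| < margin claims equivalence, |I - J| > margin is non-equivalent
    with a sure-thing superiority verdict, and |I - J| exactly equal to the
    margin follows the non-equivalence path (tie rule).
    """
    if affected_side not in ("left", "right"):
        raise ValidationError("affected_side must be 'left' or 'right'")
    if not (left.valid and right.valid):
        return DetectionCall(region, affected_side, "DDET",
                             infarct=False, indeterminate=True)
    if not margin > 0:
        raise ValidationError("DDET margin must be positive")

    diff = left.mean - right.mean  # I - J with I = left
    se_diff = math.hypot(left.se, right.se)
    absdiff = abs(diff)

    if se_diff == 0.0:
        z_equiv = -math.inf if absdiff < margin else (
            0.0 if absdiff == margin else math.inf
        )
    else:
        z_equiv = (absdiff - margin) / se_diff
    p_equiv = float(norm.cdf(z_equiv))

    if p_equiv < alpha:  # equivalence claimed: no infarct
        return DetectionCall(region, affected_side, "DDET", infarct=False,
                             z_equiv=z_equiv, p_equiv=p_equiv)

    affected = left if affected_side == "left" else right
    contra = right if affected_side == "left" else left
    hypo = contra.mean - affected.mean  # > 0 when affected side is hypodense
    if se_diff == 0.0:
        z_sup = math.inf if hypo > 0 else (-math.inf if hypo < 0 else 0.0)
    else:
        z_sup = hypo / se_diff
    p_sup = float(norm.sf(z_sup))
    return DetectionCall(
        region, affected_side, "DDET",
        infarct=p_sup < alpha,
        z_equiv=z_equiv, p_equiv=p_equiv, z_sup=z_sup, p_sup=p_sup,
    )


def detect_region(
    method: str,
    region: str,
    left: RegionStats,
    right: RegionStats,
    params: DetectionParams,
    affected_side: str,
) -> DetectionCall:
    """Dispatch one region through the named detector."""
    if method == "RELDIF":
        affected = left if affected_side == "left" else right
        contra = right if affected_side == "left" else left
        return reldif_call(
            affected, contra, params.reldif_threshold[region],
            region=region, affected_side=affected_side,
        )
    if method == "DDET":
        return ddet_call(
            left, right, params.ddet_margin[region], params.alpha,
            affected_side, region=region,
        )
    raise ValidationError(f"unknown detection method {method!r}")


def calls_to_frame(calls, patient_id: str):
    """Flatten detection calls into a pandas DataFrame row set."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "patient_id": patient_id,
                "region": c.region,
                "side": c.affected_side,
                "method": c.method,
                "infarct": bool(c.infarct),
                "delta_pct": c.delta_pct,
                "p_equiv": c.p_equiv,
                "p_sup": c.p_sup,
                "indeterminate": bool(c.indeterminate),
            }
        )
    return pd.DataFrame(rows)
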