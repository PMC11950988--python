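"""ASPECTS aggregation.

The ASPECTS starts at 10 and loses one point per MCA-territory region with
early ischemic change, so ``score = 10 - (# infarct-positive regions)``.
The dichotomized flag marks ``score < 6``, the imaging contraindication for
intravenous thrombolysis.  Indeterminate regions (all pixels excluded by
the HU window) score as negative but are counted explicitly in the report —
a region is never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .detect import DetectionCall
from .exceptions import ValidationError
from .phantom import REGIONS

DICHOTOMY_CUTOFF = 6  # ASPECTS < 6


@dataclass
class AspectsReport:
    patient_id: str
    method: str
    calls: list[DetectionCall]
    score: int
    dichotomized: bool
    indeterminate_regions: list[str] = field(default_factory=list)


def compute_aspects(
    calls: Sequence[DetectionCall],
    *,
    patient_id: str = "",
    method: str = "",
) -> AspectsReport:
    """Aggregate exactly one call per region into the 0–10 score."""
    regions = [c.region for c in calls]
    if sorted(regions) != sorted(REGIONS):
        missing = set(REGIONS) - set(regions)
        dupes = {r for r in regions if regions.count(r) > 1}
        raise ValidationError(
            f"need exactly one call per region; missing={sorted(missing)}, "
            f"duplicated={sorted(dupes)}"
        )
    if not method:
        methods = {c.method for c in calls}
        method = methods.pop() if len(methods) == 1 else "mixed"
    positives = sum(1 for c in calls if c.infarct)
    score = 10 - positives
    return AspectsReport(
        patient_id=patient_id,
        method=method,
        calls=list(calls),
        score=score,
        dichotomized=score < DICHOTOMY_CUTOFF,
        indeterminate_regions=[c.region for c in calls if c.indeterminate],
    )


def report_to_dict(report: AspectsReport) -> dict:
    """JSON-serializable form of a report (deterministic key order)."""
    return {
        "patient_id": report.patient_id,
        "method": report.method,
        "score": report.score,
        "dichotomized": report.dichotomized,
        "n_indeterminate": len(report.indeterminate_regions),
        "indeterminate_regions": sorted(report.indeterminate_regions),
        "calls": [
            {
                "region": c.region,
                "side": c.affected_side,
                "infarct": bool(c.infarct),
                "delta_pct": c.delta_pct,
                "p_equiv": c.p_equiv,
                "p_sup": c.p_sup,
                "indeterminate": bool(c.indeterminate),
            }
            for c in sorted(report.calls, key=lambda c: REGIONS.index(c.region))
        ],
    }
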