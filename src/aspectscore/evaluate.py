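"""Diagnostic-performance and rater-comparison statistics.

Tools for comparing automated readers against a gold standard and against
each other: confusion-matrix proportions, nonparametric (Mann–Whitney)
ROC AUC with the Hanley–McNeil standard error, paired one-sided Z tests for
equivalence / noninferiority / superiority on rater differences, and
Cohen's kappa with Altman's qualitative bands.

The equivalence test follows the composite-null form on the absolute
difference: H0: |I - J| - delta = 0 vs. H1: |I - J| - delta < 0, with
z = (|mean diff| - delta) / SE and p = Phi(z).  The noninferiority test of
I against J at margin delta is H0: (I - J) = -delta vs. H1: (I - J) >
-delta, p = Phi((-mean_diff - delta) / SE).  Superiority is the delta = 0
one-sided test.  All tests are evaluated at a one-sided alpha of 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .exceptions import ValidationError


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class ConfusionMetrics:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def confusion_metrics(calls: Sequence[bool], truth: Sequence[bool]) -> ConfusionMetrics:
    """Sensitivity/specificity/accuracy; zero-denominator ratios are None."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValidationError("calls and truth have different lengths")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total > 0 else None
    return ConfusionMetrics(ConfusionCounts(tp, fp, tn, fn), sens, spec, acc)


@dataclass
class AUCResult:
    auc: float
    se: float
    n_pos: int
    n_neg: int


def auc_rank(scores: Sequence[float], labels: Sequence[bool]) -> AUCResult:
    """Nonparametric ROC AUC by midranks (Mann–Whitney), Hanley–McNeil SE."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels have different lengths")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks for ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return AUCResult(float(auc), math.sqrt(max(var, 0.0)), n_pos, n_neg)


@dataclass
class RaterComparison:
    """Paired Z tests of rater I minus rater J at margin delta."""

    mean_diff: float
    se_diff: float
    margin: float
    p_equivalence: float
    p_noninferiority: float
    p_superiority: float
    n: int
    boundary: bool = False  # zero variance with the mean on a test boundary


def paired_z_tests(
    diffs: Sequence[float], margin: float, alpha: float = 0.05
) -> RaterComparison:
    """Equivalence / noninferiority / superiority Z tests on paired diffs.

    ``diffs`` are per-unit paired differences I - J (per patient or per
    patient-region).  SE is the sample SD over sqrt(n).  Small p claims the
    corresponding alternative.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValidationError("paired tests need at least two differences")
    if not margin >= 0:
        raise ValidationError("margin must be nonnegative")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(d.size))

    boundary = False
    if se == 0.0:
        boundary = abs(abs(mean) - margin) < 1e-15 or mean == -margin
        z_eq = -math.inf if abs(mean) < margin else (
            0.0 if abs(mean) == margin else math.inf
        )
        z_ni = math.inf if mean > -margin else (0.0 if mean == -margin else -math.inf)
        z_sup = math.inf if mean > 0 else (0.0 if mean == 0 else -math.inf)
        p_eq = float(norm.cdf(z_eq))
        p_ni = float(norm.sf(z_ni))
        p_sup = float(norm.sf(z_sup))
    else:
        p_eq = float(norm.cdf((abs(mean) - margin) / se))
        # H1: mean > -margin; reject H0 for large (mean + margin) / se
        p_ni = float(norm.cdf((-mean - margin) / se))
        p_sup = float(norm.sf(mean / se))
    return RaterComparison(
        mean_diff=mean, se_diff=se, margin=margin,
        p_equivalence=p_eq, p_noninferiority=p_ni, p_superiority=p_sup,
        n=int(d.size), boundary=boundary,
    )


ALTMAN_BANDS = (
    (0.81, "very good"),
    (0.61, "good"),
    (0.41, "moderate"),
    (0.21, "fair"),
)


def altman_band(kappa: float) -> str:
    """Altman's qualitative agreement band; boundaries go to the higher band
    of the interval they close (0.8 is still 'good', 0.81 is 'very good')."""
    for lo, name in ALTMAN_BANDS:
        if kappa >= lo - 1e-12:
            return name
    return "poor"


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    band: str
    undefined: bool = False


def cohen_kappa(table: Sequence[Sequence[float]]) -> KappaResult:
    """Cohen's kappa from a square agreement table, with large-sample SE.

    kappa = (po - pe) / (1 - pe); SE = sqrt(po (1 - po) / (n (1 - pe)^2));
    95% CI = kappa +/- 1.96 SE.  Degenerate marginals (pe = 1) are flagged
    undefined rather than silently reported as some number.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValidationError("agreement table must be square")
    n = t.sum()
    if not n >= 1:
        raise ValidationError("agreement table must contain at least one count")
    po = float(np.trace(t) / n)
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum() / n**2)
    if abs(1.0 - pe) < 1e-12:
        return KappaResult(float("nan"), float("nan"),
                           (float("nan"), float("nan")), "undefined", True)
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(max(po * (1.0 - po), 0.0) / (n * (1.0 - pe) ** 2))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return KappaResult(float(kappa), float(se), ci, altman_band(kappa))


def plot_roc(scores, labels, ax=None):
    """Empirical ROC curve for an ordinal rater output (matplotlib)."""
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        calls = scores >= t
        m = confusion_metrics(calls, labels)
        tpr.append(m.sensitivity if m.sensitivity is not None else 0.0)
        fpr.append(1 - (m.specificity if m.specificity is not None else 1.0))
    tpr.append(1.0)
    fpr.append(1.0)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(fpr, tpr, marker="o")
    ax.plot([0, 1], [0, 1], ls="--", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    return ax
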