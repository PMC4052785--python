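"""Classifier evaluation: confusion metrics, ROC/AUC, survival, random null.

Conventions, pinned by reproducing the published validation tables:

* poor prognosis is the positive class; higher risk score = more positive;
* accuracy uses the sum of the four confusion cells as denominator;
* confidence intervals are Wald normal-approximation intervals, not clipped
  to [0, 1] (a proportion near 0 may print a negative lower bound) and not
  continuity-corrected;
* a metric with a zero denominator is undefined (None), never reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .datasets import GOOD, POOR
from .signature import Signature

__all__ = [
    "ConfusionCells",
    "MetricReport",
    "ROCResult",
    "KMResult",
    "HazardRatioResult",
    "NullDistribution",
    "confusion",
    "metrics",
    "wald_ci",
    "roc_auc",
    "km_logrank",
    "hazard_ratio",
    "random_signature_null",
    "round_half_away",
]

_LABELS = {POOR, GOOD}


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of the printed tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionCells:
    """2x2 confusion counts with poor prognosis as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion cells must be non-negative")
        if self.n_eff < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def n_eff(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """Sensitivity/specificity/accuracy/F with 95% Wald CIs per proportion.

    A metric whose denominator is zero is None, and so is its CI.
    """

    cells: ConfusionCells
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f_value: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    accuracy_ci: tuple[float, float] | None
    auc: float | None = None


def confusion(
    predictions: Sequence[str], truths: Sequence[str]
) -> ConfusionCells:
    """Count the 2x2 table of predicted vs true poor/good labels."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.size == 0:
        raise ValueError("cannot build a confusion matrix from no samples")
    if pred.shape != true.shape:
        raise ValueError("predictions and truths differ in length")
    bad = (set(pred) | set(true)) - _LABELS
    if bad:
        raise ValueError(f"labels must be 'poor'/'good', got {sorted(bad)}")
    return ConfusionCells(
        tp=int(((pred == POOR) & (true == POOR)).sum()),
        tn=int(((pred == GOOD) & (true == GOOD)).sum()),
        fp=int(((pred == POOR) & (true == GOOD)).sum()),
        fn=int(((pred == GOOD) & (true == POOR)).sum()),
    )


def wald_ci(
    p_hat: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval p_hat +/- z * sqrt(p_hat (1 - p_hat) / n), unclipped."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must lie in [0, 1]")
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p_hat * (1 - p_hat) / n)
    return (p_hat - half, p_hat + half)


def metrics(cells: ConfusionCells, level: float = 0.95) -> MetricReport:
    """Sensitivity, specificity, accuracy and F-value from confusion cells.

    F-value is the harmonic mean of precision and sensitivity (F1).  The
    accuracy denominator is the cell sum, which may be smaller than the
    nominal cohort size when some samples were unclassifiable.
    """

    def _prop(num: int, den: int):
        if den == 0:
            return None, None
        p = num / den
        return p, wald_ci(p, den, level)

    se, se_ci = _prop(cells.tp, cells.tp + cells.fn)
    sp, sp_ci = _prop(cells.tn, cells.tn + cells.fp)
    acc, acc_ci = _prop(cells.tp + cells.tn, cells.n_eff)
    f_den = 2 * cells.tp + cells.fp + cells.fn
    f = 2 * cells.tp / f_den if f_den else None
    return MetricReport(
        cells=cells,
        sensitivity=se,
        specificity=sp,
        accuracy=acc,
        f_value=f,
        sensitivity_ci=se_ci,
        specificity_ci=sp_ci,
        accuracy_ci=acc_ci,
    )


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> ROCResult:
    """ROC curve over all thresholds and trapezoidal AUC (ties count 1/2).

    Higher score = more poor-like; the AUC equals the probability that a
    random poor sample outscores a random good one.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    y = (lab == POOR).astype(int)
    if y.all() or not y.any():
        raise ValueError("ROC needs both prognosis classes")
    fpr, tpr, thr = roc_curve(y, s)
    return ROCResult(float(roc_auc_score(y, s)), fpr, tpr, thr)


@dataclass
class KMResult:
    """Kaplan-Meier curves per group plus the two-sided log-rank test."""

    curves: dict[str, pd.DataFrame]
    statistic: float | None
    p_value: float | None
    medians: dict[str, float] = field(default_factory=dict)


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str],
) -> KMResult:
    """Product-limit survival estimate per group and a log-rank comparison.

    With no events anywhere the curves are flat at 1 and the log-rank test
    is undefined (statistic and p reported as None).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    names = pd.unique(g)
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, got {len(names)}")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for name in names:
        mask = g == name
        if not mask.any():
            raise ValueError(f"group {name!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(name))
        curves[str(name)] = kmf.survival_function_
        medians[str(name)] = float(kmf.median_survival_time_)
    if not e.any():
        return KMResult(curves, None, None, medians)
    mask = g == names[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    return KMResult(curves, float(res.test_statistic), float(res.p_value), medians)


@dataclass
class HazardRatioResult:
    hr: float
    ci: tuple[float, float]
    coef: float
    se: float
    p_value: float


def hazard_ratio(
    times: Sequence[float],
    events: Sequence[bool],
    group_indicator: Sequence[int],
) -> HazardRatioResult:
    """Cox proportional-hazards fit of a binary group indicator.

    HR = exp(coef) with a 95% Wald interval; the indicator codes the
    high-risk group as 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.asarray(group_indicator, dtype=float)
    if not e.any():
        raise ValueError("cannot fit a hazard model with no events")
    if len(np.unique(x)) < 2:
        raise ValueError("group indicator is constant")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "group": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    z = norm.ppf(0.975)
    return HazardRatioResult(
        hr=float(np.exp(coef)),
        ci=(float(np.exp(coef - z * se)), float(np.exp(coef + z * se))),
        coef=coef,
        se=se,
        p_value=float(cph.summary.loc["group", "p"]),
    )


@dataclass
class NullDistribution:
    """Evaluator values of k random gene signatures of a fixed size."""

    values: np.ndarray
    signatures: list[Signature]
    signature_size: int
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))


def random_signature_null(
    gene_ids: Sequence[str],
    signature_size: int,
    evaluator: Callable[[Signature], float],
    k: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Evaluate k random same-size gene signatures (the RAND benchmark).

    Signatures are drawn uniformly without replacement from ``gene_ids``
    with a :class:`numpy.random.default_rng` seeded by ``seed``; the
    supplied evaluator maps a signature to a scalar (e.g. held-out accuracy
    or a log-rank p value), yielding the null distribution a real signature
    must beat.
    """
    genes = np.asarray(gene_ids)
    if signature_size > genes.size:
        raise ValueError(
            f"signature_size {signature_size} exceeds gene count {genes.size}"
        )
    rng = np.random.default_rng(seed)
    signatures = [
        Signature(tuple(rng.choice(genes, size=signature_size, replace=False)),
                  name=f"rand{i:04d}")
        for i in range(k)
    ]
    values = np.asarray([evaluator(s) for s in signatures], dtype=float)
    return NullDistribution(values, signatures, signature_size, seed)
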