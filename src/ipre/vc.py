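"""Virtual-chromosome (VC) scoring of genes.

Each gene receives a score combining two components computed on a labelled,
normalized cohort:

* the correlation factor ``alpha`` — a dichotomized concordance between
  outcome and expression.  A sample agrees with the "low expression in early
  progressors" pattern (cc = +1) when TTP <= 5 years and e < 0.5, or
  TTP > 5 years and e >= 0.5; it disagrees (cc = -1) otherwise.  Then
  alpha = (p - q) / N with p, q the counts of agreeing and disagreeing
  samples.
* the penalized factor ``beta = 1 - |mean(poor) - mean(good)|`` — close to 1
  when the group means are similar, close to 0 when they differ strongly.

The score is the weighted combination ``VC = tau1 * alpha + tau2 * beta``
with published weights tau1 = 1, tau2 = -1.0011, so genes that discriminate
the groups both at the dichotomized (micro) and mean-expression (macro)
level rise to the top.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GOOD, POOR, LabeledCohort

__all__ = [
    "TAU1_DEFAULT",
    "TAU2_DEFAULT",
    "VCResult",
    "correlation_coefficient",
    "correlation_factor",
    "penalized_factor",
    "vc_score",
    "score_all",
]

TAU1_DEFAULT = 1.0
#: Published weight of the penalized factor.
TAU2_DEFAULT = -1.0011

#: Normalized-expression threshold separating under- from over-expression.
EXPRESSION_THRESHOLD = 0.5
#: Outcome horizon in years used to dichotomize TTP.
TTP_HORIZON = 5.0


@dataclass
class VCResult:
    """Per-gene VC scores.

    ``table`` is indexed by gene id with columns ``alpha``, ``beta``, ``vc``,
    ``p``, ``q`` (p + q = number of scored samples).
    """

    table: pd.DataFrame
    tau1: float = TAU1_DEFAULT
    tau2: float = TAU2_DEFAULT
    n_samples: int = 0

    @property
    def vc(self) -> pd.Series:
        return self.table["vc"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, tau1: float = TAU1_DEFAULT,
                 tau2: float = TAU2_DEFAULT) -> "VCResult":
        table = pd.read_csv(path, sep="\t", index_col="gene")
        n = int(table["p"].iloc[0] + table["q"].iloc[0]) if len(table) else 0
        return cls(table, tau1=tau1, tau2=tau2, n_samples=n)


def correlation_coefficient(
    ttp: float,
    e: float,
    *,
    horizon: float = TTP_HORIZON,
    threshold: float = EXPRESSION_THRESHOLD,
) -> int:
    """Dichotomized agreement between one sample's outcome and expression.

    Returns +1 if (TTP <= horizon and e < threshold) or
    (TTP > horizon and e >= threshold), else -1.
    """
    if (ttp <= horizon and e < threshold) or (ttp > horizon and e >= threshold):
        return 1
    return -1


def correlation_factor(
    gene_row: np.ndarray,
    ttps: np.ndarray,
    *,
    horizon: float = TTP_HORIZON,
    threshold: float = EXPRESSION_THRESHOLD,
) -> float:
    """alpha = (p - q) / N over one gene's expressions and the samples' TTPs."""
    e = np.asarray(gene_row, dtype=float)
    t = np.asarray(ttps, dtype=float)
    if e.size == 0:
        raise ValueError("cannot compute the correlation factor of no samples")
    if e.shape != t.shape:
        raise ValueError("expression and TTP vectors differ in length")
    cc = _cc_matrix(e[None, :], t, horizon, threshold)[0]
    return float(cc.mean())


def penalized_factor(gene_row: np.ndarray, labels: np.ndarray) -> float:
    """beta = 1 - |mean over poor samples - mean over good samples|."""
    e = np.asarray(gene_row, dtype=float)
    lab = np.asarray(labels)
    poor = lab == POOR
    good = lab == GOOD
    if not poor.any() or not good.any():
        raise ValueError("both prognosis groups must be non-empty")
    return float(1.0 - abs(e[poor].mean() - e[good].mean()))


def vc_score(
    alpha: float,
    beta: float,
    tau1: float = TAU1_DEFAULT,
    tau2: float = TAU2_DEFAULT,
) -> float:
    """VC = tau1 * alpha + tau2 * beta."""
    return tau1 * alpha + tau2 * beta


def _cc_matrix(
    e: np.ndarray, ttps: np.ndarray, horizon: float, threshold: float
) -> np.ndarray:
    early = ttps <= horizon
    under = e < threshold
    agree = (early & under) | (~early & ~under)
    return np.where(agree, 1, -1)


def score_all(
    cohort: LabeledCohort,
    tau1: float = TAU1_DEFAULT,
    tau2: float = TAU2_DEFAULT,
    *,
    include_constant: bool = False,
    horizon: float = TTP_HORIZON,
    threshold: float = EXPRESSION_THRESHOLD,
) -> VCResult:
    """Score every gene of a labelled, normalized cohort.

    Only labelled samples enter the computation (censored samples carry no
    5-year outcome).  Genes flagged constant during normalization are
    excluded by default: their all-zero rows would score an artifact of the
    zero fill rather than any biology.
    """
    if not cohort.expr.normalized:
        raise ValueError("score_all expects a min-max normalized cohort")
    samples = cohort.labels.index
    values = cohort.expr.values.loc[:, samples]
    if not include_constant and cohort.expr.constant_genes:
        values = values.drop(index=list(cohort.expr.constant_genes), errors="ignore")

    e = values.to_numpy(dtype=float)
    ttps = cohort.clinical.loc[samples, "ttp_years"].to_numpy(dtype=float)
    labels = cohort.labels.loc[samples].to_numpy()

    cc = _cc_matrix(e, ttps, horizon, threshold)
    n = e.shape[1]
    p = (cc == 1).sum(axis=1)
    q = n - p
    alpha = (p - q) / n

    poor = labels == POOR
    good = labels == GOOD
    if not poor.any() or not good.any():
        raise ValueError("both prognosis groups must be non-empty")
    beta = 1.0 - np.abs(e[:, poor].mean(axis=1) - e[:, good].mean(axis=1))

    table = pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "vc": tau1 * alpha + tau2 * beta,
            "p": p,
            "q": q,
        },
        index=values.index,
    )
    return VCResult(table, tau1=tau1, tau2=tau2, n_samples=n)
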