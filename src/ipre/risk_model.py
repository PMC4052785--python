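"""Clinical covariate encoding, the logistic risk model and its cutoff.

Covariate coding (poor prognosis is the positive class, coded 1):

====  ===========  ==============================  ==================
name  variable     characteristics                 code
====  ===========  ==============================  ==================
x1    tumour grade I-II / III                      0 / 1
x2    tumour size  < 2 cm / 2 to < 4 cm / >= 4 cm  0 / 0.55 / 1
x3    ER status    negative / positive             -1 / +1
x4    PR status    negative / positive             -1 / +1
x5    HER2 status  negative / positive             -1 / +1
x6    mScore       mean signature expression       value in [0, 1]
====  ===========  ==============================  ==================

The model is a maximum-likelihood logistic regression fit with backward
elimination: starting from all candidate covariates, the variable with the
largest Wald P value above ``alpha`` (0.05) is removed and the model refit,
until every retained variable is significant.  The linear predictor
RS = b0 + sum(bn * xn) is the risk score; a sample is called poor when
RS >= epsilon.  The published model ships as the preset ``"ipre-2014"``
(cutoff epsilon = -1.480).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .datasets import GOOD, POOR, ExpressionMatrix

__all__ = [
    "COVARIATE_NAMES",
    "CUTOFF_DEFAULT",
    "RiskModel",
    "encode_clinical",
    "impute_receptor",
    "fit_logistic_backward",
    "risk_score",
    "classify",
    "choose_cutoff",
    "load_preset",
]

COVARIATE_NAMES = (
    "x1_grade",
    "x2_size",
    "x3_er",
    "x4_pr",
    "x5_her2",
    "x6_mscore",
)

#: Published risk-score cutoff.
CUTOFF_DEFAULT = -1.480

_STATUS_CODE = {"positive": 1.0, "negative": -1.0}
_GRADE_CODE = {"I": 0.0, "II": 0.0, "III": 1.0}


@dataclass
class RiskModel:
    """A (fitted or preset) logistic risk model.

    ``coefficients`` maps retained covariate names to their coefficients;
    ``trace`` records backward elimination as (variable, P at removal) pairs.
    """

    intercept: float
    coefficients: dict[str, float]
    cutoff: float = CUTOFF_DEFAULT
    alpha: float = 0.05
    trace: list[tuple[str, float]] = field(default_factory=list)
    p_values: dict[str, float] = field(default_factory=dict)
    std_errors: dict[str, float] = field(default_factory=dict)
    z_values: dict[str, float] = field(default_factory=dict)
    name: str = "fitted"

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def risk_score(self, covariates) -> pd.Series | float:
        return risk_score(self, covariates)

    def classify(self, covariates) -> pd.Series | str:
        rs = self.risk_score(covariates)
        return classify(rs, self.cutoff)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "cutoff": self.cutoff,
            "alpha": self.alpha,
            "trace": [list(t) for t in self.trace],
            "p_values": self.p_values,
            "std_errors": self.std_errors,
            "z_values": self.z_values,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RiskModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            cutoff=float(d.get("cutoff", CUTOFF_DEFAULT)),
            alpha=float(d.get("alpha", 0.05)),
            trace=[(v, float(p)) for v, p in d.get("trace", [])],
            p_values={k: float(v) for k, v in d.get("p_values", {}).items()},
            std_errors={k: float(v) for k, v in d.get("std_errors", {}).items()},
            z_values={k: float(v) for k, v in d.get("z_values", {}).items()},
            name=d.get("name", "fitted"),
        )


#: The published model: size, ER, PR and mScore retained (grade and HER2
#: eliminated), fitted on the balanced integrated training compendium.
PRESET_IPRE_2014 = RiskModel(
    intercept=-0.99475,
    coefficients={
        "x2_size": -0.34534,
        "x3_er": -0.19854,
        "x4_pr": -0.21123,
        "x6_mscore": -1.13115,
    },
    cutoff=CUTOFF_DEFAULT,
    name="ipre-2014",
)

_PRESETS = {"ipre-2014": PRESET_IPRE_2014}


def load_preset(name: str) -> RiskModel:
    """Return a packaged model preset by name (currently ``"ipre-2014"``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")


def _encode_size(size_cm: float) -> float:
    if pd.isna(size_cm):
        return np.nan
    if size_cm < 0:
        raise ValueError(f"negative tumour size {size_cm!r}")
    if size_cm < 2:
        return 0.0
    if size_cm < 4:
        return 0.55
    return 1.0


def encode_clinical(clinical: pd.DataFrame, mscore: pd.Series) -> pd.DataFrame:
    """Encode a clinical table plus mScores into model covariates x1..x6.

    Missing grade or size encodes as NaN — the sample remains usable by any
    model that does not retain that covariate.  Missing ER/PR should be
    imputed (see :func:`impute_receptor`) before fitting.
    """
    idx = clinical.index
    ms = mscore.reindex(idx)
    if ((ms < 0) | (ms > 1)).any():
        raise ValueError("mScore must lie in [0, 1]")
    enc = pd.DataFrame(
        {
            "x1_grade": clinical["grade"].map(_GRADE_CODE),
            "x2_size": clinical["size_cm"].map(_encode_size),
            "x3_er": clinical["er"].map(_STATUS_CODE),
            "x4_pr": clinical["pr"].map(_STATUS_CODE),
            "x5_her2": clinical["her2"].map(_STATUS_CODE),
            "x6_mscore": ms,
        },
        index=idx,
    )
    return enc


def impute_receptor(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    *,
    threshold: float = 0.5,
    er_gene: str = "ESR1",
    pr_gene: str = "PGR",
) -> pd.DataFrame:
    """Fill missing ER/PR status from dichotomized receptor-gene expression.

    A missing status becomes positive when the sample's normalized ESR1
    (resp. PGR) expression is >= ``threshold`` — the same over-expression
    convention used by the VC score — and negative otherwise.  Recorded
    statuses are never overridden.  When the receptor gene is absent from
    the matrix the status stays missing.
    """
    out = clinical.copy()
    for column, gene in (("er", er_gene), ("pr", pr_gene)):
        missing = out[column].isna()
        if not missing.any():
            continue
        if gene not in expr.gene_ids:
            continue
        imputable = missing & out.index.isin(expr.sample_ids)
        samples = out.index[imputable]
        values = expr.values.loc[gene, samples]
        out[column] = out[column].astype(object)
        out.loc[samples, column] = np.where(
            values >= threshold, "positive", "negative"
        )
    return out


def _check_collinearity(X: pd.DataFrame) -> None:
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=0)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(arr)), arr])) == arr.shape[1] + 1:
        return
    # rank-deficient: name an offending pair if one exists
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(centered, rowvar=False)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.isclose(abs(corr[i, j]), 1.0, atol=1e-10):
                raise ValueError(
                    f"collinear covariates: {cols[i]!r} and {cols[j]!r}"
                )
    raise ValueError("design matrix is rank deficient (collinear covariates)")


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise PerfectSeparationError(
                "the outcome is perfectly separated by the covariates; "
                "a maximum-likelihood logistic fit does not exist (consider "
                "removing the separating covariate or adding samples)"
            ) from exc
    if not np.isfinite(result.params).all() or not np.isfinite(result.bse).all():
        raise PerfectSeparationError(
            "logistic fit diverged (quasi-separation); coefficients are not "
            "identifiable"
        )
    return result


def fit_logistic_backward(
    covariates: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    alpha: float = 0.05,
    cutoff: float = CUTOFF_DEFAULT,
) -> RiskModel:
    """Fit poor/good on the candidate covariates with backward elimination.

    At each step the covariate with the largest Wald P value above ``alpha``
    is removed (one per refit) until all retained covariates have P <= alpha;
    the elimination order and P values are recorded in the trace.  All
    candidate covariates must be complete (no NaN).
    """
    X = covariates.copy()
    lab = pd.Series(np.asarray(labels), index=X.index)
    bad = set(lab.unique()) - {POOR, GOOD}
    if bad:
        raise ValueError(f"labels must be 'poor'/'good', got {sorted(bad)}")
    y = (lab == POOR).to_numpy(dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least two samples per prognosis class")
    if X.isna().any().any():
        col = X.columns[X.isna().any()][0]
        raise ValueError(f"candidate covariate {col!r} has missing values")
    _check_collinearity(X)

    trace: list[tuple[str, float]] = []
    while True:
        if X.shape[1] == 0:
            # intercept-only model
            result = _fit_logit(y, X)
            return RiskModel(
                intercept=float(result.params["const"]),
                coefficients={},
                cutoff=cutoff,
                alpha=alpha,
                trace=trace,
                p_values={},
                std_errors={},
                z_values={},
            )
        result = _fit_logit(y, X)
        pvals = result.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            trace.append((str(worst), float(pvals[worst])))
            X = X.drop(columns=[worst])
            continue
        params = result.params
        return RiskModel(
            intercept=float(params["const"]),
            coefficients={c: float(params[c]) for c in X.columns},
            cutoff=cutoff,
            alpha=alpha,
            trace=trace,
            p_values={c: float(result.pvalues[c]) for c in X.columns},
            std_errors={c: float(result.bse[c]) for c in X.columns},
            z_values={c: float(result.tvalues[c]) for c in X.columns},
        )


def risk_score(model: RiskModel, covariates) -> pd.Series | float:
    """RS = b0 + sum over retained covariates of bn * xn.

    ``covariates`` may be a DataFrame (returns a Series) or a mapping /
    Series for a single sample (returns a float).  A missing or NaN retained
    covariate is an error.
    """
    if isinstance(covariates, pd.DataFrame):
        rs = pd.Series(model.intercept, index=covariates.index, name="rs", dtype=float)
        for name, coef in model.coefficients.items():
            if name not in covariates.columns:
                raise ValueError(f"retained covariate {name!r} not provided")
            col = covariates[name].astype(float)
            if col.isna().any():
                sample = covariates.index[col.isna()][0]
                raise ValueError(
                    f"retained covariate {name!r} missing for sample {sample!r}"
                )
            rs = rs + coef * col
        return rs
    row: Mapping[str, float] = dict(covariates)
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in row or pd.isna(row[name]):
            raise ValueError(f"retained covariate {name!r} not provided")
        total += coef * float(row[name])
    return float(total)


def classify(rs, epsilon: float = CUTOFF_DEFAULT):
    """poor iff RS >= epsilon (the boundary itself is poor)."""
    if isinstance(rs, pd.Series):
        out = pd.Series(np.where(rs >= epsilon, POOR, GOOD), index=rs.index,
                        name="label")
        return out
    if isinstance(rs, np.ndarray):
        return np.where(rs >= epsilon, POOR, GOOD)
    return POOR if float(rs) >= epsilon else GOOD


def _f_value(tp: int, fp: int, fn: int) -> float:
    # F1 with poor as the positive class; 0 when precision or sensitivity
    # is undefined or zero.
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def choose_cutoff(
    rs: Sequence[float] | pd.Series,
    labels: Sequence[str] | pd.Series,
    grid_step: float = 0.001,
) -> float:
    """Scan cutoffs over [min RS, max RS] and return the F-value maximizer.

    Candidates are the regular grid at ``grid_step`` plus every observed
    score, so no achievable confusion matrix is missed between grid points.
    Ties are broken toward higher specificity, then toward the smaller
    cutoff.
    """
    scores = np.asarray(rs, dtype=float)
    lab = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("no scores")
    poor = lab == POOR
    good = lab == GOOD
    if not poor.any() or not good.any():
        raise ValueError("both prognosis classes must be present")

    lo, hi = scores.min(), scores.max()
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    candidates = np.unique(np.concatenate([grid, scores]))

    poor_sorted = np.sort(scores[poor])
    good_sorted = np.sort(scores[good])
    n_poor, n_good = poor_sorted.size, good_sorted.size

    # predicted poor <=> rs >= eps
    tp = n_poor - np.searchsorted(poor_sorted, candidates, side="left")
    fp = n_good - np.searchsorted(good_sorted, candidates, side="left")
    fn = n_poor - tp
    tn = n_good - fp
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
        spec = tn / n_good

    best_f = f.max()
    mask = f == best_f
    best_spec = spec[mask].max()
    mask &= spec == best_spec
    return float(candidates[mask].min())
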