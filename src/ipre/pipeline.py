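"""End-to-end training and prediction built from the stage modules.

``train`` runs normalize -> integrate -> (balance) -> VC scoring ->
signature extraction -> covariate encoding -> backward-selected logistic
fit, and ``predict`` applies a signature + model to a new cohort.  These
are the same calls the command line makes, packaged for scripted use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import datasets, risk_model, signature as sig_mod, vc
from .datasets import ExpressionMatrix, LabeledCohort
from .risk_model import RiskModel
from .signature import RobustnessProfile, Signature
from .vc import VCResult

__all__ = ["TrainResult", "train", "predict", "normalize_cohort"]


def normalize_cohort(cohort: LabeledCohort) -> LabeledCohort:
    """Min-max normalize a cohort's expression in place of the raw matrix."""
    return LabeledCohort(
        datasets.minmax_normalize(cohort.expr), cohort.clinical, cohort.labels
    )


@dataclass
class TrainResult:
    cohort: LabeledCohort  # the integrated (and possibly balanced) cohort
    vc_result: VCResult
    profile: RobustnessProfile
    signature: Signature
    model: RiskModel
    train_rs: pd.Series


def train(
    cohorts: list[LabeledCohort],
    *,
    balance_seed: int | None = None,
    tau1: float = vc.TAU1_DEFAULT,
    tau2: float = vc.TAU2_DEFAULT,
    weight_exponent: float = sig_mod.WEIGHT_EXPONENT_DEFAULT,
    alpha: float = 0.05,
    tune_cutoff: bool = True,
    already_normalized: bool = False,
) -> TrainResult:
    """Fit the full prognosis classifier on training cohorts.

    Cohorts are normalized separately, integrated on their common genes and
    optionally class-balanced (``balance_seed``).  The fitted model's cutoff
    is the F-value-maximizing threshold over the training risk scores unless
    ``tune_cutoff`` is False (then the published default applies).
    """
    if not already_normalized:
        cohorts = [normalize_cohort(c) for c in cohorts]
    integrated = datasets.integrate(cohorts)
    if balance_seed is not None:
        integrated = datasets.balance(integrated, balance_seed)

    vc_result = vc.score_all(integrated, tau1, tau2)
    signature, profile = sig_mod.extract_signature(
        vc_result, weight_exponent, name="prognostic-signature"
    )

    labels = integrated.labels
    clinical = risk_model.impute_receptor(
        integrated.expr, integrated.clinical.loc[labels.index]
    )
    ms = sig_mod.mscore(integrated.expr, signature)
    covariates = risk_model.encode_clinical(clinical, ms)
    # candidate covariates must be complete; drop samples that still have a
    # missing value (e.g. absent receptor gene or missing grade/size)
    complete = covariates.dropna()
    model = risk_model.fit_logistic_backward(
        complete, labels.loc[complete.index], alpha=alpha
    )
    train_rs = model.risk_score(complete)
    if tune_cutoff:
        model.cutoff = risk_model.choose_cutoff(train_rs, labels.loc[complete.index])
    return TrainResult(integrated, vc_result, profile, signature, model, train_rs)


def predict(
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    signature: Signature,
    model: RiskModel,
    *,
    already_normalized: bool = False,
) -> pd.DataFrame:
    """Score and classify every sample of a test cohort.

    The test cohort is normalized independently of training.  Returns a
    DataFrame with columns ``rs`` and ``predicted`` indexed by sample;
    samples with a missing retained covariate are dropped with a ``reason``
    left in the companion ``excluded`` attribute of the frame.
    """
    if not already_normalized:
        expr = datasets.minmax_normalize(expr)
    clin = risk_model.impute_receptor(expr, clinical)
    ms = sig_mod.mscore(expr, signature)
    covariates = risk_model.encode_clinical(clin.loc[ms.index.intersection(clin.index)], ms)
    needed = list(model.retained)
    usable = covariates[needed].notna().all(axis=1) if needed else pd.Series(
        True, index=covariates.index
    )
    rs = model.risk_score(covariates.loc[usable])
    out = pd.DataFrame({"rs": rs, "predicted": risk_model.classify(rs, model.cutoff)})
    out.attrs["excluded"] = list(covariates.index[~usable])
    return out
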