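"""Synthetic multi-platform cohorts with planted prognostic genes.

The generator emulates the statistical structure the scoring pipeline
assumes: several cohorts ("platforms") of normalized-scale expression with
overlapping but unequal gene panels, a block of planted prognostic genes
whose mean shifts between prognosis groups around the 0.5 dichotomization
point, receptor reporter genes (ESR1, PGR) tied to ER/PR status, clinical
covariates driving the outcome through a known logistic model, and
time-to-progression values consistent with the 5-year labelling rule
(plus censored decoys that the labeller must exclude).

Everything needed to score recovery is returned as ground truth: the
planted gene ids, the true log-odds coefficients, and the per-sample latent
labels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import datasets
from .datasets import GOOD, POOR, ExpressionMatrix, LabeledCohort

__all__ = ["SimConfig", "GroundTruth", "simulate_cohorts", "write_cohorts"]

logger = logging.getLogger(__name__)

#: True log-odds contribution of each encoded clinical covariate to the
#: poor-prognosis outcome.  Grade is deliberately null so that backward
#: elimination has a known variable to drop.
CLINICAL_EFFECTS_DEFAULT = {
    "x1_grade": 0.0,
    "x2_size": 1.0,
    "x3_er": -1.0,
    "x4_pr": -0.8,
    "x5_her2": 0.5,
}


@dataclass
class SimConfig:
    """Generator settings; the defaults define the standard study conditions.

    ``effect`` is the planted between-group mean shift on the normalized
    expression scale; ``noise_sd`` the within-group spread.  ``n_genes``
    counts all genes per cohort including the planted block and the two
    receptor reporters.
    """

    n_cohorts: int = 3
    n_samples: int = 300
    n_genes: int = 1000
    n_prognostic: int = 50
    effect: float = 0.3
    noise_sd: float = 0.15
    poor_fraction: float = 0.4
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: dict(CLINICAL_EFFECTS_DEFAULT)
    )
    missing_rate: float = 0.1
    censored_fraction: float = 0.05
    gene_dropout: float = 0.05
    good_event_rate: float = 0.25
    module_correlation: float = 0.3
    seed: int = 20140514

    def validate(self) -> None:
        if not 0 < self.poor_fraction < 1:
            raise ValueError("poor_fraction must lie in (0, 1)")
        if not 0 <= self.effect < 1:
            raise ValueError("effect must lie in [0, 1)")
        if self.n_prognostic > self.n_genes - 2:
            raise ValueError("n_prognostic must leave room for null genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if 0.5 + self.effect / 2 + 2 * self.noise_sd > 1.5:
            raise ValueError(
                "effect + noise push group means too far outside [0, 1]; "
                "clipping would destroy the intended signal"
            )
        if not 0 <= self.censored_fraction < 1:
            raise ValueError("censored_fraction must lie in [0, 1)")
        if not 0 <= self.module_correlation < 1:
            raise ValueError("module_correlation must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    planted_genes: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    labels: dict[str, pd.Series]  # cohort id -> latent poor/good per sample

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_genes": list(self.planted_genes),
            "coefficients": self.coefficients,
            "labels": {c: s.to_dict() for c, s in self.labels.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _calibrate_intercept(linear: np.ndarray, poor_fraction: float) -> float:
    """Intercept b0 with mean sigmoid(b0 + linear) == poor_fraction."""
    return float(
        brentq(lambda b0: expit(b0 + linear).mean() - poor_fraction, -30.0, 30.0)
    )


def simulate_cohorts(cfg: SimConfig | None = None) -> tuple[list[LabeledCohort], GroundTruth]:
    """Generate labelled cohorts plus ground truth, reproducibly from the seed."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    planted = tuple(f"PG{i:04d}" for i in range(cfg.n_prognostic))
    n_null = cfg.n_genes - cfg.n_prognostic - 2
    nulls = tuple(f"NG{i:04d}" for i in range(n_null))
    reporters = ("ESR1", "PGR")

    truth_labels: dict[str, pd.Series] = {}
    cohorts: list[LabeledCohort] = []
    n_clipped = total_values = 0

    for c in range(cfg.n_cohorts):
        cohort_id = f"sim{c + 1}"
        n = cfg.n_samples
        samples = [f"s{c + 1}_{i:03d}" for i in range(n)]

        grade = rng.choice(["I", "II", "III"], size=n, p=[0.2, 0.45, 0.35])
        size_cm = rng.uniform(0.5, 6.0, size=n)
        er = rng.random(n) < 0.65
        pr = rng.random(n) < 0.55
        her2 = rng.random(n) < 0.20

        x = {
            "x1_grade": (grade == "III").astype(float),
            "x2_size": np.select([size_cm < 2, size_cm < 4], [0.0, 0.55], 1.0),
            "x3_er": np.where(er, 1.0, -1.0),
            "x4_pr": np.where(pr, 1.0, -1.0),
            "x5_her2": np.where(her2, 1.0, -1.0),
        }
        linear = sum(cfg.clinical_effects.get(k, 0.0) * v for k, v in x.items())
        if c == 0:
            # one true intercept for all cohorts, calibrated so the expected
            # poor fraction matches the configured rate
            b0 = _calibrate_intercept(linear, cfg.poor_fraction)
        poor = rng.random(n) < expit(b0 + linear)

        n_cens = int(round(cfg.censored_fraction * n))
        censored = np.zeros(n, dtype=bool)
        if n_cens:
            censored[rng.choice(n, size=n_cens, replace=False)] = True

        ttp = np.where(poor, rng.uniform(0.0, 5.0, n), rng.uniform(5.0, 12.0, n))
        ttp = np.clip(ttp, 1e-3, None)  # TTP must be strictly positive
        event = np.where(poor, True, rng.random(n) < cfg.good_event_rate)
        # censored decoys: follow-up ended before 5 years, no event observed
        ttp[censored] = rng.uniform(0.0, 5.0, censored.sum()).clip(min=1e-3)
        event[censored] = False

        means = np.full((cfg.n_genes, n), 0.5)
        gene_ids = list(planted) + list(nulls) + list(reporters)
        means[: cfg.n_prognostic, poor] = 0.5 - cfg.effect / 2
        means[: cfg.n_prognostic, ~poor] = 0.5 + cfg.effect / 2
        means[-2] = np.where(er, 0.75, 0.25)  # ESR1 tracks ER status
        means[-1] = np.where(pr, 0.75, 0.25)  # PGR tracks PR status
        raw = rng.normal(means, cfg.noise_sd)
        if cfg.module_correlation > 0 and cfg.n_prognostic:
            # planted genes form a co-expressed module: each sample carries a
            # shared latent factor so the module mean stays realistically
            # noisy instead of averaging away as 1/sqrt(n_prognostic).  Each
            # gene's marginal spread stays noise_sd.
            rho = cfg.module_correlation
            shared = rng.normal(0.0, 1.0, size=n)
            idio = rng.normal(0.0, 1.0, size=(cfg.n_prognostic, n))
            raw[: cfg.n_prognostic] = (
                means[: cfg.n_prognostic]
                + cfg.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio)
            )
        clipped = (raw < 0) | (raw > 1)
        n_clipped += int(clipped.sum())
        total_values += raw.size
        values = pd.DataFrame(np.clip(raw, 0.0, 1.0), index=gene_ids, columns=samples)

        # unequal per-cohort panels: each cohort is missing a random slice of
        # the null genes, so integration must intersect
        n_drop = int(round(cfg.gene_dropout * n_null))
        if n_drop:
            dropped = rng.choice(list(nulls), size=n_drop, replace=False)
            values = values.drop(index=list(dropped))

        er_status = np.where(er, "positive", "negative").astype(object)
        pr_status = np.where(pr, "positive", "negative").astype(object)
        er_status[rng.random(n) < cfg.missing_rate] = np.nan
        pr_status[rng.random(n) < cfg.missing_rate] = np.nan

        clinical = pd.DataFrame(
            {
                "ttp_years": ttp,
                "event": event.astype(bool),
                "er": er_status,
                "pr": pr_status,
                "her2": np.where(her2, "positive", "negative"),
                "grade": grade,
                "size_cm": size_cm,
                "cohort_id": cohort_id,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        labels = datasets.assign_labels(clinical)
        cohorts.append(LabeledCohort(ExpressionMatrix(values), clinical, labels))
        truth_labels[cohort_id] = pd.Series(
            np.where(poor, POOR, GOOD), index=samples
        )

    if total_values:
        logger.info(
            "clipped %.3f%% of expression values to [0, 1]",
            100.0 * n_clipped / total_values,
        )
    coefficients = {"intercept": b0, **cfg.clinical_effects}
    return cohorts, GroundTruth(planted, coefficients, truth_labels)


def write_cohorts(
    cohorts: list[LabeledCohort],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write each cohort as expr_/clinical_ TSVs plus ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort in cohorts:
        cid = cohort.clinical["cohort_id"].iloc[0]
        cohort.expr.to_tsv(outdir / f"expr_{cid}.tsv")
        cohort.clinical.rename_axis("sample_id").to_csv(
            outdir / f"clinical_{cid}.tsv", sep="\t", na_rep="NA"
        )
    truth.to_json(outdir / "ground_truth.json")
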