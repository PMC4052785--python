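"""Signature extraction from ranked VC scores, and the per-sample mScore.

Genes are sorted by VC descending; the robustness score of the top-m prefix
is the weighted prefix sum

    R_m = m^(-1/2) * sum_{n=1..m} VC_n,

the inverse-square-root weighting used in rank aggregation.  The signature is
the prefix that maximizes R_m.  The mScore of a sample is the mean normalized
expression of the signature genes, later used as the expression covariate of
the risk model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionMatrix
from .vc import VCResult

__all__ = [
    "RobustnessProfile",
    "Signature",
    "rank_genes",
    "robustness_profile",
    "select_signature",
    "extract_signature",
    "mscore",
]

logger = logging.getLogger(__name__)

#: Exponent w of the prefix weight m^(-w).  0.5 is the inverse square root
#: of the prefix length; 1.0 gives the plain prefix mean as an alternative.
WEIGHT_EXPONENT_DEFAULT = 0.5


@dataclass
class RobustnessProfile:
    """Ranked genes with their prefix robustness scores.

    ``m_star`` is the 1-based rank of the maximal robustness score (first
    index on exact ties, giving the smaller signature).
    """

    ranked_genes: tuple[str, ...]
    vc_sorted: np.ndarray
    r_scores: np.ndarray
    m_star: int

    def __post_init__(self) -> None:
        if not 1 <= self.m_star <= len(self.ranked_genes):
            raise ValueError("m_star out of range")


@dataclass
class Signature:
    """An ordered, duplicate-free set of signature genes."""

    gene_ids: tuple[str, ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("a signature cannot be empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature genes must be unique")

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def to_txt(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.gene_ids) + "\n")

    @classmethod
    def from_txt(cls, path: str | Path, name: str | None = None) -> "Signature":
        genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(tuple(genes), name=name or Path(path).stem)

    def to_gmt(self, path: str | Path, description: str = "") -> None:
        line = "\t".join([self.name, description, *self.gene_ids])
        Path(path).write_text(line + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "Signature":
        fields = Path(path).read_text().strip().split("\t")
        if len(fields) < 3:
            raise ValueError("GMT line needs name, description and >= 1 gene")
        return cls(tuple(fields[2:]), name=fields[0])


def rank_genes(vc: VCResult | pd.Series) -> tuple[tuple[str, ...], np.ndarray]:
    """Sort genes by VC descending, breaking ties lexicographically by id."""
    series = vc.vc if isinstance(vc, VCResult) else vc
    if len(series) == 0:
        raise ValueError("no genes to rank")
    ordered = series.sort_index().sort_values(ascending=False, kind="stable")
    return tuple(ordered.index), ordered.to_numpy(dtype=float)


def robustness_profile(
    vc_sorted: Sequence[float],
    weight_exponent: float = WEIGHT_EXPONENT_DEFAULT,
) -> tuple[np.ndarray, int]:
    """Prefix robustness scores R_m = m^(-w) * sum(VC_1..VC_m) and argmax.

    The input must already be sorted non-increasing; ties in the maximum are
    resolved toward the smallest m.
    """
    scores = np.asarray(vc_sorted, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("vc_sorted must be non-increasing")
    m = np.arange(1, scores.size + 1)
    r = np.cumsum(scores) / m ** weight_exponent
    return r, int(np.argmax(r)) + 1


def select_signature(profile: RobustnessProfile, name: str = "signature") -> Signature:
    """The signature is the top-m* ranked genes of the profile."""
    return Signature(profile.ranked_genes[: profile.m_star], name=name)


def extract_signature(
    vc: VCResult | pd.Series,
    weight_exponent: float = WEIGHT_EXPONENT_DEFAULT,
    name: str = "signature",
) -> tuple[Signature, RobustnessProfile]:
    """rank -> robustness profile -> prefix cut, in one call."""
    genes, vc_sorted = rank_genes(vc)
    r, m_star = robustness_profile(vc_sorted, weight_exponent)
    profile = RobustnessProfile(genes, vc_sorted, r, m_star)
    return select_signature(profile, name=name), profile


def mscore(
    expr: ExpressionMatrix,
    signature: Signature,
    sample: str | None = None,
) -> pd.Series | float:
    """Mean normalized expression of the signature genes per sample.

    Signature genes absent from the matrix (e.g. a test platform that lacks
    them) are skipped with a warning; with no signature gene present the
    mScore is undefined and an error is raised.  Returns a Series over all
    samples, or a float when ``sample`` is given.
    """
    present = [g for g in signature.gene_ids if g in expr.gene_ids]
    missing = len(signature.gene_ids) - len(present)
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if missing:
        logger.warning(
            "%d of %d signature genes absent from the expression matrix; "
            "mScore uses the %d present genes",
            missing, signature.size, len(present),
        )
    scores = expr.values.loc[present].mean(axis=0)
    scores.name = "mscore"
    if sample is not None:
        return float(scores[sample])
    return scores
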