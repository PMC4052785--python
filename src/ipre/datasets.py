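"""Reading, collapsing, normalizing and integrating multi-cohort expression data.

The containers here are thin wrappers around :class:`pandas.DataFrame` in the
orientation used throughout the package: expression matrices are genes x
samples, clinical tables are one row per sample.  All downstream scoring
assumes expression has been min-max normalized per gene *within each cohort*
so that values live in [0, 1] and the 0.5 over/under-expression threshold is
meaningful across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabeledCohort",
    "ProbeCollapseLog",
    "CLINICAL_COLUMNS",
    "read_expression",
    "read_clinical",
    "collapse_probes",
    "minmax_normalize",
    "integrate",
    "assign_labels",
    "balance",
    "write_cohort",
    "read_cohort",
    "read_probe_map",
]

logger = logging.getLogger(__name__)

#: Expected columns of a clinical table (besides the sample_id index).
CLINICAL_COLUMNS = (
    "ttp_years",
    "event",
    "er",
    "pr",
    "her2",
    "grade",
    "size_cm",
    "cohort_id",
)

POOR, GOOD = "poor", "good"


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    constant_genes
        Gene ids whose expression was constant when min-max normalization was
        applied (their rows are all zero); empty before normalization.
    normalized
        True once values have been min-max scaled to [0, 1] per gene.
    """

    values: pd.DataFrame
    constant_genes: tuple[str, ...] = ()
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def to_tsv(self, path: str | Path, *, gene_column: str = "gene") -> None:
        self.values.rename_axis(gene_column).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(read_expression(path))


@dataclass
class LabeledCohort:
    """Expression + clinical data with per-sample prognosis labels.

    ``labels`` maps sample id -> {"poor", "good"}; poor means metastasis or
    recurrence observed within the labelling horizon (5 years by default),
    good means progression-free beyond it.  Labelled samples must be present
    in both the expression matrix and the clinical table; censored samples
    may exist in either container but carry no label.
    """

    expr: ExpressionMatrix
    clinical: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        missing_expr = self.labels.index.difference(self.expr.sample_ids)
        if len(missing_expr):
            raise ValueError(
                f"labelled sample {missing_expr[0]!r} absent from expression matrix"
            )
        missing_clin = self.labels.index.difference(self.clinical.index)
        if len(missing_clin):
            raise ValueError(
                f"labelled sample {missing_clin[0]!r} absent from clinical table"
            )
        bad = set(self.labels.unique()) - {POOR, GOOD}
        if bad:
            raise ValueError(f"labels must be 'poor'/'good', got {sorted(bad)}")

    @property
    def n_labeled(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {POOR: int(vc.get(POOR, 0)), GOOD: int(vc.get(GOOD, 0))}

    def subset(self, sample_ids: Sequence[str]) -> "LabeledCohort":
        """Restrict the cohort to the given samples (order preserved)."""
        ids = pd.Index(sample_ids)
        return LabeledCohort(
            expr=ExpressionMatrix(
                self.expr.values.loc[:, ids],
                constant_genes=self.expr.constant_genes,
                normalized=self.expr.normalized,
            ),
            clinical=self.clinical.loc[self.clinical.index.intersection(ids)],
            labels=self.labels.loc[self.labels.index.intersection(ids)],
        )


@dataclass
class ProbeCollapseLog:
    """Record of what :func:`collapse_probes` dropped."""

    n_affx: int = 0
    n_unmapped: int = 0
    dropped_probes: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_affx + self.n_unmapped


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix: first column gene/probe id, then samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a per-sample clinical TSV (missing values encoded as ``NA``).

    Columns: sample_id, ttp_years, event, er, pr, her2, grade, size_cm,
    cohort_id.  ``event`` is parsed to boolean; receptor statuses are kept as
    the strings "positive"/"negative" with NaN for missing.
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns {missing}")
    df.index = df.index.astype(str)
    df["event"] = df["event"].map(
        {True: True, False: False, 1: True, 0: False, "yes": True, "no": False,
         "1": True, "0": False, "True": True, "False": False}
    )
    ttp = df["ttp_years"]
    bad = ttp.notna() & ~(np.isfinite(ttp) & (ttp > 0))
    if bad.any():
        raise ValueError(
            f"ttp_years must be finite and positive; offending sample "
            f"{df.index[bad][0]!r}"
        )
    return df


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a two-column TSV probe_id -> gene_symbol map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene"],
                     dtype=str, comment="#")
    return df.set_index("probe_id")["gene"]


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping[str, str] | pd.Series,
) -> tuple[ExpressionMatrix, ProbeCollapseLog]:
    """Collapse a probe x sample matrix to gene level.

    Control probes (ids starting with ``AFFX``, which map to no gene) and
    probes absent from ``probe_map`` are dropped; when several probes map to
    the same gene the gene row is their arithmetic mean.
    """
    if probe_matrix.index.has_duplicates:
        raise ValueError("probe ids must be unique")
    pmap = pd.Series(dict(probe_map)) if not isinstance(probe_map, pd.Series) else probe_map

    log = ProbeCollapseLog()
    is_affx = probe_matrix.index.astype(str).str.startswith("AFFX")
    log.n_affx = int(is_affx.sum())
    log.dropped_probes.extend(probe_matrix.index[is_affx])
    kept = probe_matrix.loc[~is_affx]

    mapped = kept.index.isin(pmap.index)
    log.n_unmapped = int((~mapped).sum())
    log.dropped_probes.extend(kept.index[~mapped])
    kept = kept.loc[mapped]

    if kept.empty:
        raise ValueError("no probe maps to any gene: empty collapsed matrix")

    genes = pmap.reindex(kept.index)
    collapsed = kept.groupby(genes.values).mean()
    collapsed.index = collapsed.index.astype(str)
    collapsed = collapsed.sort_index()
    logger.info(
        "collapsed %d probes to %d genes (dropped %d AFFX, %d unmapped)",
        len(probe_matrix), len(collapsed), log.n_affx, log.n_unmapped,
    )
    return ExpressionMatrix(collapsed), log


def minmax_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene row to [0, 1]: e' = (e - min) / (max - min).

    Applied within a single cohort.  Genes whose expression is constant
    (max == min) are set to 0 everywhere and flagged in ``constant_genes``
    so downstream scoring can exclude them.
    """
    values = expr.values
    if values.shape[1] < 1:
        raise ValueError("cannot normalize a matrix with no samples")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        g, s = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite expression for gene {values.index[g]!r}, "
            f"sample {values.columns[s]!r}"
        )
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0  # avoid 0/0; constant rows forced to 0 below
    out = (arr - lo) / span
    out[constant] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        constant_genes=tuple(values.index[constant]),
        normalized=True,
    )


def integrate(
    cohorts: Sequence[LabeledCohort],
    *,
    exclude_samples: Iterable[str] = (),
) -> LabeledCohort:
    """Merge normalized cohorts on their common genes.

    The integrated gene set is the intersection of all cohorts' gene sets in
    lexicographic order (platform-order independent); samples are concatenated
    with ids prefixed by their cohort id to guarantee global uniqueness.
    ``exclude_samples`` removes known duplicate samples by original id.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    for c in cohorts:
        if not c.expr.normalized:
            raise ValueError("integrate expects min-max normalized cohorts")

    common = cohorts[0].expr.gene_ids
    for c in cohorts[1:]:
        common = common.intersection(c.expr.gene_ids)
    if len(common) == 0:
        raise ValueError("empty gene intersection across cohorts")
    common = common.sort_values()

    excluded = set(exclude_samples)
    mats, clins, labels, const = [], [], [], set()
    for c in cohorts:
        keep = [s for s in c.expr.sample_ids if s not in excluded]
        cid = _cohort_id(c)
        prefix = {s: f"{cid}:{s}" for s in keep}
        mats.append(c.expr.values.loc[common, keep].rename(columns=prefix))
        clin = c.clinical.loc[[s for s in c.clinical.index if s not in excluded]]
        clins.append(clin.rename(index=prefix))
        lab = c.labels.loc[[s for s in c.labels.index if s not in excluded]]
        labels.append(lab.rename(index=prefix))
        const.update(set(c.expr.constant_genes) & set(common))

    merged = ExpressionMatrix(
        pd.concat(mats, axis=1),
        constant_genes=tuple(sorted(const)),
        normalized=True,
    )
    return LabeledCohort(merged, pd.concat(clins), pd.concat(labels))


def _cohort_id(cohort: LabeledCohort) -> str:
    ids = cohort.clinical["cohort_id"].dropna().unique()
    return str(ids[0]) if len(ids) else "cohort"


def assign_labels(clinical: pd.DataFrame, horizon: float = 5.0) -> pd.Series:
    """Dichotomize samples into poor/good prognosis at ``horizon`` years.

    poor: event observed with TTP <= horizon; good: progression-free beyond
    horizon (with or without a later event).  Samples censored before the
    horizon carry no 5-year information and are excluded (logged), as are
    samples with missing TTP.
    """
    ttp = clinical["ttp_years"]
    event = clinical["event"].astype("boolean")

    no_ttp = ttp.isna()
    if no_ttp.any():
        logger.warning(
            "excluding %d samples with missing ttp_years (e.g. %r)",
            int(no_ttp.sum()), clinical.index[no_ttp][0],
        )
    poor = (~no_ttp) & (ttp <= horizon) & event.fillna(False)
    good = (~no_ttp) & (ttp > horizon)
    censored = (~no_ttp) & (ttp <= horizon) & ~event.fillna(False)
    if censored.any():
        logger.info(
            "excluding %d samples censored before the %g-year horizon",
            int(censored.sum()), horizon,
        )
    labels = pd.Series(
        np.where(poor, POOR, GOOD), index=clinical.index, dtype=object
    )[poor | good]
    return labels


def write_cohort(cohort: LabeledCohort, outdir: str | Path) -> None:
    """Write a cohort directory: expr.tsv, clinical.tsv, labels.tsv, meta.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expr.to_tsv(outdir / "expr.tsv")
    cohort.clinical.rename_axis("sample_id").to_csv(
        outdir / "clinical.tsv", sep="\t", na_rep="NA"
    )
    cohort.labels.rename("label").rename_axis("sample_id").to_csv(
        outdir / "labels.tsv", sep="\t"
    )
    meta = {
        "normalized": cohort.expr.normalized,
        "constant_genes": list(cohort.expr.constant_genes),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_cohort(indir: str | Path) -> LabeledCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    import json

    indir = Path(indir)
    values = read_expression(indir / "expr.tsv")
    clinical = read_clinical(indir / "clinical.tsv")
    labels = pd.read_csv(indir / "labels.tsv", sep="\t", index_col="sample_id")[
        "label"
    ]
    labels.index = labels.index.astype(str)
    meta_path = indir / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    expr = ExpressionMatrix(
        values,
        constant_genes=tuple(meta.get("constant_genes", ())),
        normalized=bool(meta.get("normalized", False)),
    )
    return LabeledCohort(expr, clinical, labels)


def balance(cohort: LabeledCohort, seed: int) -> LabeledCohort:
    """Equalize class sizes by uniform undersampling of the majority class.

    The minority class is kept whole; the majority class is subsampled
    without replacement with :class:`numpy.random.default_rng` seeded by
    ``seed``, so the selection is reproducible.  Sample order is preserved.
    """
    counts = cohort.class_counts()
    if counts[POOR] == 0 or counts[GOOD] == 0:
        raise ValueError("both prognosis classes must be non-empty to balance")
    minority = POOR if counts[POOR] <= counts[GOOD] else GOOD
    majority = GOOD if minority == POOR else POOR

    rng = np.random.default_rng(seed)
    maj_ids = cohort.labels.index[cohort.labels == majority]
    chosen = set(rng.choice(maj_ids.to_numpy(), size=counts[minority], replace=False))
    keep = [
        s for s in cohort.labels.index
        if cohort.labels[s] == minority or s in chosen
    ]
    return cohort.subset(keep)
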