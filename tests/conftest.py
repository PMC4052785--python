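import numpy as np
import pandas as pd
import pytest

from ipre.datasets import ExpressionMatrix, LabeledCohort


def make_cohort(values, ttps, cohort_id="c1", sample_prefix="s", labels=None,
                normalized=True, constant_genes=()):
    """Build a small labelled cohort from a gene->values mapping and TTPs.

    Samples with TTP <= 5 are poor (event observed), samples with TTP > 5
    good, unless explicit labels are given.
    """
    genes = list(values)
    n = len(next(iter(values.values())))
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(
            np.array([values[g] for g in genes], dtype=float),
            index=genes, columns=samples,
        ),
        normalized=normalized,
        constant_genes=constant_genes,
    )
    ttps = np.asarray(ttps, dtype=float)
    clinical = pd.DataFrame(
        {
            "ttp_years": ttps,
            "event": ttps <= 5,
            "er": "positive",
            "pr": "positive",
            "her2": "negative",
            "grade": "II",
            "size_cm": 2.5,
            "cohort_id": cohort_id,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    if labels is None:
        labels = pd.Series(np.where(ttps <= 5, "poor", "good"), index=samples)
    else:
        labels = pd.Series(labels, index=samples)
    return LabeledCohort(expr, clinical, labels)


@pytest.fixture
def toy_cohort():
    """4 samples (2 poor, 2 good), 3 genes, already on the normalized scale."""
    return make_cohort(
        {
            "gA": [0.1, 0.2, 0.9, 0.8],   # low in poor, high in good
            "gB": [0.9, 0.7, 0.2, 0.1],   # reversed pattern
            "gC": [0.5, 0.5, 0.5, 0.5],   # uninformative
        },
        ttps=[2.0, 4.0, 7.0, 9.0],
    )
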