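import numpy as np
import pandas as pd
import pytest

from prepostx.core_io import CountMatrix, ExprMatrix
from prepostx.simulate import SimParams, simulate_paired_counts


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across read-only tests."""
    params = SimParams(n_genes=800, seed=11)
    counts, meta, truth = simulate_paired_counts(params)
    return params, counts, meta, truth


@pytest.fixture()
def paired_meta_2subj():
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2"],
            "subject_id": ["A", "A", "B", "B"],
            "cohort": ["ACD"] * 4,
            "timepoint": ["TP1", "TP2", "TP1", "TP2"],
        }
    )


def acd_subset(counts: CountMatrix, meta: pd.DataFrame):
    sub = meta[meta["cohort"] == "ACD"].reset_index(drop=True)
    return CountMatrix(counts.counts[sub["sample_id"].tolist()]), sub


def random_expr(rng: np.random.Generator, n_genes: int, n_samples: int) -> ExprMatrix:
    return ExprMatrix(
        pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{j:02d}" for j in range(n_samples)],
        )
    )
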