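"""Multi-cohort case-control differential expression.

Emulates a cross-platform meta-cohort workflow: per-cohort harmonization
(optional quantile normalization followed by per-gene z-scoring within each
cohort), PCA-based outlier removal, and a per-gene Welch t-test between
cases and controls on the harmonized values. Because harmonized values are
on a log-like scale the group mean difference is reported directly as the
log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExprMatrix, ValidationError, make_de_table


@dataclass
class CohortConfig:
    outlier_sd: float = 4.0
    harmonization: str = "zscore_per_cohort"  # or "quantile_then_zscore"

    def __post_init__(self) -> None:
        if self.outlier_sd <= 0:
            raise ValidationError("outlier_sd must be > 0")
        if self.harmonization not in ("zscore_per_cohort", "quantile_then_zscore"):
            raise ValidationError(f"unknown harmonization mode {self.harmonization!r}")


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Within-cohort quantile normalization of sample columns to the mean
    sorted profile; ties receive the mean reference value of their ranks."""
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="mergesort")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    ranks = np.empty(n_genes)
    for j in range(n_samples):
        col = values[:, j]
        ranks = stats.rankdata(col, method="average") - 1.0
        out[:, j] = np.interp(ranks, np.arange(n_genes), ref)
    del order
    return out


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd


def harmonize_cohorts(
    matrices: list[tuple[ExprMatrix, str]],
    config: CohortConfig | None = None,
) -> tuple[ExprMatrix, pd.Series]:
    """Restrict cohorts to shared genes, harmonize each, and concatenate.

    Returns the merged matrix plus a per-sample cohort label Series.
    """
    config = config or CohortConfig()
    if not matrices:
        raise ValidationError("no cohorts provided")
    shared = matrices[0][0].values.index
    for em, _ in matrices[1:]:
        shared = shared.intersection(em.values.index)
    if len(shared) == 0:
        raise ValidationError("empty gene intersection across cohorts")
    shared = sorted(shared)
    parts = []
    labels = []
    for em, label in matrices:
        vals = em.values.loc[shared].to_numpy(dtype=float)
        if config.harmonization == "quantile_then_zscore":
            vals = _quantile_normalize(vals)
        vals = _zscore_rows(vals)
        parts.append(pd.DataFrame(vals, index=shared, columns=em.values.columns))
        labels.extend([label] * vals.shape[1])
    merged = pd.concat(parts, axis=1)
    return ExprMatrix(merged), pd.Series(labels, index=merged.columns, name="cohort")


def detect_outliers(expr: ExprMatrix, config: CohortConfig | None = None) -> pd.Series:
    """Flag samples far from the centroid in (PC1, PC2).

    A sample is flagged when its centroid distance exceeds the mean distance
    by more than ``outlier_sd`` standard deviations of the distances; the
    rule is applied once more after removing the first round of flags.
    Fewer than 4 samples: nothing is flagged.
    """
    config = config or CohortConfig()
    samples = expr.values.columns
    flags = pd.Series(False, index=samples, name="outlier")
    if len(samples) <= 3:
        return flags
    current = np.array(samples)
    for _ in range(2):  # initial pass + one iteration
        sub = expr.values[current].to_numpy(dtype=float)
        X = sub.T - sub.mean(axis=1)  # samples x genes, gene-centered
        U, S, _ = np.linalg.svd(X, full_matrices=False)
        proj = U[:, :2] * S[:2]
        d = np.linalg.norm(proj - proj.mean(axis=0), axis=1)
        sd = d.std(ddof=1)
        if sd == 0:
            break
        new = (d - d.mean()) > config.outlier_sd * sd
        if not new.any():
            break
        flags[current[new]] = True
        current = current[~new]
        if len(current) <= 3:
            break
    return flags


def case_control_de(
    expr: ExprMatrix,
    meta: pd.DataFrame,
    case_label: str = "CASE",
    control_label: str = "CTRL_CC",
) -> pd.DataFrame:
    """Per-gene Welch t-test, cases vs controls, on harmonized log-scale values.

    log2FC is the case-minus-control mean difference (values are already on
    a log scale); BH FDR across genes.
    """
    lookup = meta.set_index("sample_id")["cohort"]
    missing = [s for s in expr.sample_ids if s not in lookup.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    groups = lookup.loc[expr.sample_ids].to_numpy()
    for label in (case_label, control_label):
        if (groups == label).sum() < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    cases = vals[:, groups == case_label]
    ctrls = vals[:, groups == control_label]
    stat, pvalue = stats.ttest_ind(cases, ctrls, axis=1, equal_var=False)
    stat = np.asarray(stat, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    log2fc = cases.mean(axis=1) - ctrls.mean(axis=1)
    # constant identical groups yield NaN t; difference 0 -> p = 1
    degenerate = ~np.isfinite(pvalue)
    stat[degenerate] = 0.0
    pvalue[degenerate] = 1.0
    return make_de_table(expr.gene_ids, log2fc, stat, pvalue)
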