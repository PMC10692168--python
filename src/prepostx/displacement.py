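"""PCA of pre/post transcriptomes and the transcriptome displacement (TD) score.

TD quantifies how far individual transcriptomes move between the two
timepoints in PC space: for a cohort and component j it is the mean over
subjects of |proj_TP1 - proj_TP2| on that component. Because it is built
from absolute paired differences it is invariant to component sign flips
and to subject ordering, and scales linearly with the expression matrix.

Top-loading genes are selected by a *range* rule on the loading vector:
genes whose loading falls within the top or bottom ``fraction`` of the
loading range (not the loading quantiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ExprMatrix, ValidationError, paired_subjects


@dataclass
class PCAResult:
    projections: pd.DataFrame   # sample x component scores
    loadings: pd.DataFrame      # gene x component unit-norm weights
    var_explained: np.ndarray   # fraction per returned component


def pca_transcriptomes(
    expr: ExprMatrix,
    n_components: int = 2,
    meta: pd.DataFrame | None = None,
    subject_center: bool = False,
) -> PCAResult:
    """Deterministic PCA of samples on gene-centered log expression.

    Sign convention: each component is oriented so its largest-magnitude
    loading is positive. With ``subject_center`` (requires paired ``meta``)
    each subject's mean profile is removed first, so components reflect
    within-subject (timepoint) variation.
    """
    values = expr.values
    if n_components > min(values.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds matrix rank bound {min(values.shape)}"
        )
    if values.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = values.to_numpy(dtype=float).T  # samples x genes
    if subject_center:
        if meta is None:
            raise ValidationError("subject_center requires sample metadata")
        lookup = meta.set_index("sample_id")["subject_id"]
        subjects = np.array([lookup[s] for s in values.columns])
        for subj in np.unique(subjects):
            rows = subjects == subj
            X[rows] -= X[rows].mean(axis=0, keepdims=True)
    X = X - X.mean(axis=0, keepdims=True)  # gene-center
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((S**2).sum())
    k = n_components
    # orient: largest-|loading| entry positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    proj = U[:, :k] * S[:k]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        projections=pd.DataFrame(proj, index=values.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=values.index, columns=comp_names),
        var_explained=(S[:k] ** 2) / total if total > 0 else np.zeros(k),
    )


@dataclass
class TDReport:
    td: pd.DataFrame          # rows (cohort, component) with TD value
    per_subject: pd.DataFrame  # subject-level |TP1 - TP2| displacements
    td_mean: pd.Series        # per cohort, mean TD across requested components


def td_score(
    pca: PCAResult,
    meta: pd.DataFrame,
    components: list[str] | None = None,
) -> TDReport:
    """Transcriptome displacement per cohort and principal component.

    TD(cohort, j) = mean over subjects i of |proj_TP1(i, j) - proj_TP2(i, j)|.
    Also reports the mean of TD across the requested components per cohort.
    """
    components = components or list(pca.projections.columns)
    missing = [c for c in components if c not in pca.projections.columns]
    if missing:
        raise ValidationError(f"unknown components: {missing}")
    pairs = paired_subjects(meta)
    proj = pca.projections
    absent = [
        row.subject_id
        for row in pairs.itertuples()
        if row.tp1 not in proj.index or row.tp2 not in proj.index
    ]
    if absent:
        raise ValidationError(f"subjects missing projections for TP1/TP2: {absent}")
    records = []
    for row in pairs.itertuples():
        for comp in components:
            records.append(
                {
                    "cohort": row.cohort,
                    "subject_id": row.subject_id,
                    "component": comp,
                    "displacement": abs(proj.at[row.tp1, comp] - proj.at[row.tp2, comp]),
                }
            )
    per_subject = pd.DataFrame(records)
    td = (
        per_subject.groupby(["cohort", "component"], sort=True)["displacement"]
        .mean()
        .rename("td")
        .reset_index()
    )
    td_mean = td.groupby("cohort")["td"].mean()
    return TDReport(td=td, per_subject=per_subject, td_mean=td_mean)


def top_loading_genes(
    pca: PCAResult, component: str = "PC1", fraction: float = 0.10
) -> pd.DataFrame:
    """Genes in the top or bottom ``fraction`` of the loading *range*.

    A gene is kept if loading >= min + (1 - fraction) * range or
    loading <= min + fraction * range; result sorted by |loading| descending.
    """
    if not 0.0 < fraction < 0.5:
        raise ValidationError("fraction must be in (0, 0.5)")
    if component not in pca.loadings.columns:
        raise ValidationError(f"unknown component {component!r}")
    load = pca.loadings[component]
    lo, hi = float(load.min()), float(load.max())
    rng = hi - lo
    if rng == 0:
        warnings.warn("constant loadings; no top-loading genes", stacklevel=2)
        return pd.DataFrame(columns=["gene_id", "loading", "tail"])
    upper = lo + (1.0 - fraction) * rng
    lower = lo + fraction * rng
    sel = load[(load >= upper) | (load <= lower)]
    out = pd.DataFrame(
        {
            "gene_id": sel.index,
            "loading": sel.to_numpy(),
            "tail": np.where(sel.to_numpy() >= upper, "top", "bottom"),
        }
    )
    return out.reindex(out["loading"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
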