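"""Sample-wise gene-set scoring and pathway-level contrasts.

``gsva_scores`` computes a per-sample, per-set enrichment score in three
steps:

1. an expression-level statistic per gene and sample from the gene's
   empirical distribution across samples -- either a Gaussian-kernel CDF
   estimate with bandwidth sd/4 (default) or the plain ECDF (``kernel="ecdf"``,
   exactly rank-based and therefore invariant under any strictly monotone
   per-gene transform);
2. within each sample, genes are ranked by that statistic and receive the
   symmetric rank weight | N/2 - rank | ** tau;
3. a weighted Kolmogorov-Smirnov random walk down the ranked list; the
   enrichment score is the maximum positive deviation plus the maximum
   negative deviation (the "max deviation" variant), which lies in [-1, 1].

Pathway-level differential activity between timepoints is a paired t-test
on per-subject score differences. The cohort pathway-activation (PA)
contrast summarizes each set by the mean gene-level log2FC per cohort and a
Welch t-test between the two cohorts' per-gene log2FC vectors, then applies
the conservative activity filter |PA_acd| + |PA_control| > pa_threshold and
p < p_threshold (strict inequalities).
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExprMatrix,
    GeneSetCatalog,
    ValidationError,
    make_de_table,
    paired_subjects,
)

logger = logging.getLogger(__name__)


def _gene_stat(values: np.ndarray, kernel: str) -> np.ndarray:
    """Per-gene expression-level statistic across samples, shape (G, S)."""
    g, s = values.shape
    if kernel == "ecdf":
        out = np.empty_like(values, dtype=float)
        for i in range(g):
            out[i] = stats.rankdata(values[i], method="average") / s
        return out
    if kernel != "gaussian":
        raise ValidationError(f"unknown kernel {kernel!r}")
    sd = values.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    # z[g, j] = mean_k Phi((x_gj - x_gk) / h_g); chunk genes to bound memory
    out = np.empty_like(values, dtype=float)
    chunk = max(1, int(2e7 // (s * s)))
    for start in range(0, g, chunk):
        stop = min(start + chunk, g)
        diff = (values[start:stop, :, None] - values[start:stop, None, :]) / h[
            start:stop, None, None
        ]
        out[start:stop] = stats.norm.cdf(diff).mean(axis=2)
    const = sd == 0
    if const.any():
        out[const] = 0.5
    return out


def gsva_scores(
    expr: ExprMatrix,
    catalog: GeneSetCatalog,
    tau: float = 1.0,
    min_set_size: int = 5,
    kernel: str = "gaussian",
) -> pd.DataFrame:
    """Set x sample enrichment scores in [-1, 1].

    Sets with fewer than ``min_set_size`` measured genes are dropped (and
    logged); an error is raised if nothing remains.
    """
    values = expr.values.to_numpy(dtype=float)
    genes = list(expr.values.index)
    n_genes, n_samples = values.shape
    z = _gene_stat(values, kernel)
    # rank genes within each sample by decreasing statistic
    order = np.argsort(-z, axis=0, kind="mergesort")  # (G, S): gene index at each rank
    ranks = np.empty_like(order)
    col = np.arange(n_samples)
    ranks[order, col] = np.arange(1, n_genes + 1)[:, None]
    weight = np.abs(n_genes / 2.0 - ranks) ** tau  # symmetric rank weight
    weight_ord = np.take_along_axis(weight, order, axis=0)

    gene_pos = {gid: i for i, gid in enumerate(genes)}
    kept: list[str] = []
    rows: list[np.ndarray] = []
    for gs in catalog:
        members = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if len(members) < min_set_size:
            logger.info("dropping set %s: %d measured genes < %d", gs.name, len(members), min_set_size)
            continue
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[members] = True
        ind_ord = in_set[order]  # (G, S) membership in ranked order
        hit_w = np.where(ind_ord, weight_ord, 0.0)
        hit_tot = hit_w.sum(axis=0)
        hit_tot = np.where(hit_tot > 0, hit_tot, 1.0)
        cum_hit = np.cumsum(hit_w, axis=0) / hit_tot
        n_out = n_genes - len(members)
        cum_miss = np.cumsum(~ind_ord, axis=0) / (n_out if n_out else 1)
        d = cum_hit - cum_miss
        es = np.maximum(d, 0.0).max(axis=0) + np.minimum(d, 0.0).min(axis=0)
        kept.append(gs.name)
        rows.append(es)
    if not kept:
        raise ValidationError("all gene sets were dropped (too few measured genes)")
    return pd.DataFrame(np.vstack(rows), index=kept, columns=expr.values.columns)


def paired_pathway_de(scores: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Paired TP2 - TP1 t-test per pathway on sample-wise scores.

    The ``log2fc`` column carries the mean paired score difference.
    """
    pairs = paired_subjects(meta)
    missing = [
        r.subject_id for r in pairs.itertuples()
        if r.tp1 not in scores.columns or r.tp2 not in scores.columns
    ]
    if missing:
        raise ValidationError(f"subjects without score columns: {missing}")
    diffs = (
        scores[pairs["tp2"].tolist()].to_numpy() - scores[pairs["tp1"].tolist()].to_numpy()
    )
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    pvalue = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0
    t[zero_var] = 0.0
    exact_shift = zero_var & (mean != 0)
    t[exact_shift] = np.sign(mean[exact_shift]) * np.inf
    pvalue = np.where(zero_var, np.where(mean == 0, 1.0, 0.0), pvalue)
    return make_de_table(list(scores.index), mean, t, pvalue)


def pathway_activity_compare(
    de_acd: pd.DataFrame,
    de_control: pd.DataFrame,
    catalog: GeneSetCatalog,
    pa_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Cohort pathway-activation records from two gene-level DE tables.

    PA_cohort is the mean log2FC over the set's measured genes; the
    between-cohort p-value is a Welch t-test on the two per-gene log2FC
    samples of the set. Records are sorted by |PA_acd| + |PA_control|
    descending, with the activity/significance filter flag attached.
    """
    lfc_a = de_acd.set_index("feature_id")["log2fc"]
    lfc_c = de_control.set_index("feature_id")["log2fc"]
    shared = lfc_a.index.intersection(lfc_c.index)
    rows = []
    for gs in catalog:
        members = [g for g in gs.genes if g in shared]
        if not members:
            logger.info("dropping set %s: empty after intersection", gs.name)
            continue
        fa = lfc_a.loc[members].to_numpy()
        fc = lfc_c.loc[members].to_numpy()
        pa_acd = float(fa.mean())
        pa_control = float(fc.mean())
        if len(members) >= 2 and (np.ptp(fa) > 0 or np.ptp(fc) > 0):
            _, p = stats.ttest_ind(fa, fc, equal_var=False)
            p = float(p)
        else:
            p = math.nan
        rows.append(
            {
                "set_name": gs.name,
                "n_genes": len(members),
                "pa_acd": pa_acd,
                "pa_control": pa_control,
                "pa_sum_abs": abs(pa_acd) + abs(pa_control),
                "pvalue": p,
            }
        )
    records = pd.DataFrame(rows)
    if len(records):
        records["passes_filter"] = (records["pa_sum_abs"] > pa_threshold) & (
            records["pvalue"] < p_threshold
        )
        records = records.sort_values("pa_sum_abs", ascending=False).reset_index(drop=True)
    else:
        warnings.warn("no pathway records after intersection", stacklevel=2)
        records = pd.DataFrame(
            columns=["set_name", "n_genes", "pa_acd", "pa_control", "pa_sum_abs", "pvalue", "passes_filter"]
        )
    return records


def filter_differential_activation(
    records: pd.DataFrame,
    pa_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Strict activity filter: |PA_acd| + |PA_control| > pa_threshold and
    p < p_threshold. Boundary records (==) are excluded."""
    if len(records) == 0:
        return records.copy()
    records = records.copy()
    records["passes_filter"] = (records["pa_sum_abs"] > pa_threshold) & (
        records["pvalue"] < p_threshold
    )
    return records[records["passes_filter"]].reset_index(drop=True)
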