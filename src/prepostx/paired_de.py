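"""Paired pre/post differential expression on RNA-seq counts.

The model is a per-gene negative binomial GLM with log link,

    log mu_ij = log s_j + subject_i + beta * 1[timepoint(j) = TP2],

fitted by iteratively reweighted least squares with the dispersion held
fixed at a plug-in estimate. Subject indicator covariates absorb
patient-to-patient baseline differences, so the timepoint coefficient is
the within-subject (paired) log fold change. The Wald statistic
beta / SE(beta) is referred to the standard normal and BH-adjusted across
tested genes.

Normalization uses median-of-ratios size factors; dispersions come from a
method-of-moments estimator on normalized counts with a residual-df
correction for the paired design, optionally shrunk toward a fitted
mean-dispersion trend (on by default -- the gene-wise estimator is noisy at
paired-cohort sample sizes and shrinkage is what keeps the Wald test
calibrated; see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    CountMatrix,
    ValidationError,
    bh_adjust,
    make_de_table,
    paired_subjects,
    spearman_rho,
)

_MIN_DISPERSION = 1e-8


@dataclass
class DEConfig:
    min_total_count: int = 10
    min_samples_expressed: int = 3
    alpha_nominal: float = 0.05
    alpha_fdr: float = 0.05
    heatmap_p: float = 0.005
    heatmap_lfc: float = 0.5
    shrink_dispersion_trend: bool = True
    max_iter: int = 100
    deviance_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.min_total_count < 0 or self.min_samples_expressed < 0:
            raise ValidationError("filter thresholds must be >= 0")
        for name in ("alpha_nominal", "alpha_fdr", "heatmap_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def size_factors(counts: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean across samples; each
    sample's factor is the median ratio of its counts to the reference over
    genes with an all-positive row. With ``pseudo_reference=True`` the
    geometric mean is taken over positive counts only, rescuing datasets
    where no gene is expressed in every sample.
    """
    y = counts.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(y)
    if pseudo_reference:
        pos = y > 0
        usable = pos.sum(axis=1) > 0
        log_geo = np.full(y.shape[0], -np.inf)
        log_geo[usable] = np.where(pos, logs, 0.0)[usable].sum(axis=1) / pos[usable].sum(axis=1)
    else:
        usable = (y > 0).all(axis=1)
        if not usable.any():
            raise ValidationError(
                "no gene has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        log_geo = logs.mean(axis=1)
    ratios = logs[usable] - log_geo[usable, None]
    factors = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=0))
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ValidationError("size factor estimation failed (zero/invalid median ratio)")
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def filter_low_expression(counts: CountMatrix, config: DEConfig) -> CountMatrix:
    """Drop genes with total count below ``min_total_count`` or expressed
    (count > 0) in fewer than ``min_samples_expressed`` samples."""
    df = counts.counts
    keep = (df.sum(axis=1) >= config.min_total_count) & (
        (df > 0).sum(axis=1) >= config.min_samples_expressed
    )
    if not keep.any():
        raise ValidationError("low-expression filter removed all genes")
    n_removed = int((~keep).sum())
    if n_removed:
        warnings.warn(f"filter_low_expression removed {n_removed} genes", stacklevel=2)
    return CountMatrix(df.loc[keep])


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _paired_design_matrix(meta: pd.DataFrame, sample_ids: list[str]) -> tuple[np.ndarray, int]:
    """Design matrix (intercept + subject indicators + TP2 indicator) aligned
    to ``sample_ids``; returns (X, index of the timepoint column)."""
    meta = meta.set_index("sample_id").loc[sample_ids]
    subjects = sorted(meta["subject_id"].unique())
    n = len(sample_ids)
    p = len(subjects) + 1
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for k, subj in enumerate(subjects[1:], start=1):
        X[:, k] = (meta["subject_id"] == subj).to_numpy(dtype=float)
    X[:, -1] = (meta["timepoint"] == "TP2").to_numpy(dtype=float)
    return X, p - 1


def estimate_dispersions(
    counts: CountMatrix,
    sf: pd.Series,
    meta: pd.DataFrame,
    shrink_trend: bool = True,
) -> pd.Series:
    """Gene-wise method-of-moments NB dispersion on normalized counts.

    Residual variance is taken about the least-squares fit of the paired
    design (subject + timepoint), with an n/(n - p) degrees-of-freedom
    correction, and the Poisson component mean(1/s_j)*qbar is subtracted:

        alpha = (s2_resid - qbar * mean(1/s)) / qbar^2 ,  floored at 1e-8.

    With ``shrink_trend`` the estimates are replaced by the fitted trend
    a0 + a1/qbar (least squares over genes, both coefficients clamped >= 0),
    blended 50:50 with the gene-wise value on the log scale.
    """
    y = counts.counts.to_numpy(dtype=float)
    s = sf.loc[counts.sample_ids].to_numpy()
    q = y / s
    X, _ = _paired_design_matrix(meta, counts.sample_ids)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"{n} samples cannot identify {p} design parameters")
    # residuals about the paired-design LS fit, all genes at once
    beta_hat, *_ = np.linalg.lstsq(X, q.T, rcond=None)
    resid = q - (X @ beta_hat).T
    s2 = (resid**2).sum(axis=1) / (n - p)
    qbar = q.mean(axis=1)
    xi = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gw = (s2 - xi * qbar) / qbar**2
    degenerate = ~np.isfinite(alpha_gw)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate genes floored in dispersion estimation",
            stacklevel=2,
        )
    alpha_gw = np.where(np.isfinite(alpha_gw), alpha_gw, _MIN_DISPERSION)
    alpha_gw = np.maximum(alpha_gw, _MIN_DISPERSION)
    if shrink_trend and len(alpha_gw) >= 10:
        # fit alpha = a0 + a1/qbar on genes with informative estimates
        use = alpha_gw > 10 * _MIN_DISPERSION
        if use.sum() >= 10:
            A = np.column_stack([np.ones(use.sum()), 1.0 / qbar[use]])
            coef, *_ = np.linalg.lstsq(A, alpha_gw[use], rcond=None)
            a0, a1 = np.maximum(coef, 0.0)
            trend = np.maximum(a0 + a1 / qbar, _MIN_DISPERSION)
            alpha_gw = np.exp(0.5 * (np.log(alpha_gw) + np.log(trend)))
    return pd.Series(alpha_gw, index=counts.gene_ids, name="dispersion")


# ---------------------------------------------------------------------------
# NB GLM, batched IRLS
# ---------------------------------------------------------------------------


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial deviance per gene (rows), alpha fixed per gene."""
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-link GLMs for all genes at once (shared design matrix).

    Returns (coefficients genes x p, covariance diagonal for the last
    column, converged mask).
    """
    n_genes, n = y.shape
    p = X.shape[1]
    eta = np.log(np.maximum(y, 0.5))  # linear predictor incl. offset
    beta = np.zeros((n_genes, p))
    dev = np.full(n_genes, np.inf)
    active = np.ones(n_genes, dtype=bool)
    converged = np.zeros(n_genes, dtype=bool)
    A_last = np.zeros((n_genes, p, p))
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        eta_a = np.clip(eta[idx], -30.0, 30.0)
        mu = np.exp(eta_a)
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + alpha[idx, None] * mu)
        z = (eta_a - offset[None, :]) + (y[idx] - mu) / mu
        Xw = X[None, :, :] * w[:, :, None]
        A = np.einsum("gnp,nq->gpq", Xw, X)
        b = np.einsum("gnp,gn->gp", Xw, z)
        A_reg = A + 1e-10 * np.eye(p)[None, :, :]
        try:
            beta_new = np.linalg.solve(A_reg, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack(
                [np.linalg.lstsq(A_reg[g], b[g], rcond=None)[0] for g in range(len(idx))]
            )
        eta_new = beta_new @ X.T + offset[None, :]
        mu_new = np.exp(np.clip(eta_new, -30.0, 30.0))
        dev_new = _nb_deviance(y[idx], np.maximum(mu_new, 1e-10), alpha[idx])
        beta[idx] = beta_new
        eta[idx] = eta_new
        A_last[idx] = A
        done = np.abs(dev[idx] - dev_new) < tol * (np.abs(dev_new) + 0.1)
        dev[idx] = dev_new
        converged[idx[done]] = True
        active[idx[done]] = False
    # recompute information at the final coefficients for SEs
    eta_f = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu_f = np.maximum(np.exp(eta_f), 1e-10)
    w_f = mu_f / (1.0 + alpha[:, None] * mu_f)
    Xw = X[None, :, :] * w_f[:, :, None]
    A_f = np.einsum("gnp,nq->gpq", Xw, X) + 1e-10 * np.eye(p)[None, :, :]
    cov_last = np.linalg.inv(A_f)[:, -1, -1]
    return beta, cov_last, converged


def paired_nb_wald(
    counts: CountMatrix,
    meta: pd.DataFrame,
    config: DEConfig | None = None,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Paired TP1-vs-TP2 NB Wald test for a single cohort.

    Returns a DE table with columns feature_id, log2fc, stat, pvalue, fdr,
    direction, baseMean, converged. Non-convergent genes carry NaN p-values
    and are excluded from the BH adjustment.
    """
    config = config or DEConfig()
    pairs = paired_subjects(meta)
    cohorts = set(pairs["cohort"])
    if len(cohorts) != 1:
        raise ValidationError(f"paired_nb_wald expects a single cohort, got {sorted(cohorts)}")
    used = meta[meta["sample_id"].isin(counts.sample_ids)]
    if len(used) != len(counts.sample_ids):
        raise ValidationError("metadata does not cover all count columns")
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(
            counts, sf, meta, shrink_trend=config.shrink_dispersion_trend
        )
    y = counts.counts.to_numpy(dtype=float)
    s = sf.loc[counts.sample_ids].to_numpy()
    X, tp_col = _paired_design_matrix(meta, counts.sample_ids)
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("fewer samples than design parameters")
    alpha = dispersions.loc[counts.gene_ids].to_numpy()
    offset = np.log(s)
    beta, var_tp, converged = _irls_nb(
        y, X, offset, alpha, config.max_iter, config.deviance_tol
    )
    coef = beta[:, tp_col]  # timepoint coefficient (last design column)
    se = np.sqrt(np.maximum(var_tp, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, 0.0)
    # reference the Wald statistic to t with residual df: at paired-cohort
    # sample sizes (n - p around 15) the normal tail is visibly anti-
    # conservative; see docs/methods.md
    df_resid = X.shape[0] - X.shape[1]
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    pvalue = np.where(converged, pvalue, np.nan)
    log2fc = coef / math.log(2.0)
    base_mean = (y / s).mean(axis=1)
    n_bad = int((~converged).sum())
    if n_bad:
        warnings.warn(f"{n_bad} genes did not converge; flagged with NaN p", stacklevel=2)
    return make_de_table(
        counts.gene_ids,
        log2fc,
        z,
        pvalue,
        extra={"baseMean": base_mean, "converged": converged},
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class DEGSummary:
    n_deg: int
    n_up: int
    n_down: int
    n_null_fc: int
    up_down_ratio: float
    n_fdr_significant: int
    biotype_table: pd.DataFrame | None = None


def summarize_degs(
    de: pd.DataFrame,
    annotation: pd.Series | None = None,
    config: DEConfig | None = None,
) -> DEGSummary:
    """Two-tier DEG summary: nominal DEGs (raw p < alpha_nominal) split by
    direction, FDR-significant genes counted separately, and an optional
    per-biotype tabulation (genes without annotation fall in "No data")."""
    config = config or DEConfig()
    degs = de[de["pvalue"] < config.alpha_nominal]
    n_up = int((degs["log2fc"] > 0).sum())
    n_down = int((degs["log2fc"] < 0).sum())
    n_null = int((degs["log2fc"] == 0).sum())
    if n_down > 0:
        ratio = round(n_up / n_down, 2)
    else:
        ratio = math.nan
        if len(degs) == 0:
            warnings.warn("empty DEG set; up/down ratio undefined", stacklevel=2)
    n_fdr = int((de["fdr"] < config.alpha_fdr).sum())
    biotype_table = None
    if annotation is not None:
        biotype = degs["feature_id"].map(annotation).fillna("No data")
        rows = []
        for bt, grp in degs.groupby(biotype.values):
            rows.append(
                {
                    "biotype": bt,
                    "n": len(grp),
                    "n_UR": int((grp["log2fc"] > 0).sum()),
                    "n_DR": int((grp["log2fc"] < 0).sum()),
                }
            )
        biotype_table = pd.DataFrame(rows).sort_values("biotype").reset_index(drop=True)
    return DEGSummary(
        n_deg=len(degs),
        n_up=n_up,
        n_down=n_down,
        n_null_fc=n_null,
        up_down_ratio=ratio,
        n_fdr_significant=n_fdr,
        biotype_table=biotype_table,
    )


def deg_count_ratio(summary_a: DEGSummary, summary_b: DEGSummary) -> float:
    """Ratio of nominal DEG counts between two cohorts, one decimal."""
    if summary_b.n_deg == 0:
        return math.nan
    return round(summary_a.n_deg / summary_b.n_deg, 1)


@dataclass
class FCDensityReport:
    median_a: float
    median_b: float
    n_shared: int
    rho_overall: float
    p_overall: float
    n_same_sign: int
    rho_same_sign: float
    n_opposite_sign: int
    rho_opposite_sign: float
    pct_same_sign: float


def log2fc_density_summary(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    config: DEConfig | None = None,
) -> FCDensityReport:
    """Median DEG log2FC per table plus shared-DEG correlation structure.

    Shared DEGs are features nominally significant in both tables; they are
    split by log2FC sign agreement and Spearman correlations are reported
    overall and within each sign class (subsets below 3 members get NaN rho).
    """
    config = config or DEConfig()
    deg_a = de_a[de_a["pvalue"] < config.alpha_nominal].set_index("feature_id")
    deg_b = de_b[de_b["pvalue"] < config.alpha_nominal].set_index("feature_id")
    shared = deg_a.index.intersection(deg_b.index)
    med_a = float(deg_a["log2fc"].median()) if len(deg_a) else math.nan
    med_b = float(deg_b["log2fc"].median()) if len(deg_b) else math.nan
    if len(shared) == 0:
        warnings.warn("no shared DEGs between the two tables", stacklevel=2)
        return FCDensityReport(med_a, med_b, 0, math.nan, math.nan, 0, math.nan, 0, math.nan, math.nan)
    fa = deg_a.loc[shared, "log2fc"].to_numpy()
    fb = deg_b.loc[shared, "log2fc"].to_numpy()

    def _rho(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) < 3:
            return math.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return spearman_rho(x, y)[0]

    rho_all, p_all = (
        spearman_rho(fa, fb) if len(shared) >= 3 else (math.nan, math.nan)
    )
    same = np.sign(fa) * np.sign(fb) > 0
    opposite = np.sign(fa) * np.sign(fb) < 0
    n_same, n_opp = int(same.sum()), int(opposite.sum())
    pct_same = 100.0 * n_same / (n_same + n_opp) if (n_same + n_opp) else math.nan
    return FCDensityReport(
        median_a=med_a,
        median_b=med_b,
        n_shared=len(shared),
        rho_overall=rho_all,
        p_overall=p_all,
        n_same_sign=n_same,
        rho_same_sign=_rho(fa[same], fb[same]),
        n_opposite_sign=n_opp,
        rho_opposite_sign=_rho(fa[opposite], fb[opposite]),
        pct_same_sign=pct_same,
    )
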