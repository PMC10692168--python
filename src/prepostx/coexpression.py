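"""Signed weighted gene co-expression network analysis.

Workflow: remove subject effects from paired log expression, keep the most
variable genes, choose a soft-threshold power beta for the signed adjacency
a_ij = ((1 + cor_ij) / 2) ** beta by the scale-free fit criterion, build the
topological overlap matrix (TOM), cluster 1 - TOM by average linkage with a
static tree cut, and summarize modules by their eigengenes. Modules are
named after their hub gene (highest intramodular connectivity); genes in
clusters below the minimum size are labeled "unassigned".

Module-trait statistics use Pearson correlation of eigengenes with a
per-sample trait encoding (TP2 indicator for the music stimulus), with BH
FDR across modules. Module membership (MM) is the correlation of each gene
with each eigengene; the MM-trait link correlates, within a module, gene MM
with the gene's own trait correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import ExprMatrix, GeneSetCatalog, ValidationError, bh_adjust, pearson_with_p

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionParams:
    top_variance_fraction: float = 0.75
    beta_grid: tuple[int, ...] = tuple(range(1, 21))
    scalefree_r2_target: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.99      # fraction of the merge-height range
    kme_min: float = 0.5          # prune members with |eigengene correlation| below this
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.top_variance_fraction <= 1.0:
            raise ValidationError("top_variance_fraction must be in (0, 1]")
        if any(b < 1 for b in self.beta_grid):
            raise ValidationError("soft powers must be >= 1")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValidationError("cut_height must be in (0, 1]")


def remove_subject_effect(expr: ExprMatrix, meta: pd.DataFrame) -> ExprMatrix:
    """Subtract each subject's mean across its samples, per gene."""
    lookup = meta.set_index("sample_id")["subject_id"]
    missing = [s for s in expr.sample_ids if s not in lookup.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    values = expr.values.to_numpy(dtype=float).copy()
    subjects = lookup.loc[expr.sample_ids].to_numpy()
    singletons = []
    for subj in np.unique(subjects):
        cols = subjects == subj
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
        if cols.sum() == 1:
            singletons.append(subj)
    if singletons:
        warnings.warn(
            f"subjects with a single sample zeroed by subject centering: {singletons}",
            stacklevel=2,
        )
    return ExprMatrix(pd.DataFrame(values, index=expr.values.index, columns=expr.values.columns))


def variance_filter(expr: ExprMatrix, fraction: float = 0.75) -> ExprMatrix:
    """Keep the ceil(fraction * n_genes) genes with highest sample variance;
    ties broken by lexicographically smaller gene id first."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    var = expr.values.var(axis=1, ddof=1)
    k = math.ceil(fraction * len(var))
    ranking = sorted(var.index, key=lambda g: (-var[g], g))
    keep = sorted(ranking[:k], key=list(expr.values.index).index)
    return ExprMatrix(expr.values.loc[keep])


def signed_adjacency(values: np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency ((1 + cor) / 2) ** beta with unit diagonal."""
    cor = np.corrcoef(values)
    cor = np.clip(np.nan_to_num(cor, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return ((1.0 + cor) / 2.0) ** beta


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 (and slope) of log10 p(k) vs log10 k over connectivity bins."""
    k = k[np.isfinite(k) & (k > 0)]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2), float(slope)


@dataclass
class SoftThresholdResult:
    beta: int
    diagnostics: pd.DataFrame
    reached_target: bool


def pick_soft_threshold(
    expr: ExprMatrix, params: CoexpressionParams | None = None
) -> SoftThresholdResult:
    """Smallest power whose scale-free fit (with negative slope) reaches the
    R^2 target, else the argmax R^2 with a warning."""
    params = params or CoexpressionParams()
    if expr.values.shape[1] < 3:
        raise ValidationError("need >= 3 samples to estimate correlations")
    values = expr.values.to_numpy(dtype=float)
    cor = np.corrcoef(values)
    cor = np.clip(np.nan_to_num(cor, nan=0.0), -1.0, 1.0)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)  # exclude self-connectivity
    rows = []
    for beta in params.beta_grid:
        k = (base**beta).sum(axis=1)
        r2, slope = _scale_free_r2(k)
        signed_r2 = r2 if slope < 0 else 0.0
        rows.append(
            {"beta": beta, "r2": signed_r2, "slope": slope, "mean_connectivity": float(k.mean())}
        )
    diag = pd.DataFrame(rows)
    ok = diag[diag["r2"] >= params.scalefree_r2_target]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
        reached = True
    else:
        beta = int(diag.loc[diag["r2"].idxmax(), "beta"])
        reached = False
        warnings.warn(
            f"scale-free R2 target {params.scalefree_r2_target} not reached; "
            f"using beta={beta} (max R2 = {diag['r2'].max():.2f})",
            stacklevel=2,
        )
    return SoftThresholdResult(beta=beta, diagnostics=diag, reached_target=reached)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix from a (signed) adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), l_ij = sum_u a_iu a_uj
    over u != i, j; diagonal set to 1.
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    k_min = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (k_min + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleAssignment:
    labels: pd.Series                      # gene -> module name (hub gene) or UNASSIGNED
    hub_genes: dict[str, str] = field(default_factory=dict)
    eigengenes: pd.DataFrame | None = None  # module x sample
    module_trait: pd.DataFrame | None = None
    module_membership: pd.DataFrame | None = None
    mm_trait_link: pd.DataFrame | None = None

    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]

    def genes_of(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    expr: ExprMatrix,
    beta: int,
    params: CoexpressionParams | None = None,
) -> ModuleAssignment:
    """TOM-based average-linkage clustering with a static tree cut.

    The tree is cut at ``cut_height`` of the merge-height range; clusters
    smaller than ``min_module_size`` become unassigned, and cluster members
    whose correlation with the cluster eigengene falls below ``kme_min`` are
    pruned back to unassigned (weakly attached genes otherwise get absorbed
    by the generous static cut). Each module is named after its hub gene,
    the member with the highest intramodular connectivity.
    """
    params = params or CoexpressionParams()
    genes = list(expr.values.index)
    values = expr.values.to_numpy(dtype=float)
    adjacency = signed_adjacency(values, beta)
    tom = tom_similarity(adjacency)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    heights = Z[:, 2]
    cut = heights.min() + params.cut_height * (heights.max() - heights.min())
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    hubs: dict[str, str] = {}
    a0 = adjacency.copy()
    np.fill_diagonal(a0, 0.0)
    for cluster_id in np.unique(raw):
        members = np.flatnonzero(raw == cluster_id)
        if len(members) < params.min_module_size:
            continue
        members = _prune_by_kme(values, members, params.kme_min)
        if len(members) < params.min_module_size:
            continue
        intra = a0[np.ix_(members, members)].sum(axis=1)
        hub = genes[members[int(np.argmax(intra))]]
        labels.iloc[members] = hub
        hubs[hub] = hub
    if not hubs:
        warnings.warn("no module reached min_module_size; all genes unassigned", stacklevel=2)
    return ModuleAssignment(labels=labels, hub_genes=hubs)


def _prune_by_kme(values: np.ndarray, members: np.ndarray, kme_min: float) -> np.ndarray:
    """Drop cluster members weakly correlated with the cluster eigengene."""
    if kme_min <= 0 or len(members) < 3:
        return members
    sub = values[members]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    standardized = (sub - mean) / sd
    eig = np.linalg.svd(standardized, full_matrices=False)[2][0]
    e = eig - eig.mean()
    en = np.linalg.norm(e)
    if en == 0:
        return members
    kme = (standardized @ e) / (np.linalg.norm(standardized, axis=1) * en + 1e-300)
    return members[np.abs(kme) >= kme_min]


def module_eigengenes(expr: ExprMatrix, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-variance across samples and sign-oriented so that
    the mean gene-eigengene correlation is non-negative.
    """
    samples = expr.values.columns
    rows = {}
    for module in assignment.modules():
        member_expr = expr.values.loc[assignment.genes_of(module)].to_numpy(dtype=float)
        mean = member_expr.mean(axis=1, keepdims=True)
        sd = member_expr.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        standardized = (member_expr - mean) / sd
        U, S, Vt = np.linalg.svd(standardized, full_matrices=False)
        eig = Vt[0]
        if np.mean(standardized @ eig) < 0:  # orient toward the member genes
            eig = -eig
        sd_e = eig.std(ddof=1)
        rows[module] = eig / (sd_e if sd_e > 0 else 1.0)
    eigengenes = pd.DataFrame(rows, index=samples).T
    assignment.eigengenes = eigengenes
    return eigengenes


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    trait: pd.Series,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson R of each eigengene with the trait, t-approximation p, BH FDR."""
    if len(trait) != eigengenes.shape[1]:
        raise ValidationError("trait length must equal sample count")
    t = trait.loc[eigengenes.columns].to_numpy(dtype=float)
    rows = []
    for module in eigengenes.index:
        r, p = pearson_with_p(eigengenes.loc[module].to_numpy(), t)
        rows.append({"module": module, "R": r, "pvalue": p, "degenerate": not np.isfinite(r)})
    out = pd.DataFrame(rows)
    ok = out["pvalue"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "pvalue"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def module_membership(expr: ExprMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Correlation of each gene's profile with each module eigengene."""
    values = expr.values.to_numpy(dtype=float)
    vc = values - values.mean(axis=1, keepdims=True)
    vs = np.sqrt((vc**2).sum(axis=1))
    eg = eigengenes.to_numpy(dtype=float)
    ec = eg - eg.mean(axis=1, keepdims=True)
    es = np.sqrt((ec**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        mm = (vc @ ec.T) / np.outer(vs, es)
    mm = np.clip(np.nan_to_num(mm, nan=0.0), -1.0, 1.0)
    return pd.DataFrame(mm, index=expr.values.index, columns=eigengenes.index)


def gene_trait_correlation(expr: ExprMatrix, trait: pd.Series) -> pd.Series:
    """Per-gene Pearson correlation with the trait encoding."""
    t = trait.loc[expr.values.columns].to_numpy(dtype=float)
    values = expr.values.to_numpy(dtype=float)
    vc = values - values.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc @ tc) / denom
    return pd.Series(np.clip(np.nan_to_num(r, nan=0.0), -1, 1), index=expr.values.index)


def mm_trait_link(
    mm: pd.DataFrame,
    gene_trait_cor: pd.Series,
    assignment: ModuleAssignment,
) -> pd.DataFrame:
    """Per module: correlation across member genes of MM vs gene-trait R."""
    rows = []
    for module in assignment.modules():
        genes = assignment.genes_of(module)
        if len(genes) < 3:
            rows.append({"module": module, "n_genes": len(genes), "R": math.nan, "pvalue": math.nan})
            continue
        r, p = pearson_with_p(
            mm.loc[genes, module].to_numpy(), gene_trait_cor.loc[genes].to_numpy()
        )
        rows.append({"module": module, "n_genes": len(genes), "R": r, "pvalue": p})
    return pd.DataFrame(rows)


def module_enrichment(
    assignment: ModuleAssignment,
    catalog: GeneSetCatalog,
    background: list[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of catalog sets in each module,
    BH-adjusted across all module x set tests."""
    background = background or list(assignment.labels.index)
    bg = set(background)
    M = len(bg)
    rows = []
    for module in assignment.modules():
        members = set(assignment.genes_of(module)) & bg
        for gs in catalog:
            set_genes = set(gs.genes) & bg
            k = len(members & set_genes)
            if not set_genes:
                continue
            p = stats.hypergeom.sf(k - 1, M, len(set_genes), len(members))
            rows.append(
                {
                    "module": module,
                    "set_name": gs.name,
                    "n_overlap": k,
                    "n_set": len(set_genes),
                    "n_module": len(members),
                    "pvalue": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out
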