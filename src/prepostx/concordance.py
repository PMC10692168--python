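"""Cross-contrast concordance: does the music response oppose the disease signature?

Two differential-expression tables (the music contrast A and a disease
case-control contrast B) are joined on feature id, restricted to features
FDR-significant in the disease contrast, and each feature is classified by
log2FC sign agreement: concordant (same sign), discordant (opposite sign)
or null (either log2FC exactly 0; excluded from percentages). Spearman
correlations of the paired log2FC vectors are reported overall and within
each sign class. A strongly negative overall rho with a high discordant
percentage is the "compensatory" signature.

The same operations apply unchanged to pathway-level tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ValidationError, spearman_rho


def overlap_features(de_music: pd.DataFrame, de_disease: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two DE tables on feature_id with _music/_disease suffixes."""
    a = de_music.set_index("feature_id")[["log2fc", "pvalue", "fdr"]].add_suffix("_music")
    b = de_disease.set_index("feature_id")[["log2fc", "pvalue", "fdr"]].add_suffix("_disease")
    pairs = a.join(b, how="inner")
    if len(pairs) == 0:
        raise ValidationError("no overlapping features between the two contrasts")
    return pairs.rename_axis("feature_id").reset_index()


def select_fdr_features(
    pairs: pd.DataFrame, which: str = "disease", alpha: float = 0.05
) -> pd.DataFrame:
    """Subset pairs by FDR < alpha in the designated contrast
    (``disease`` (default), ``music`` or ``either``)."""
    if which == "disease":
        keep = pairs["fdr_disease"] < alpha
    elif which == "music":
        keep = pairs["fdr_music"] < alpha
    elif which == "either":
        keep = (pairs["fdr_disease"] < alpha) | (pairs["fdr_music"] < alpha)
    else:
        raise ValidationError(f"unknown selection {which!r}")
    out = pairs[keep.fillna(False)].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("no FDR-significant features selected", stacklevel=2)
    return out


def classify_quadrants(pairs: pd.DataFrame) -> pd.DataFrame:
    """Label each pair concordant / discordant / null by log2FC sign product."""
    prod = np.sign(pairs["log2fc_music"].to_numpy()) * np.sign(
        pairs["log2fc_disease"].to_numpy()
    )
    labeled = pairs.copy()
    labeled["quadrant"] = np.where(prod > 0, "concordant", np.where(prod < 0, "discordant", "null"))
    return labeled


@dataclass
class ConcordanceResult:
    n_overlap: int
    n_fdr: int
    pairs: pd.DataFrame
    n_concordant: int
    n_discordant: int
    n_null: int
    pct_concordant: float
    pct_discordant: float
    rho_overall: float
    p_overall: float
    rho_concordant: float
    rho_discordant: float


def concordance_correlations(
    labeled: pd.DataFrame, n_overlap: int | None = None
) -> ConcordanceResult:
    """Quadrant counts, percentages and Spearman correlations.

    Percentages are over classified (non-null) pairs. Subsets with fewer
    than 3 members get NaN rho, flagged by a warning.
    """
    n_con = int((labeled["quadrant"] == "concordant").sum())
    n_dis = int((labeled["quadrant"] == "discordant").sum())
    n_null = int((labeled["quadrant"] == "null").sum())
    denom = n_con + n_dis
    pct_con = 100.0 * n_con / denom if denom else math.nan
    pct_dis = 100.0 * n_dis / denom if denom else math.nan

    def _rho(df: pd.DataFrame) -> tuple[float, float]:
        if len(df) < 3:
            if len(df):
                warnings.warn("subset smaller than 3; rho undefined", stacklevel=3)
            return (math.nan, math.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return spearman_rho(
                df["log2fc_music"].to_numpy(), df["log2fc_disease"].to_numpy()
            )

    rho_all, p_all = _rho(labeled)
    rho_con, _ = _rho(labeled[labeled["quadrant"] == "concordant"])
    rho_dis, _ = _rho(labeled[labeled["quadrant"] == "discordant"])
    return ConcordanceResult(
        n_overlap=n_overlap if n_overlap is not None else len(labeled),
        n_fdr=len(labeled),
        pairs=labeled,
        n_concordant=n_con,
        n_discordant=n_dis,
        n_null=n_null,
        pct_concordant=pct_con,
        pct_discordant=pct_dis,
        rho_overall=rho_all,
        p_overall=p_all,
        rho_concordant=rho_con,
        rho_discordant=rho_dis,
    )


def run_concordance(
    de_music: pd.DataFrame,
    de_disease: pd.DataFrame,
    which: str = "disease",
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Overlap -> FDR subset -> quadrants -> correlations, in one call."""
    pairs = overlap_features(de_music, de_disease)
    selected = select_fdr_features(pairs, which=which, alpha=alpha)
    labeled = classify_quadrants(selected)
    return concordance_correlations(labeled, n_overlap=len(pairs))


@dataclass
class ContrastOverlapReport:
    n_intersection: int
    rho_disease: float
    p_disease: float
    features: list[str]


def compare_disease_contrasts(
    result_a: ConcordanceResult, result_b: ConcordanceResult
) -> ContrastOverlapReport:
    """Intersect two contrasts' FDR feature sets and correlate their
    disease-contrast log2FC across the intersection."""
    a = result_a.pairs.set_index("feature_id")
    b = result_b.pairs.set_index("feature_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        warnings.warn("disease contrasts share no FDR features", stacklevel=2)
        return ContrastOverlapReport(0, math.nan, math.nan, [])
    if len(shared) >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearman_rho(
                a.loc[shared, "log2fc_disease"].to_numpy(),
                b.loc[shared, "log2fc_disease"].to_numpy(),
            )
    else:
        rho, p = math.nan, math.nan
    return ContrastOverlapReport(len(shared), rho, p, list(shared))


def summarize_concordance(result: ConcordanceResult) -> pd.DataFrame:
    """One-row TSV-ready summary of a ConcordanceResult."""
    return pd.DataFrame(
        [
            {
                "n_overlap": result.n_overlap,
                "n_fdr": result.n_fdr,
                "n_concordant": result.n_concordant,
                "n_discordant": result.n_discordant,
                "n_null": result.n_null,
                "pct_concordant": result.pct_concordant,
                "pct_discordant": result.pct_discordant,
                "rho_overall": result.rho_overall,
                "p_overall": result.p_overall,
                "rho_concordant": result.rho_concordant,
                "rho_discordant": result.rho_discordant,
            }
        ]
    )
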