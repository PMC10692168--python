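"""Synthetic study generator with known ground truth.

Emulates the three data layers the analysis pipeline consumes:

1. paired pre/post (TP1/TP2) RNA-seq counts for a patient cohort (ACD) and a
   healthy control cohort, with subject random effects on the log scale and
   cohort-specific music effect sizes;
2. a Gaussian log-intensity case-control cohort (microarray-like) whose
   disease effects are anti-correlated with the patient cohort's music
   effects -- the "compensation" design;
3. a gene-set catalog in which a fraction of sets is loaded with affected
   genes of coherent effect sign.

Counts are negative binomial with var = mu + alpha * mu^2 and a dispersion
trend alpha(mu) = a0 + a1/mu that decreases with abundance, the standard
bulk RNA-seq mean-variance behaviour. Music effects have fixed magnitude
sigma_beta (times amplitude_ratio in the patient cohort) and random sign,
so the per-gene effect SD equals sigma_beta while keeping per-cohort
detection power analytically transparent.

The case-control disease effect of a music-responsive gene g is

    delta_cc(g) = -kappa * beta_acd(g) + Normal(0, sigma_noise_cc),

giving a design (Pearson) correlation between delta_cc and beta_acd of
-kappa*sb / sqrt(kappa^2 sb^2 + sigma_noise_cc^2) with sb the patient-cohort
effect SD. The defaults are tuned by this closed form to a design
correlation of -0.75. Non-responsive genes have delta_cc = 0.

Every output is a deterministic function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CountMatrix,
    ExprMatrix,
    GeneSetCatalog,
    ValidationError,
    validate_sample_table,
    write_count_matrix,
    write_expr_matrix,
    write_gmt,
    write_sample_table,
)


@dataclass
class SimParams:
    """Generator parameters; defaults define the study conditions."""

    n_genes: int = 4000
    n_subjects_acd: int = 16
    n_subjects_control: int = 14
    pi_de: float = 0.2                 # fraction of music-responsive genes
    sigma_beta: float = 0.15           # SD of control-cohort music effect (log2)
    amplitude_ratio: float = 2.3       # ACD effect SD / control effect SD
    sigma_subject: float = 0.3         # subject random effect SD (log2)
    mu_log_mean: float = 5.0           # baseline abundance: ln-mean of lognormal
    sigma_log_mean: float = 1.5        # baseline abundance: ln-SD
    dispersion_a0: float = 0.05        # alpha(mu) = a0 + a1/mu
    dispersion_a1: float = 2.0
    lib_size_sigma: float = 0.2        # per-sample depth factor, lognormal SD (ln)
    n_cases: int = 307                 # MCI-like cohort size (AD-like uses 480)
    n_controls_cc: int = 482
    kappa: float = 1.0                 # disease-vs-music coupling
    sigma_noise_cc: float = 0.304      # residual SD of disease effect (log2)
    sigma_expr_cc: float = 1.0         # within-group log-intensity SD
    baseline_cc: float = 7.0           # log-intensity baseline mean
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 60)
    frac_loaded_sets: float = 0.3
    load_purity: float = 0.8           # fraction of a loaded set drawn from DE genes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_de", "frac_loaded_sets", "load_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "sigma_beta",
            "sigma_subject",
            "sigma_log_mean",
            "sigma_noise_cc",
            "sigma_expr_cc",
            "lib_size_sigma",
            "dispersion_a0",
            "dispersion_a1",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.amplitude_ratio <= 0:
            raise ValidationError("amplitude_ratio must be > 0")
        for name in ("n_genes", "n_subjects_acd", "n_subjects_control", "n_cases", "n_controls_cc"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("set_size_range must satisfy 1 <= lo <= hi")


def design_cc_correlation(params: SimParams) -> float:
    """Closed-form Pearson corr(delta_cc, beta_acd) among responsive genes."""
    sb = params.sigma_beta * params.amplitude_ratio
    denom = np.hypot(params.kappa * sb, params.sigma_noise_cc)
    if denom == 0:
        return 0.0
    return -params.kappa * sb / denom


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_truth(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene ground truth: responsiveness, music effects, disease effect."""
    n = params.n_genes
    is_de = rng.random(n) < params.pi_de
    sign = rng.choice([-1.0, 1.0], size=n)
    beta_control = np.where(is_de, sign * params.sigma_beta, 0.0)
    beta_acd = beta_control * params.amplitude_ratio
    noise = rng.normal(0.0, params.sigma_noise_cc, size=n)
    delta_cc = np.where(is_de, -params.kappa * beta_acd + noise, 0.0)
    truth = pd.DataFrame(
        {
            "gene_id": _gene_ids(n),
            "is_de": is_de,
            "beta_acd": beta_acd,
            "beta_control": beta_control,
            "delta_cc": delta_cc,
        }
    )
    truth.index = pd.Index(truth["gene_id"].to_numpy(), name=None)
    return truth


def simulate_paired_counts(
    params: SimParams,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate paired TP1/TP2 NB counts for the ACD and control cohorts.

    Returns (counts, sample table, truth table). For gene g in subject i at
    timepoint t the NB mean is

        mu = depth_j * mu_g * 2**(s_i + beta_{g, cohort(i)} * 1[t = TP2])

    with subject effect s_i ~ Normal(0, sigma_subject) on the log2 scale.
    """
    rng = np.random.default_rng(params.seed)
    truth = simulate_truth(params, rng)
    mu_g = np.exp(rng.normal(params.mu_log_mean, params.sigma_log_mean, params.n_genes))
    alpha = params.dispersion_a0 + params.dispersion_a1 / mu_g

    meta_rows = []
    columns: dict[str, np.ndarray] = {}
    for cohort, n_subj, beta in (
        ("ACD", params.n_subjects_acd, truth["beta_acd"].to_numpy()),
        ("CONTROL", params.n_subjects_control, truth["beta_control"].to_numpy()),
    ):
        subj_eff = rng.normal(0.0, params.sigma_subject, n_subj)
        for i in range(n_subj):
            subject = f"{cohort[:3]}{i + 1:02d}"
            for tp in ("TP1", "TP2"):
                depth = np.exp(rng.normal(0.0, params.lib_size_sigma))
                log2_mean = subj_eff[i] + (beta if tp == "TP2" else 0.0)
                mu = depth * mu_g * np.exp2(log2_mean)
                n_nb = 1.0 / alpha
                p_nb = n_nb / (n_nb + mu)
                sample = f"{subject}_{tp}"
                columns[sample] = rng.negative_binomial(n_nb, p_nb)
                meta_rows.append(
                    {
                        "sample_id": sample,
                        "subject_id": subject,
                        "cohort": cohort,
                        "timepoint": tp,
                    }
                )
    counts = CountMatrix(pd.DataFrame(columns, index=truth.index.copy()))
    meta = validate_sample_table(pd.DataFrame(meta_rows))
    return counts, meta, truth


def simulate_case_control(
    params: SimParams,
    truth: pd.DataFrame,
    n_cases: int | None = None,
    delta_scale: float = 1.0,
    case_label: str = "CASE",
    seed_offset: int = 1,
) -> tuple[ExprMatrix, pd.DataFrame]:
    """Simulate Gaussian log-intensities for a case-control cohort.

    Cases are shifted by ``delta_scale * delta_cc`` from the truth table.
    ``seed_offset`` decouples the stream from the count simulation so two
    disease cohorts (MCI-like, AD-like) can be drawn from the same truth
    with independent sampling noise.
    """
    if "delta_cc" not in truth.columns:
        raise ValidationError("truth table lacks delta_cc; run simulate_paired_counts first")
    rng = np.random.default_rng(params.seed + seed_offset)
    n_genes = len(truth)
    n_cases = params.n_cases if n_cases is None else n_cases
    n_ctrl = params.n_controls_cc
    baseline = params.baseline_cc + rng.normal(0.0, 1.0, n_genes)
    total = n_cases + n_ctrl
    values = rng.normal(0.0, params.sigma_expr_cc, size=(n_genes, total)) + baseline[:, None]
    values[:, :n_cases] += delta_scale * truth["delta_cc"].to_numpy()[:, None]
    prefix = case_label[:2]
    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n_cases)] + [
        f"CC{i + 1:04d}" for i in range(n_ctrl)
    ]
    expr = ExprMatrix(pd.DataFrame(values, index=truth["gene_id"].tolist(), columns=sample_ids))
    meta = validate_sample_table(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": sample_ids,
                "cohort": ["CASE"] * n_cases + ["CTRL_CC"] * n_ctrl,
                "timepoint": ["NA"] * total,
            }
        )
    )
    return expr, meta


def simulate_gene_sets(params: SimParams, truth: pd.DataFrame) -> GeneSetCatalog:
    """Generate a catalog where ``frac_loaded_sets`` of sets are enriched for
    responsive genes of coherent effect sign and the rest are uniform draws."""
    lo, hi = params.set_size_range
    if hi > params.n_genes:
        raise ValidationError("set_size_range exceeds n_genes")
    rng = np.random.default_rng(params.seed + 2)
    genes = truth["gene_id"].to_numpy()
    up_pool = genes[(truth["is_de"] & (truth["beta_acd"] > 0)).to_numpy()]
    down_pool = genes[(truth["is_de"] & (truth["beta_acd"] < 0)).to_numpy()]
    n_loaded = int(round(params.frac_loaded_sets * params.n_sets))
    catalog = GeneSetCatalog()
    width = len(str(params.n_sets))
    for i in range(params.n_sets):
        size = int(rng.integers(lo, hi + 1))
        loaded = i < n_loaded
        if loaded:
            pool = up_pool if rng.random() < 0.5 else down_pool
            n_from_pool = min(int(round(params.load_purity * size)), len(pool))
            members = list(rng.choice(pool, size=n_from_pool, replace=False))
            rest_pool = np.setdiff1d(genes, np.array(members, dtype=genes.dtype))
            members += list(rng.choice(rest_pool, size=size - n_from_pool, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        kind = "loaded" if loaded else "null"
        catalog.add(f"SET{i + 1:0{width}d}", kind, members)
    return catalog


@dataclass
class SyntheticStudy:
    """One complete synthetic study: paired counts, two disease cohorts, sets."""

    params: SimParams
    counts: CountMatrix
    meta: pd.DataFrame
    truth: pd.DataFrame
    cc_expr_mci: ExprMatrix
    cc_meta_mci: pd.DataFrame
    cc_expr_ad: ExprMatrix
    cc_meta_ad: pd.DataFrame
    catalog: GeneSetCatalog = field(repr=False, default=None)


def simulate_study(params: SimParams, n_cases_ad: int = 480) -> SyntheticStudy:
    """Generate the full study: paired counts plus MCI-like and AD-like cohorts."""
    counts, meta, truth = simulate_paired_counts(params)
    cc_mci, meta_mci = simulate_case_control(params, truth, seed_offset=1)
    cc_ad, meta_ad = simulate_case_control(
        params, truth, n_cases=n_cases_ad, seed_offset=3
    )
    catalog = simulate_gene_sets(params, truth)
    return SyntheticStudy(
        params, counts, meta, truth, cc_mci, meta_mci, cc_ad, meta_ad, catalog
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """Write all study files (TSV/GMT) plus the ground truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "meta": outdir / "meta.tsv",
        "cc_expr": outdir / "cc_expr.tsv",
        "cc_meta": outdir / "cc_meta.tsv",
        "cc_expr_ad": outdir / "cc_expr_ad.tsv",
        "cc_meta_ad": outdir / "cc_meta_ad.tsv",
        "sets": outdir / "sets.gmt",
        "truth": outdir / "truth.tsv",
        "params": outdir / "sim_params.tsv",
    }
    write_count_matrix(study.counts, paths["counts"])
    write_sample_table(study.meta, paths["meta"])
    write_expr_matrix(study.cc_expr_mci, paths["cc_expr"])
    write_sample_table(study.cc_meta_mci, paths["cc_meta"])
    write_expr_matrix(study.cc_expr_ad, paths["cc_expr_ad"])
    write_sample_table(study.cc_meta_ad, paths["cc_meta_ad"])
    write_gmt(study.catalog, paths["sets"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    flat = {k: str(v) for k, v in asdict(study.params).items()}
    pd.Series(flat, name="value").rename_axis("param").to_csv(paths["params"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
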