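"""End-to-end orchestration of the analysis blocks.

``run_prepost`` covers the paired pre/post study for each cohort:
differential expression, summaries, PCA + transcriptome displacement,
pathway scores with paired pathway DE and the cohort activation contrast,
and co-expression modules. ``run_full_study`` adds the case-control
contrasts (MCI-like and AD-like) and the gene- and pathway-level
concordance analyses.

Every stage writes fixed-order TSVs into the output directory and the run
ends with a manifest (config, seed, package version, output checksums) so
a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_de import CohortConfig, case_control_de, detect_outliers, harmonize_cohorts
from .coexpression import (
    CoexpressionParams,
    detect_modules,
    gene_trait_correlation,
    mm_trait_link,
    module_eigengenes,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
    remove_subject_effect,
    variance_filter,
)
from .concordance import run_concordance, compare_disease_contrasts, summarize_concordance
from .core_io import (
    CountMatrix,
    ExprMatrix,
    FormatError,
    GeneSetCatalog,
    read_count_matrix,
    read_expr_matrix,
    read_gene_annotation,
    read_gmt,
    read_sample_table,
    write_de_table,
    write_expr_matrix,
)
from .displacement import pca_transcriptomes, td_score, top_loading_genes
from .paired_de import (
    DEConfig,
    deg_count_ratio,
    filter_low_expression,
    log2fc_density_summary,
    paired_nb_wald,
    size_factors,
    summarize_degs,
)
from .pathway_activity import (
    filter_differential_activation,
    gsva_scores,
    paired_pathway_de,
    pathway_activity_compare,
)
from .simulate import SimParams, simulate_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and tunables; loadable from a YAML key/value file."""

    counts: str = "counts.tsv"
    meta: str = "meta.tsv"
    sets: str = "sets.gmt"
    annotation: str | None = None
    cc_expr: str | None = None          # MCI-like cohort expression
    cc_meta: str | None = None
    cc_expr_ad: str | None = None       # AD-like cohort expression
    cc_meta_ad: str | None = None
    outdir: str = "prepostx_out"
    seed: int = 0
    n_components: int = 2
    loading_fraction: float = 0.10
    gsva_tau: float = 1.0
    gsva_min_set_size: int = 5
    gsva_kernel: str = "gaussian"
    gsva_kernel_cc: str = "ecdf"        # rank statistic for the large cohort
    concordance_alpha: float = 0.05
    concordance_which: str = "disease"
    run_coexpression: bool = True
    de: DEConfig = field(default_factory=DEConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    coexpr: CoexpressionParams = field(default_factory=CoexpressionParams)

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict[str, Any] | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if overrides:
            raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for key, value in raw.items():
            if key in ("de", "cohort", "coexpr") and isinstance(value, dict):
                sub = getattr(cfg, key)
                for k, v in value.items():
                    if not hasattr(sub, k):
                        raise FormatError(f"unknown config key {key}.{k}")
                    setattr(sub, k, type(getattr(sub, k))(v) if v is not None else v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise FormatError(f"unknown config key {key!r}")
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["coexpr"]["beta_grid"] = list(d["coexpr"]["beta_grid"])
        return d


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.1fs", stage, time.time() - self.t0)
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", stage, time.time() - self.t0)

    return _Timer()


def log_normalized_expression(counts: CountMatrix, sf: pd.Series) -> ExprMatrix:
    """log2(normalized count + 1) expression for PCA/GSVA/co-expression."""
    q = counts.counts.to_numpy(dtype=float) / sf.loc[counts.sample_ids].to_numpy()
    return ExprMatrix(
        pd.DataFrame(np.log2(q + 1.0), index=counts.gene_ids, columns=counts.sample_ids)
    )


def _prepost_one_cohort(
    cohort: str,
    counts: CountMatrix,
    meta: pd.DataFrame,
    catalog: GeneSetCatalog,
    annotation: pd.Series | None,
    config: PipelineConfig,
    outdir: Path,
) -> dict[str, Any]:
    sub_meta = meta[meta["cohort"] == cohort].reset_index(drop=True)
    sub_counts = CountMatrix(counts.counts[sub_meta["sample_id"].tolist()])
    tag = cohort.lower()
    with _timed(f"paired_de[{cohort}]"):
        filtered = filter_low_expression(sub_counts, config.de)
        sf = size_factors(filtered)
        de = paired_nb_wald(filtered, sub_meta, config.de, sf=sf)
        write_de_table(de, outdir / f"de_genes_{tag}.tsv")
        summary = summarize_degs(de, annotation, config.de)
        if summary.biotype_table is not None:
            summary.biotype_table.to_csv(outdir / f"summary_{tag}.tsv", sep="\t", index=False)
    with _timed(f"displacement[{cohort}]"):
        expr = log_normalized_expression(filtered, sf)
        pca = pca_transcriptomes(
            expr, config.n_components, meta=sub_meta, subject_center=True
        )
        pca.projections.to_csv(outdir / f"pca_projections_{tag}.tsv", sep="\t")
        pca.loadings.to_csv(outdir / f"pca_loadings_{tag}.tsv", sep="\t", float_format="%.6g")
        td = td_score(pca, sub_meta)
        td.td.to_csv(outdir / f"td_report_{tag}.tsv", sep="\t", index=False)
        top = top_loading_genes(pca, "PC1", config.loading_fraction)
        top.to_csv(outdir / f"top_loading_genes_{tag}.tsv", sep="\t", index=False)
    with _timed(f"pathway_scores[{cohort}]"):
        scores = gsva_scores(
            expr, catalog, config.gsva_tau, config.gsva_min_set_size, config.gsva_kernel
        )
        scores.to_csv(outdir / f"pathway_scores_{tag}.tsv", sep="\t", float_format="%.6g")
        de_pathways = paired_pathway_de(scores, sub_meta)
        write_de_table(de_pathways, outdir / f"de_pathways_{tag}.tsv")
    result = {
        "de": de,
        "de_pathways": de_pathways,
        "summary": summary,
        "expr": expr,
        "pca": pca,
        "td": td,
        "scores": scores,
        "meta": sub_meta,
    }
    if config.run_coexpression:
        with _timed(f"coexpression[{cohort}]"):
            centered = remove_subject_effect(expr, sub_meta)
            top_var = variance_filter(centered, config.coexpr.top_variance_fraction)
            soft = pick_soft_threshold(top_var, config.coexpr)
            assignment = detect_modules(top_var, soft.beta, config.coexpr)
            trait = pd.Series(
                (
                    sub_meta.set_index("sample_id")
                    .loc[top_var.sample_ids, "timepoint"]
                    == "TP2"
                ).astype(float),
                name="music",
            )
            if assignment.modules():
                eigengenes = module_eigengenes(top_var, assignment)
                mt = module_trait_correlation(eigengenes, trait, config.coexpr.fdr_threshold)
                mm = module_membership(top_var, eigengenes)
                gt = gene_trait_correlation(top_var, trait)
                link = mm_trait_link(mm, gt, assignment)
                eigengenes.to_csv(outdir / f"eigengenes_{tag}.tsv", sep="\t", float_format="%.6g")
                mt.to_csv(outdir / f"module_trait_{tag}.tsv", sep="\t", index=False)
                modules_df = pd.DataFrame(
                    {"gene_id": assignment.labels.index, "module": assignment.labels.values}
                )
                own_mm = [
                    mm.at[g, m] if m in mm.columns else np.nan
                    for g, m in zip(modules_df["gene_id"], modules_df["module"])
                ]
                modules_df["module_membership"] = own_mm
                modules_df.to_csv(outdir / f"modules_{tag}.tsv", sep="\t", index=False)
                link.to_csv(outdir / f"mm_trait_link_{tag}.tsv", sep="\t", index=False)
                result.update(
                    {"assignment": assignment, "module_trait": mt, "soft_beta": soft.beta}
                )
            else:
                result.update({"assignment": assignment, "module_trait": None, "soft_beta": soft.beta})
    return result


def run_prepost(config: PipelineConfig) -> dict[str, Any]:
    """Paired pre/post analysis for both cohorts plus the cross-cohort comparisons."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = read_count_matrix(config.counts)
    meta = read_sample_table(config.meta)
    catalog = read_gmt(config.sets)
    annotation = read_gene_annotation(config.annotation) if config.annotation else None
    results: dict[str, Any] = {"config": config}
    for cohort in ("ACD", "CONTROL"):
        if (meta["cohort"] == cohort).any():
            results[cohort] = _prepost_one_cohort(
                cohort, counts, meta, catalog, annotation, config, outdir
            )
    if "ACD" in results and "CONTROL" in results:
        with _timed("cross_cohort"):
            density = log2fc_density_summary(
                results["ACD"]["de"], results["CONTROL"]["de"], config.de
            )
            ratio = deg_count_ratio(results["ACD"]["summary"], results["CONTROL"]["summary"])
            pd.DataFrame(
                [{**asdict(density), "deg_count_ratio_acd_over_control": ratio}]
            ).to_csv(outdir / "cross_cohort_summary.tsv", sep="\t", index=False)
            pa = pathway_activity_compare(
                results["ACD"]["de"], results["CONTROL"]["de"], catalog
            )
            pa.to_csv(outdir / "pa_compare.tsv", sep="\t", index=False, float_format="%.6g")
            pa_pass = filter_differential_activation(pa)
            pa_pass.to_csv(outdir / "pa_filtered.tsv", sep="\t", index=False, float_format="%.6g")
            results["density"] = density
            results["deg_ratio"] = ratio
            results["pa_compare"] = pa
    _write_manifest(config, outdir)
    return results


def _disease_contrast(
    expr_path: str,
    meta_path: str,
    label: str,
    catalog: GeneSetCatalog,
    config: PipelineConfig,
    outdir: Path,
) -> dict[str, Any]:
    expr = read_expr_matrix(expr_path)
    meta = read_sample_table(meta_path)
    with _timed(f"cohort_de[{label}]"):
        flags = detect_outliers(expr, config.cohort)
        keep = [s for s in expr.sample_ids if not flags[s]]
        expr = ExprMatrix(expr.values[keep])
        harmonized, _ = harmonize_cohorts([(expr, label)], config.cohort)
        de = case_control_de(harmonized, meta)
        write_de_table(de, outdir / f"de_casecontrol_{label.lower()}.tsv")
    with _timed(f"cohort_pathways[{label}]"):
        scores = gsva_scores(
            harmonized, catalog, config.gsva_tau, config.gsva_min_set_size, config.gsva_kernel_cc
        )
        de_pathways = case_control_de(
            ExprMatrix(scores), meta
        )
        write_de_table(de_pathways, outdir / f"de_casecontrol_pathways_{label.lower()}.tsv")
    return {"de": de, "de_pathways": de_pathways, "n_outliers": int(flags.sum())}


def run_full_study(config: PipelineConfig) -> dict[str, Any]:
    """Pre/post block plus disease contrasts and concordance analyses."""
    if not config.cc_expr or not config.cc_meta:
        raise FormatError("run_full_study requires config keys cc_expr and cc_meta")
    for key in ("cc_expr", "cc_meta", "cc_expr_ad", "cc_meta_ad"):
        path = getattr(config, key)
        if path and not Path(path).exists():
            raise FormatError(f"config key {key} points to a missing file: {path}")
    results = run_prepost(config)
    outdir = Path(config.outdir)
    catalog = read_gmt(config.sets)
    contrasts = {"MCI": (config.cc_expr, config.cc_meta)}
    if config.cc_expr_ad and config.cc_meta_ad:
        contrasts["AD"] = (config.cc_expr_ad, config.cc_meta_ad)
    de_music = results["ACD"]["de"]
    dep_music = results["ACD"]["de_pathways"]
    conc_gene: dict[str, Any] = {}
    conc_path: dict[str, Any] = {}
    for label, (expr_path, meta_path) in contrasts.items():
        disease = _disease_contrast(expr_path, meta_path, label, catalog, config, outdir)
        results[f"cc_{label}"] = disease
        with _timed(f"concordance[{label}]"):
            cg = run_concordance(
                de_music, disease["de"], config.concordance_which, config.concordance_alpha
            )
            cg.pairs.to_csv(
                outdir / f"concordance_genes_{label.lower()}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            summarize_concordance(cg).to_csv(
                outdir / f"concordance_genes_{label.lower()}_summary.tsv", sep="\t", index=False
            )
            cp = run_concordance(
                dep_music, disease["de_pathways"], config.concordance_which, config.concordance_alpha
            )
            summarize_concordance(cp).to_csv(
                outdir / f"concordance_pathways_{label.lower()}_summary.tsv", sep="\t", index=False
            )
            conc_gene[label] = cg
            conc_path[label] = cp
    results["concordance_genes"] = conc_gene
    results["concordance_pathways"] = conc_path
    if len(conc_gene) == 2:
        overlap = compare_disease_contrasts(conc_gene["MCI"], conc_gene["AD"])
        pd.DataFrame(
            [
                {
                    "n_intersection": overlap.n_intersection,
                    "rho_disease": overlap.rho_disease,
                    "p_disease": overlap.p_disease,
                }
            ]
        ).to_csv(outdir / "disease_contrast_overlap.tsv", sep="\t", index=False)
        results["disease_overlap"] = overlap
    _write_manifest(config, outdir)
    return results


def run_demo(outdir: str | Path, seed: int = 0, params: SimParams | None = None) -> dict[str, Any]:
    """Simulate a study with default parameters and run the full pipeline on it."""
    outdir = Path(outdir)
    datadir = outdir / "data"
    params = params or SimParams(seed=seed)
    study = simulate_study(params)
    paths = write_study(study, datadir)
    config = PipelineConfig(
        counts=paths["counts"],
        meta=paths["meta"],
        sets=paths["sets"],
        cc_expr=paths["cc_expr"],
        cc_meta=paths["cc_meta"],
        cc_expr_ad=paths["cc_expr_ad"],
        cc_meta_ad=paths["cc_meta_ad"],
        outdir=str(outdir / "results"),
        seed=seed,
    )
    return run_full_study(config)


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    entries = {}
    for path in sorted(outdir.glob("*.tsv")):
        entries[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "package": "prepostx",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": entries,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
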