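"""Shared data containers, file readers/writers and small statistical utilities.

Conventions used throughout the package:

* expression and count matrices are stored genes x samples, with gene ids as
  the row index and sample ids as the column header;
* feature ids are opaque strings matched by exact equality;
* all tabular outputs are TSV with a fixed column order;
* missing values are rejected at read time -- every stage operates on
  complete matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


COHORTS = ("ACD", "CONTROL", "CASE", "CTRL_CC")
TIMEPOINTS = ("TP1", "TP2", "NA")

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count matrix."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("count matrix contains non-finite values")
        if values.size and (values < 0).any():
            bad = df.index[(values < 0).any(axis=1)][0]
            raise ValidationError(f"negative count for gene {bad!r}")
        if values.size and not np.array_equal(values, np.round(values)):
            bad = df.index[(values != np.round(values)).any(axis=1)][0]
            raise ValidationError(f"non-integer count for gene {bad!r}")
        self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ExprMatrix:
    """Real-valued gene x sample matrix (log-scale expression or normalized counts)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCatalog:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))  # preserves first-seen order
        if not deduped:
            raise ValidationError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(name, description, tuple(deduped))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _check_unique(index: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for item in index:
        if item in seen:
            raise FormatError(f"duplicate {what} id {item!r}")
        seen.add(item)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ValidationError(f"missing values in {path}")
    return df


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV/CSV with a header row of sample ids and gene ids in column 1."""
    return CountMatrix(_read_table(path))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_expr_matrix(path: str | Path) -> ExprMatrix:
    return ExprMatrix(_read_table(path))


def write_expr_matrix(em: ExprMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


SAMPLE_COLUMNS = ("sample_id", "subject_id", "cohort", "timepoint")


def validate_sample_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata: mandatory columns, enums, unique sample ids."""
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    meta = meta.copy()
    for col in SAMPLE_COLUMNS:
        meta[col] = meta[col].astype(str)
    _check_unique(meta["sample_id"], "sample")
    bad_cohort = sorted(set(meta["cohort"]) - set(COHORTS))
    if bad_cohort:
        raise ValidationError(f"unknown cohort value(s): {bad_cohort}")
    bad_tp = sorted(set(meta["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"unknown timepoint value(s): {bad_tp}")
    return meta.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # keep_default_na: "NA" is a legal timepoint value, not a missing cell
    return validate_sample_table(pd.read_csv(path, sep=sep, keep_default_na=False))


def write_sample_table(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def paired_subjects(meta: pd.DataFrame) -> pd.DataFrame:
    """Return one row per subject with its TP1 and TP2 sample ids.

    Raises ValidationError naming the offending subjects if any subject does
    not have exactly one TP1 and one TP2 sample.
    """
    meta = validate_sample_table(meta)
    rows = []
    bad = []
    for subject, grp in meta.groupby("subject_id", sort=True):
        tp1 = grp.loc[grp["timepoint"] == "TP1", "sample_id"].tolist()
        tp2 = grp.loc[grp["timepoint"] == "TP2", "sample_id"].tolist()
        if len(tp1) != 1 or len(tp2) != 1:
            bad.append(subject)
        else:
            rows.append(
                {
                    "subject_id": subject,
                    "cohort": grp["cohort"].iloc[0],
                    "tp1": tp1[0],
                    "tp2": tp2[0],
                }
            )
    if bad:
        raise ValidationError(f"subjects without exactly one TP1 and one TP2 sample: {bad}")
    return pd.DataFrame(rows)


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file: tab-separated ``name, description, gene, gene, ...``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    catalog = GeneSetCatalog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            catalog.add(fields[0], fields[1], fields[2:])
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in catalog:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gene_annotation(path: str | Path) -> pd.Series:
    """Read a two-column (gene_id, biotype) table into a Series keyed by gene id."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise FormatError("annotation table needs at least 2 columns (gene_id, biotype)")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "biotype"]
    df["gene_id"] = df["gene_id"].astype(str)
    _check_unique(df["gene_id"], "gene")
    return df.set_index("gene_id")["biotype"].astype(str)


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ["feature_id", "log2fc", "stat", "pvalue", "fdr", "direction"]


def make_de_table(
    feature_ids: Sequence[str],
    log2fc: np.ndarray,
    stat: np.ndarray,
    pvalue: np.ndarray,
    extra: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble a DE table with BH FDR and direction labels.

    ``pvalue`` entries may be NaN (e.g. non-convergent fits); those features
    are excluded from the BH adjustment and carry NaN FDR.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    stat = np.asarray(stat, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    n = len(feature_ids)
    if not (len(log2fc) == len(stat) == len(pvalue) == n):
        raise ValidationError("DE table column length mismatch")
    fdr = np.full(n, np.nan)
    ok = np.isfinite(pvalue)
    if ok.any():
        fdr[ok] = bh_adjust(pvalue[ok])
    direction = np.where(log2fc > 0, "UP", np.where(log2fc < 0, "DOWN", "NULL"))
    table = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "log2fc": log2fc,
            "stat": stat,
            "pvalue": pvalue,
            "fdr": fdr,
            "direction": direction,
        }
    )
    if extra:
        for key, values in extra.items():
            table[key] = values
    return table


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    cols = DE_COLUMNS + [c for c in de.columns if c not in DE_COLUMNS]
    de.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# statistics utilities
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; asymptotic two-sided p.

    Returns ``(nan, nan)`` with a warning if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("spearman_rho: length mismatch")
    if x.size < 3:
        raise ValidationError("spearman_rho requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman_rho: constant input, rho undefined", RuntimeWarning)
        return (math.nan, math.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t approximation (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return (r, float(p))
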