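"""Input/output, validation and multi-cohort assembly.

This module owns the three container types the rest of the pipeline works
with — :class:`ExpressionMatrix`, :class:`GeneSetCollection` and
:class:`SurvivalTable` — plus the external formats: GMT gene-set files,
tab-separated expression / clinical / mutation / copy-number / methylation
tables, the FPKM→TPM conversion, log2 transformation, cohort merging and
an empirical-Bayes (ComBat-style) batch adjustment.

All expression values are expected on the log2 scale once they enter the
pipeline.  Gene identifiers are treated as opaque strings: probe→symbol
mapping is the caller's responsibility.  Missing expression values are
rejected rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SurvivalTable",
    "read_gmt",
    "fpkm_to_tpm",
    "log2_transform",
    "merge_cohorts",
    "batch_adjust",
    "read_expression",
    "write_expression",
    "read_clinical",
    "read_maf",
    "read_cnv",
    "read_methylation",
    "read_probe_annotation",
]

METHYLATION_REGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
ISLAND_STATUSES = ("Island", "Shore", "Shelf", "OpenSea")

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of log2-scale expression with cohort provenance.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.  All
        entries must be finite; identifiers must be unique.
    cohort_of_sample
        Series mapping sample id → cohort label.  Defaults to a single
        cohort named ``"cohort0"``.
    """

    values: pd.DataFrame
    cohort_of_sample: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite (no NaN/Inf); "
                             "missing values are not imputed")
        if self.cohort_of_sample is None:
            self.cohort_of_sample = pd.Series(
                "cohort0", index=self.values.columns, name="cohort"
            )
        else:
            self.cohort_of_sample = pd.Series(self.cohort_of_sample)
            missing = self.values.columns.difference(self.cohort_of_sample.index)
            if len(missing):
                raise ValueError(f"samples without cohort label: {list(missing)[:5]}")
            self.cohort_of_sample = self.cohort_of_sample.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.cohort_of_sample.copy())

    def split_by_cohort(self) -> dict[str, "ExpressionMatrix"]:
        out: dict[str, ExpressionMatrix] = {}
        for label in pd.unique(self.cohort_of_sample):
            cols = self.cohort_of_sample.index[self.cohort_of_sample == label]
            out[label] = ExpressionMatrix(
                self.values[cols], self.cohort_of_sample[cols]
            )
        return out


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]
    category: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional category labels (e.g. collagen/glycoprotein)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} does not match set name {gs.name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def union_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self:
            out.update(gs.genes)
        return out

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})

    def filter_by_size(self, min_size: int = 5, max_size: int = 2000,
                       universe=None) -> "GeneSetCollection":
        """Drop sets whose (optionally universe-restricted) size is outside bounds."""
        uni = set(universe) if universe is not None else None
        kept = {}
        for gs in self:
            genes = [g for g in gs.genes if uni is None or g in uni]
            if min_size <= len(genes) <= max_size:
                kept[gs.name] = gs
        return GeneSetCollection(kept)


@dataclass
class SurvivalTable:
    """Per-sample clinical table: survival endpoints plus optional covariates.

    Mandatory columns: ``os_time`` (months, ≥0) and ``os_event`` (0/1).
    Optional: ``rfs_time``/``rfs_event``, ``stage`` (ordinal I..IV given as
    1..4), ``chemo`` (0/1), ``subtype`` (free label).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in clinical table")
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing mandatory column {col!r}")
        self._check_endpoint("os_time", "os_event")
        if "rfs_time" in df.columns or "rfs_event" in df.columns:
            if not {"rfs_time", "rfs_event"} <= set(df.columns):
                raise ValueError("rfs_time and rfs_event must be given together")
            self._check_endpoint("rfs_time", "rfs_event")
        if "chemo" in df.columns:
            vals = df["chemo"].dropna().unique()
            if not set(np.asarray(vals)).issubset({0, 1}):
                raise ValueError("chemo flag must be 0/1")

    def _check_endpoint(self, time_col: str, event_col: str) -> None:
        t = self.data[time_col].dropna()
        if (t < 0).any():
            raise ValueError(f"{time_col} contains negative times")
        ev = self.data[event_col].dropna().unique()
        if not set(np.asarray(ev)).issubset({0, 1}):
            raise ValueError(f"{event_col} must be binary 0/1, got {sorted(ev)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, which: str = "os") -> tuple[np.ndarray, np.ndarray]:
        """Return (times, events) arrays for ``"os"`` or ``"rfs"``."""
        t = self.data[f"{which}_time"].to_numpy(dtype=float)
        e = self.data[f"{which}_event"].to_numpy(dtype=int)
        return t, e

    def aligned(self, sample_ids) -> "SurvivalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return SurvivalTable(self.data.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path, category_map=None) -> GeneSetCollection:
    """Parse a GMT file (one gene set per line: name, description, genes...).

    Within-set duplicate genes are removed with a warning; a line with fewer
    than three tab-separated fields raises a parse error naming the line.
    ``category_map`` optionally maps set name → category label.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"gene set {name!r} (line {lineno}): removed "
                    f"{len(genes) - len(deduped)} duplicate gene(s)"
                )
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            category = "" if category_map is None else category_map.get(name, "")
            sets[name] = GeneSet(name, desc, tuple(deduped), category)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# normalisation steps
# ---------------------------------------------------------------------------

def fpkm_to_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale FPKM columns to TPM: each sample (column) sums to 1e6."""
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM matrix contains negative entries")
    colsum = arr.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if len(zero):
        raise ValueError(
            f"all-zero expression column(s): {list(matrix.columns[zero])[:5]}"
        )
    out = arr / colsum * 1e6
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix, offset: float = 1.0):
    """log2(x + offset); input must be non-negative.

    Accepts a DataFrame (returned as DataFrame) or an
    :class:`ExpressionMatrix`-shaped DataFrame the caller then wraps.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = np.asarray(df, dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_transform requires non-negative input")
    out = np.log2(arr + offset)
    if isinstance(df, pd.DataFrame):
        out = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(out, matrix.cohort_of_sample.copy())
    return out


def merge_cohorts(cohorts: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cohorts on the intersection of their gene universes.

    Gene order follows the first cohort.  Sample ids must be globally unique;
    each sample keeps (or is assigned) its cohort label.
    """
    if len(cohorts) < 2:
        raise ValueError("merge_cohorts requires at least two cohorts")
    common = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        common &= set(c.gene_ids)
    if not common:
        raise ValueError("cohorts share no genes: empty intersection")
    genes = [g for g in cohorts[0].gene_ids if g in common]

    seen: set[str] = set()
    for i, c in enumerate(cohorts):
        clash = seen & set(c.sample_ids)
        if clash:
            raise ValueError(f"sample-id collision across cohorts: {sorted(clash)[:5]}")
        seen |= set(c.sample_ids)

    blocks, labels = [], []
    for i, c in enumerate(cohorts):
        blocks.append(c.values.loc[genes])
        lab = c.cohort_of_sample.copy()
        if lab.nunique() == 1 and lab.iloc[0] == "cohort0":
            lab = pd.Series(f"cohort{i}", index=lab.index)
        labels.append(lab)
    values = pd.concat(blocks, axis=1)
    cohort = pd.concat(labels)
    return ExpressionMatrix(values, cohort)


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment (ComBat-style)
# ---------------------------------------------------------------------------

def _eb_priors(gamma_hat, delta_hat2):
    # method-of-moments priors: normal for location, inverse-gamma for scale
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    v = delta_hat2.mean()
    s2 = delta_hat2.var(ddof=1)
    a = (2 * s2 + v**2) / s2 if s2 > 0 else np.inf
    b = (v * s2 + v**3) / s2 if s2 > 0 else np.inf
    return gamma_bar, tau2, a, b


def batch_adjust(merged: ExpressionMatrix, max_iter: int = 200,
                 tol: float = 1e-8) -> ExpressionMatrix:
    """Remove per-batch location/scale effects with empirical-Bayes shrinkage.

    Per gene, batch means and variances are estimated on pooled-standardized
    data, shrunk across genes (normal prior on location, inverse-gamma on
    scale, parametric method-of-moments priors), removed, and the grand mean
    and pooled variance restored.  Genes with zero pooled variance are
    returned unchanged; a gene constant within one batch has only its
    location adjusted there.
    """
    batches = merged.cohort_of_sample.to_numpy()
    labels, batch_idx = np.unique(batches, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("batch_adjust requires >=2 cohorts")
    n_b = np.bincount(batch_idx)
    small = [str(labels[i]) for i in np.flatnonzero(n_b < 3)]
    if small:
        raise ValueError(f"batch(es) with fewer than 3 samples: {small}")

    X = merged.values.to_numpy(dtype=float)
    G, n = X.shape
    B = len(labels)

    # per-gene per-batch means; grand mean weighted by batch size
    batch_means = np.empty((G, B))
    for b in range(B):
        batch_means[:, b] = X[:, batch_idx == b].mean(axis=1)
    grand = batch_means @ (n_b / n)
    resid = X - batch_means[:, batch_idx]
    var_pooled = (resid**2).sum(axis=1) / n

    keep = var_pooled > 0
    out = X.copy()
    if keep.any():
        Z = (X[keep] - grand[keep, None]) / np.sqrt(var_pooled[keep])[:, None]
        gamma_star = np.empty((Z.shape[0], B))
        delta_star = np.empty((Z.shape[0], B))
        for b in range(B):
            Zb = Z[:, batch_idx == b]
            g_hat = Zb.mean(axis=1)
            d_hat2 = Zb.var(axis=1, ddof=1)
            gamma_bar, tau2, a_pr, b_pr = _eb_priors(g_hat, d_hat2)
            g_star = g_hat.copy()
            d_star = np.where(d_hat2 > 0, d_hat2, 1.0)
            if np.isfinite(a_pr) and tau2 > 0:
                for _ in range(max_iter):
                    g_new = (n_b[b] * tau2 * g_hat + d_star * gamma_bar) / (
                        n_b[b] * tau2 + d_star
                    )
                    sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                    d_new = (b_pr + 0.5 * sum2) / (n_b[b] / 2 + a_pr - 1)
                    change = max(
                        np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max()
                    )
                    g_star, d_star = g_new, d_new
                    if change < tol:
                        break
            # zero within-batch variance: location-only adjustment there
            d_star = np.where(d_hat2 > 0, d_star, 1.0)
            gamma_star[:, b] = g_star
            delta_star[:, b] = d_star
        Zadj = (Z - gamma_star[:, batch_idx]) / np.sqrt(delta_star[:, batch_idx])
        out[keep] = Zadj * np.sqrt(var_pooled[keep])[:, None] + grand[keep, None]

    values = pd.DataFrame(out, index=merged.values.index, columns=merged.values.columns)
    return ExpressionMatrix(values, merged.cohort_of_sample.copy())


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def _read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_expression(path, cohort: str | None = None) -> ExpressionMatrix:
    """Read a gene × sample TSV (first column gene id, header sample ids)."""
    df = _read_tsv(path)
    em = ExpressionMatrix(df)
    if cohort is not None:
        em.cohort_of_sample = pd.Series(cohort, index=df.columns, name="cohort")
    return em


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> SurvivalTable:
    """Read a clinical TSV indexed by sample id; validates endpoint columns."""
    df = _read_tsv(path)
    return SurvivalTable(df)


def write_clinical(surv: SurvivalTable, path) -> None:
    surv.data.to_csv(path, sep="\t", index_label="sample_id")


def read_maf(path) -> pd.DataFrame:
    """Read a minimal MAF-like mutation table (one record per row)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF table missing mandatory column(s): {missing}")
    return df


def read_cnv(path) -> pd.DataFrame:
    """Read gene × sample integer copy-number calls in {-2..2}."""
    df = _read_tsv(path)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr), equal_nan=False):
            raise ValueError("CNV calls must be integers")
        df = df.astype(int)
        arr = df.to_numpy()
    if arr.size and (arr.min() < -2 or arr.max() > 2):
        raise ValueError("CNV calls out of range {-2..2}")
    return df


def read_methylation(path) -> pd.DataFrame:
    """Read probe × sample beta values, validated to lie in [0, 1]."""
    df = _read_tsv(path)
    arr = df.to_numpy(dtype=float)
    if arr.size and ((arr < 0).any() or (arr > 1).any()):
        raise ValueError("methylation beta values must lie in [0, 1]")
    return df


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation: probe id, region label, island status[, gene]."""
    df = _read_tsv(path)
    for col in ("region", "island_status"):
        if col not in df.columns:
            raise ValueError(f"probe annotation missing mandatory column {col!r}")
    bad = set(df["region"].dropna().unique()) - set(METHYLATION_REGIONS)
    if bad:
        raise ValueError(f"unknown region label(s): {sorted(bad)}")
    bad = set(df["island_status"].dropna().unique()) - set(ISLAND_STATUSES)
    if bad:
        raise ValueError(f"unknown island status label(s): {sorted(bad)}")
    return df
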