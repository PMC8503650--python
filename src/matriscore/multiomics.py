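"""Associating the ECM score with mutation burden, copy-number burden and
DNA methylation.

TMB here is the raw count of nonsilent mutation records per sample — no
per-megabase denominator is applied, so values are comparable only within
one variant-calling pipeline.  CNV burden is the L1 norm of gene-level
thresholded calls (sum of |call| over genes).  Methylation contrasts report
per-probe delta-beta (high − low), Wilcoxon rank-sum p and BH q, and
summaries per region label and per CpG-island status; probes collapse to
genes by mean delta-beta before process-level enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import GseaResult, preranked_gsea
from .io_formats import GeneSetCollection, MAF_REQUIRED_COLUMNS

__all__ = [
    "SILENT_CLASSIFICATIONS",
    "tmb_from_maf",
    "cnv_burden",
    "score_association",
    "methylation_contrast",
    "methylation_process_gsea",
]

# variant classes that do NOT count toward tumor mutation burden
SILENT_CLASSIFICATIONS = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "IGR", "RNA", "3'Flank", "5'Flank"}
)

NONSILENT_KNOWN = frozenset(
    {"Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
     "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
     "Splice_Site", "Translation_Start_Site"}
)


def tmb_from_maf(maf: pd.DataFrame, sample_ids=None) -> pd.Series:
    """Per-sample count of nonsilent mutation records.

    ``sample_ids`` optionally fixes the output index (samples with no
    records get 0).  Unknown classification strings are counted as
    nonsilent with a warning.
    """
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF table missing column(s): {missing}")
    cls = maf["Variant_Classification"].astype(str)
    unknown = set(cls.unique()) - SILENT_CLASSIFICATIONS - NONSILENT_KNOWN
    if unknown:
        warnings.warn(
            f"unknown variant classification(s) counted as nonsilent: {sorted(unknown)}"
        )
    nonsilent = maf[~cls.isin(SILENT_CLASSIFICATIONS)]
    counts = nonsilent.groupby("Tumor_Sample_Barcode").size()
    if sample_ids is not None:
        counts = counts.reindex(list(sample_ids), fill_value=0)
    counts = counts.astype(int)
    counts.name = "tmb"
    return counts


def cnv_burden(calls: pd.DataFrame) -> pd.Series:
    """Per-sample L1 burden of gene × sample copy-number calls in {-2..2}."""
    arr = calls.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("CNV calls must be integers")
    if arr.size and (arr.min() < -2 or arr.max() > 2):
        raise ValueError("CNV calls out of range {-2..2}")
    out = pd.Series(np.abs(arr).sum(axis=0), index=calls.columns, name="cnv_burden")
    return out


def score_association(score: pd.Series, burden: pd.Series,
                      high: pd.Series | None = None) -> dict:
    """Spearman association of a per-sample score with a per-sample burden.

    Returns ``{"rho", "rho_p", "n"}`` plus, when a boolean/0-1 ``high``
    grouping is supplied, the two-sided Wilcoxon rank-sum p of the
    high-vs-low contrast.  Requires ≥10 paired samples and non-constant
    vectors (Spearman rho is undefined for a constant vector).
    """
    common = score.index.intersection(burden.index)
    if len(common) < 10:
        raise ValueError("need at least 10 paired samples")
    x = score.loc[common].to_numpy(dtype=float)
    y = burden.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    out = {"rho": float(rho), "rho_p": float(p), "n": int(len(common))}
    if high is not None:
        h = high.loc[common].astype(bool).to_numpy()
        if h.any() and (~h).any():
            stat, wp = stats.mannwhitneyu(y[h], y[~h], alternative="two-sided")
            out["wilcoxon_p"] = float(wp)
            out["median_high"] = float(np.median(y[h]))
            out["median_low"] = float(np.median(y[~h]))
    return out


def methylation_contrast(
    beta: pd.DataFrame,
    high_samples,
    low_samples,
    annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-probe delta-beta (mean high − mean low) with Wilcoxon p and BH q.

    Returns ``(probe_table, region_summary, island_summary)``.  Probes
    absent from the annotation are excluded; the count is reported in a
    warning.  Both groups need ≥3 samples; beta values must be in [0, 1].
    """
    high_samples, low_samples = list(high_samples), list(low_samples)
    if len(high_samples) < 3 or len(low_samples) < 3:
        raise ValueError("each group needs at least 3 samples")
    arr = beta.to_numpy(dtype=float)
    if arr.size and ((arr < 0).any() or (arr > 1).any()):
        raise ValueError("beta values must lie in [0, 1]")

    annotated = beta.index.intersection(annotation.index)
    dropped = len(beta.index) - len(annotated)
    if dropped:
        warnings.warn(f"{dropped} unannotated probe(s) excluded")
    b = beta.loc[annotated]
    hi = b[high_samples].to_numpy(dtype=float)
    lo = b[low_samples].to_numpy(dtype=float)
    delta = hi.mean(axis=1) - lo.mean(axis=1)
    pvals = np.ones(len(annotated))
    for i in range(len(annotated)):
        if np.ptp(np.concatenate([hi[i], lo[i]])) == 0:
            pvals[i] = 1.0
        else:
            _, pvals[i] = stats.mannwhitneyu(hi[i], lo[i], alternative="two-sided")
    qvals = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "p": pvals,
            "q": qvals,
            "region": annotation.loc[annotated, "region"],
            "island_status": annotation.loc[annotated, "island_status"],
        },
        index=annotated,
    )
    region_summary = table.groupby("region", observed=True).agg(
        mean_delta=("delta_beta", "mean"),
        n_probes=("delta_beta", "size"),
        n_significant=("q", lambda q: int((q < 0.05).sum())),
    )
    island_summary = table.groupby("island_status", observed=True).agg(
        mean_delta=("delta_beta", "mean"),
        n_probes=("delta_beta", "size"),
        n_significant=("q", lambda q: int((q < 0.05).sum())),
    )
    return table, region_summary, island_summary


def methylation_process_gsea(
    probe_table: pd.DataFrame,
    probe_to_gene: pd.Series,
    process_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[GseaResult]:
    """Pre-ranked enrichment of biological-process sets on delta-beta.

    Probes collapse to genes by mean delta-beta; genes are ranked decreasing
    (most hypermethylated in the high group first) and handed to
    :func:`preranked_gsea`, so a hypomethylated process shows a negative ES.
    """
    common = probe_table.index.intersection(probe_to_gene.index)
    if len(common) == 0:
        raise ValueError("no probe maps to a gene")
    per_gene = (
        probe_table.loc[common, "delta_beta"]
        .groupby(probe_to_gene.loc[common])
        .mean()
    )
    order = sorted(per_gene.index, key=lambda g: (-per_gene[g], g))
    ranked = per_gene.loc[order]
    return preranked_gsea(ranked, process_sets, n_perm=n_perm, seed=seed)
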