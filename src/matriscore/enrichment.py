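"""Single-sample gene-set scoring and pre-ranked GSEA.

The per-sample scorer is a GSVA-style statistic for continuous (log2,
microarray-like) expression: for every gene a Gaussian-kernel ECDF value of
each sample against the gene's cross-sample distribution (bandwidth =
per-gene sd / 4), a per-sample ranking of genes by that statistic, the
symmetric rank weight |N/2 − rank|, and a weighted Kolmogorov–Smirnov-like
random walk down the ranked list.  The walk score is the signed sum of the
maximum positive and minimum negative deviation ("max.diff" convention),
and the full pathway × sample matrix is rescaled by its largest absolute
entry so scores lie in [-1, 1].  That final rescale is this package's
normalisation convention.

The ECM score is simply this score for the core-matrisome gene set.

Pre-ranked GSEA takes a log2-fold-change ranking, weights hits by |log2FC|
(exponent 1) and builds its null by gene-label permutation — appropriate
because the input is a ranked list rather than a sample matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "PathwayScoreMatrix",
    "GseaResult",
    "gsva_score",
    "ecm_score",
    "rank_by_log2fc",
    "preranked_gsea",
]

DEFAULT_SEED = 20210927


@dataclass
class PathwayScoreMatrix:
    """Pathways × samples single-sample enrichment scores."""

    scores: pd.DataFrame  # pathways x samples

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate pathway names")
        arr = self.scores.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("scores must be finite")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def row(self, name: str) -> pd.Series:
        return self.scores.loc[name]


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: tuple[str, ...]
    size: int


# ---------------------------------------------------------------------------
# kernel-ECDF single-sample scoring
# ---------------------------------------------------------------------------

def _kernel_ecdf(X: np.ndarray) -> np.ndarray:
    """Gaussian-kernel ECDF statistic z_ij per gene i, sample j.

    z_ij = mean_k Phi((x_ij - x_ik) / h_i) with bandwidth h_i = sd_i / 4.
    A gene with zero variance gets the neutral value 0.5 everywhere.
    """
    G, n = X.shape
    Z = np.empty_like(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    for i in range(G):
        if sd[i] <= 0:
            Z[i] = 0.5
        else:
            h = sd[i] / 4.0
            Z[i] = ndtr((X[i][:, None] - X[i][None, :]) / h).mean(axis=1)
    return Z


def _walk_scores(Z: np.ndarray, member: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Random-walk enrichment for one gene set over all samples.

    ``member`` is the boolean set-membership vector over genes.  Genes are
    ranked per sample by decreasing z (ties broken by gene order), set genes
    step up proportionally to |N/2 - rank|**tau, others step down uniformly.
    Returns max positive + min negative walk deviation per sample.
    """
    G, n = Z.shape
    m = int(member.sum())
    order = np.argsort(-Z, axis=0, kind="stable")  # G x n: gene index at each rank
    # rank weight depends only on position: |G/2 - (position+1)|
    pos_weight = np.abs(G / 2.0 - np.arange(1, G + 1)) ** tau
    in_set = member[order]  # G x n boolean in rank order
    hit_w = np.where(in_set, pos_weight[:, None], 0.0)
    hit_sum = hit_w.sum(axis=0)
    hit_sum[hit_sum == 0] = 1.0  # walk contributes nothing if all weights zero
    steps = hit_w / hit_sum - (~in_set) / float(G - m)
    walk = np.cumsum(steps, axis=0)
    return np.maximum(walk.max(axis=0), 0.0) + np.minimum(walk.min(axis=0), 0.0)


def gsva_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 2000,
    tau: float = 1.0,
    rescale: bool = True,
) -> PathwayScoreMatrix:
    """Score every gene set in every sample (kernel-ECDF random walk).

    Sets with fewer than ``min_size`` (or more than ``max_size``) genes
    present in the expression matrix are skipped with a warning; a set equal
    to the whole gene universe is an error (the non-set decrement is
    undefined).  With ``rescale`` the final matrix is divided by its largest
    absolute score so values lie in [-1, 1].
    """
    if expr.n_samples < 3:
        raise ValueError("gsva_score requires at least 3 samples")
    X = expr.values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    G = len(gene_index)

    Z = _kernel_ecdf(X)

    rows, names = [], []
    for gs in sets:
        idx = [gene_index[g] for g in gs.genes if g in gene_index]
        if len(idx) == G:
            raise ValueError(f"set {gs.name!r} equals the whole gene universe")
        if not (min_size <= len(idx) <= max_size):
            warnings.warn(
                f"set {gs.name!r}: {len(idx)} genes present, outside "
                f"[{min_size}, {max_size}] — skipped"
            )
            continue
        member = np.zeros(G, dtype=bool)
        member[idx] = True
        rows.append(_walk_scores(Z, member, tau=tau))
        names.append(gs.name)
    if not rows:
        raise ValueError("no gene set passed the size filter")
    scores = np.vstack(rows)
    if rescale:
        top = np.abs(scores).max()
        if top > 0:
            scores = scores / top
    return PathwayScoreMatrix(pd.DataFrame(scores, index=names, columns=expr.sample_ids))


def ecm_score(
    expr: ExpressionMatrix,
    core_matrisome_set: GeneSet,
    co_scored: GeneSetCollection | None = None,
    **cfg,
) -> pd.Series:
    """Per-sample ECM score: the single-sample score of the core matrisome set.

    When ``co_scored`` sets are given they are scored jointly (they share the
    final rescale), mirroring a run over a full pathway collection.
    """
    all_sets = {core_matrisome_set.name: core_matrisome_set}
    if co_scored is not None:
        for gs in co_scored:
            if gs.name != core_matrisome_set.name:
                all_sets[gs.name] = gs
    psm = gsva_score(expr, GeneSetCollection(all_sets), **cfg)
    if core_matrisome_set.name not in psm.pathway_names:
        raise ValueError("core matrisome set was filtered out (too few genes present)")
    out = psm.row(core_matrisome_set.name).copy()
    out.name = "ecm_score"
    return out


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def rank_by_log2fc(expr: ExpressionMatrix, group_a, group_b) -> pd.Series:
    """Per-gene mean(A) − mean(B) on the log2 scale, sorted decreasing.

    Ties are broken lexicographically by gene id.  Groups must be disjoint
    and contain at least two samples each.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    fc = expr.values[group_a].mean(axis=1) - expr.values[group_b].mean(axis=1)
    order = sorted(fc.index, key=lambda g: (-fc[g], g))
    out = fc.loc[order]
    out.name = "log2fc"
    return out


def _es_curve(weights: np.ndarray, hits: np.ndarray) -> tuple[float, int]:
    """Enrichment score of one hit pattern: signed deviation of max |deviation|."""
    N = len(weights)
    m = int(hits.sum())
    w_hit = np.where(hits, weights, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all-zero weights inside the set: uniform hit steps
        w_hit = hits.astype(float)
        denom = float(m)
    walk = np.cumsum(w_hit / denom - (~hits) / float(N - m))
    peak = int(np.argmax(np.abs(walk)))
    return float(walk[peak]), peak


def _null_es(weights: np.ndarray, m: int, n_perm: int, rng) -> np.ndarray:
    """Gene-label permutation null: random placements of m hits."""
    N = len(weights)
    null = np.empty(n_perm)
    miss_step = 1.0 / (N - m)
    for p in range(n_perm):
        idx = rng.choice(N, size=m, replace=False)
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        w_hit = np.where(hits, weights, 0.0)
        denom = w_hit.sum()
        if denom == 0:
            w_hit = hits.astype(float)
            denom = float(m)
        walk = np.cumsum(w_hit / denom - (~hits) * miss_step)
        null[p] = walk[np.argmax(np.abs(walk))]
    return null


def preranked_gsea(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = DEFAULT_SEED,
    weight_exponent: float = 1.0,
) -> list[GseaResult]:
    """Weighted KS enrichment on a pre-ranked gene list.

    Hit steps are weighted by |log2FC|**weight_exponent; the null comes from
    seeded gene-label permutation.  NES = ES / mean(|null ES| of matching
    sign); the empirical p is one-sided on matching sign with denominator
    (n_perm + 1); q is Benjamini–Hochberg within each ES sign.  Sets disjoint
    from the ranked list are skipped with a warning.
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = np.asarray(ranked.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    N = len(genes)

    results: list[GseaResult] = []
    raw: list[tuple[GeneSet, float, int, np.ndarray]] = []
    for gs in sets:
        idx = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if not idx:
            warnings.warn(f"set {gs.name!r} disjoint from ranked list — skipped")
            continue
        if len(idx) == N:
            warnings.warn(f"set {gs.name!r} covers the whole ranked list — skipped")
            continue
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        es, peak = _es_curve(weights, hits)
        null = _null_es(weights, len(idx), n_perm, rng)
        raw.append((gs, es, peak, null))

    records = []
    for gs, es, peak, null in raw:
        same_sign = null[null * es >= 0] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        # empirical p on |ES| against the whole permutation null: uniform
        # under the null and attains 1/(n_perm+1) for a maximal score
        more_extreme = int(np.sum(np.abs(null) >= abs(es)))
        p = (1 + more_extreme) / (n_perm + 1)
        hits = np.zeros(N, dtype=bool)
        hits[[gene_pos[g] for g in gs.genes if g in gene_pos]] = True
        if es >= 0:
            leading = tuple(genes[: peak + 1][hits[: peak + 1]])
        else:
            leading = tuple(genes[peak:][hits[peak:]])
        records.append((gs.name, es, nes, p, leading, int(hits.sum())))

    # BH within each sign
    qs = np.full(len(records), np.nan)
    for sign in (1, -1):
        idx = [i for i, r in enumerate(records) if np.sign(r[1]) == sign or (sign == 1 and r[1] == 0)]
        if idx:
            pvals = [records[i][3] for i in idx]
            qvals = multipletests(pvals, method="fdr_bh")[1]
            for i, q in zip(idx, qvals):
                qs[i] = q
    for (name, es, nes, p, leading, size), q in zip(records, qs):
        results.append(GseaResult(name, es, nes, p, float(q), leading, size))
    return results
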