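"""Consensus clustering of ECM-gene expression and partition agreement.

The consensus procedure repeatedly subsamples the samples, runs
agglomerative clustering (Euclidean distance, Ward linkage) on each
subsample, and records how often each sample pair lands in the same cluster
relative to how often it was co-sampled.  Features (rows) are z-scored
before distance computation so every gene contributes on the same scale.
The final assignment at each k comes from average-linkage hierarchical
clustering of the consensus dissimilarity (1 − consensus).

The number of clusters is chosen with the delta-area criterion on the CDF
of consensus values: the k after which the area gain collapses.  Agreement
between two partitions with arbitrary labels is measured by Cohen's kappa
after an optimal one-to-one class matching (assignment problem), with a
seeded permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

__all__ = ["ConsensusResult", "consensus_cluster", "select_k", "cohen_kappa"]

WEAK_STRUCTURE_PAC = 0.5


@dataclass
class ConsensusResult:
    consensus: dict[int, np.ndarray]        # k -> sample x sample matrix in [0,1]
    assignments: dict[int, np.ndarray]      # k -> integer labels (1..k)
    within_cluster_consensus: dict[int, float]
    k_range: tuple[int, ...]
    reps: int
    item_frac: float
    seed: int
    sample_ids: tuple[str, ...] = field(default=())

    def area_under_cdf(self, k: int) -> float:
        """Area under the empirical CDF of off-diagonal consensus values."""
        m = self.consensus[k]
        vals = np.sort(m[np.triu_indices_from(m, k=1)])
        if len(vals) == 0:
            return 0.0
        # A = sum over steps of CDF * width, on [0, 1]
        grid = np.concatenate([vals, [1.0]])
        cdf = np.arange(1, len(vals) + 1) / len(vals)
        widths = np.diff(np.concatenate([[0.0], grid]))
        return float(np.sum(np.concatenate([[0.0], cdf]) * widths))


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def consensus_cluster(
    X: np.ndarray,
    k_range=(2, 3, 4, 5, 6),
    reps: int = 200,
    item_frac: float = 0.8,
    seed: int = 0,
    sample_ids=None,
) -> ConsensusResult:
    """Consensus matrix + assignments for each k over subsampled Ward runs.

    ``X`` is features × samples.  Each rep draws ``item_frac`` of the
    samples without replacement, computes one Ward dendrogram and cuts it at
    every k in ``k_range``.  consensus[i, j] = co-cluster count / co-sample
    count; never-co-sampled pairs get 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    k_range = tuple(int(k) for k in k_range)
    n = X.shape[1]
    if n < 2 * max(k_range):
        raise ValueError("need at least 2*max(k) samples")
    if reps < 50:
        raise ValueError("reps must be >= 50")
    if not (0 < item_frac <= 1):
        raise ValueError("item_frac must be in (0, 1]")

    Xz = _zscore_rows(X)
    rng = np.random.default_rng(seed)
    n_sub = max(int(np.ceil(item_frac * n)), max(k_range))

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = Xz[:, idx].T  # samples x features
        lk = linkage(sub, method="ward")
        pair = np.ix_(idx, idx)
        co_sampled[pair] += 1
        for k in k_range:
            labels = fcluster(lk, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_clustered[k][pair] += same

    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pair(s) never co-sampled; "
            "their consensus is set to 0"
        )
    denom = np.where(co_sampled == 0, 1.0, co_sampled)

    consensus, assignments, within = {}, {}, {}
    for k in k_range:
        M = co_clustered[k] / denom
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        consensus[k] = M
        dist = squareform(1.0 - M, checks=False)
        labels = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
        assignments[k] = labels
        vals = []
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) > 1:
                sub = M[np.ix_(members, members)]
                vals.append(sub[np.triu_indices_from(sub, k=1)].mean())
        within[k] = float(np.mean(vals)) if vals else 1.0

    return ConsensusResult(
        consensus=consensus,
        assignments=assignments,
        within_cluster_consensus=within,
        k_range=k_range,
        reps=reps,
        item_frac=item_frac,
        seed=seed,
        sample_ids=tuple(sample_ids) if sample_ids is not None else (),
    )


def _pac(consensus: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus in (lo, hi)."""
    v = consensus[np.triu_indices_from(consensus, k=1)]
    return float(np.mean((v > lo) & (v < hi))) if len(v) else 0.0


def select_k(result: ConsensusResult) -> tuple[int, dict]:
    """Delta-area criterion: k after which the consensus-CDF area gain collapses.

    Relative area increments Δ(k) are computed per the standard convention
    (Δ(k_min) = A(k_min)); the chosen k maximizes the drop Δ(k) − Δ(k+1).
    Structureless data is flagged ``weak_structure`` when the proportion of
    ambiguous clustering (consensus entries in (0.1, 0.9)) at the chosen k
    exceeds 0.5 — real cluster structure drives consensus toward 0/1, so a
    mostly-intermediate consensus means the returned k is not meaningful.
    """
    ks = sorted(result.k_range)
    if len(ks) < 1:
        raise ValueError("empty k_range")
    areas = {k: result.area_under_cdf(k) for k in ks}
    if len(ks) == 1:
        k = ks[0]
        return k, {"areas": areas, "delta": {k: areas[k]},
                   "pac": _pac(result.consensus[k]),
                   "weak_structure": _pac(result.consensus[k]) > WEAK_STRUCTURE_PAC}
    delta = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        base = areas[prev] if areas[prev] > 0 else 1.0
        delta[k] = (areas[k] - areas[prev]) / base
    drop = {k: delta[k] - delta.get(k_next, 0.0)
            for k, k_next in zip(ks, ks[1:] + [None])}  # type: ignore[list-item]
    chosen = max(ks, key=lambda k: (drop[k], -k))
    pac = _pac(result.consensus[chosen])
    return chosen, {"areas": areas, "delta": delta, "drop": drop, "pac": pac,
                    "weak_structure": pac > WEAK_STRUCTURE_PAC}


# ---------------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------------

def _aligned_kappa(a: np.ndarray, b: np.ndarray, n_classes: int,
                   match: bool = True) -> float:
    table = np.zeros((n_classes, n_classes))
    np.add.at(table, (a, b), 1)
    if match:
        # optimal one-to-one class matching maximizing agreement
        r, c = linear_sum_assignment(-table)
    else:
        r = c = np.arange(n_classes)
    aligned = table[np.ix_(r, c)]
    n = table.sum()
    p_o = np.trace(aligned) / n
    rows = aligned.sum(axis=1) / n
    cols = aligned.sum(axis=0) / n
    p_e = float(np.sum(rows * cols))
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1 - p_e))


def cohen_kappa(labels_a, labels_b, n_perm: int = 2000, seed: int = 0,
                match_classes: bool = True) -> tuple[float, float]:
    """Cohen's kappa between two partitions, with a permutation p-value.

    With ``match_classes`` (the default, for cluster labels whose numbering
    is arbitrary) the contingency table is padded to square and classes are
    matched one-to-one by the assignment problem before computing
    kappa = (p_o − p_e)/(1 − p_e); this matching selects the best of k!
    alignments and therefore carries a small positive bias under the null
    (≈0.05 for three classes at n = 300).  Set ``match_classes=False`` when
    the two label spaces already correspond — the plain kappa is then
    exactly centered at 0 under independence.  The p-value permutes one
    labeling (``n_perm`` seeded shuffles, one-sided for agreement, with the
    same matching applied to every permutation).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    if ai.max() < 1 or bi.max() < 1:
        raise ValueError("both partitions need at least 2 classes")
    n_classes = max(ai.max(), bi.max()) + 1  # pad with empty classes

    kappa = _aligned_kappa(ai, bi, n_classes, match=match_classes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _aligned_kappa(ai, rng.permutation(bi), n_classes,
                          match=match_classes) >= kappa:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return kappa, float(p)
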