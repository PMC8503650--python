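"""Pathway-level prognostic screening, cross-cohort intersection, Spearman
correlation networks and degree-based hub discovery.

This is the route from "thousands of pathway scores" to "one dominant
program": every pathway score is screened with a univariate Cox model,
pathways prognostic in every cohort are intersected, the surviving pathways
are wired into a |Spearman rho| > threshold network per cohort, and the
hubs (highest-degree nodes) are ranked across cohorts.  The same machinery
runs at gene level to rank hub genes inside a gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SurvivalTable
from .survival_stats import best_cutpoint, cox_univariate, logrank_test

__all__ = [
    "prognostic_screen",
    "intersect_prognostic",
    "correlation_network",
    "hub_ranking",
    "HubRanking",
    "jaccard_index",
    "gene_hub_screen",
]

RISK, FAVORABLE, NON_PROGNOSTIC = "risk", "favorable", "non-prognostic"


def prognostic_screen(
    scores: pd.DataFrame,
    surv: SurvivalTable,
    alpha: float = 0.05,
    endpoint: str = "os",
    adjust: bool = False,
    emit_logrank: bool = False,
    minprop: float = 0.1,
) -> pd.DataFrame:
    """Univariate Cox screen of every pathway (row) against survival.

    Classification: ``risk`` if HR > 1 and p < alpha, ``favorable`` if
    HR < 1 and p < alpha, otherwise ``non-prognostic``.  The p used for
    classification is the unadjusted Cox Wald p; ``adjust`` adds a BH column
    and classifies on it instead.  ``emit_logrank`` additionally reports the
    log-rank p after a best-cutpoint dichotomization of each row (the
    optimistic post-selection p some studies quote).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    aligned = surv.aligned(scores.columns)
    t, e = aligned.endpoint(endpoint)
    if e.sum() < 2:
        raise ValueError("fewer than 2 events")

    rows = []
    for name, row in scores.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((name, np.nan, np.nan, np.nan, NON_PROGNOSTIC, True, np.nan))
            continue
        fit = cox_univariate(x, t, e)
        lr_p = np.nan
        if emit_logrank:
            try:
                cp = best_cutpoint(x, t, e, minprop=minprop)
                high = (x > cp.cutpoint).astype(int)
                _, lr_p, _ = logrank_test(t, e, high)
            except ValueError:
                lr_p = np.nan
        rows.append((name, fit.hr, fit.wald_p, fit.log2_hr, None, False, lr_p))

    df = pd.DataFrame(
        rows, columns=["pathway", "hr", "wald_p", "log2_hr",
                       "classification", "degenerate", "logrank_p"]
    ).set_index("pathway")
    pcol = "wald_p"
    if adjust:
        ok = df["wald_p"].notna()
        df.loc[ok, "q"] = multipletests(df.loc[ok, "wald_p"], method="fdr_bh")[1]
        pcol = "q"
    sig = df[pcol] < alpha
    df.loc[df["classification"].isna() & sig & (df["hr"] > 1), "classification"] = RISK
    df.loc[df["classification"].isna() & sig & (df["hr"] < 1), "classification"] = FAVORABLE
    df["classification"] = df["classification"].fillna(NON_PROGNOSTIC)
    if not emit_logrank:
        df = df.drop(columns=["logrank_p"])
    return df


def intersect_prognostic(screens: list[pd.DataFrame]) -> pd.DataFrame:
    """Pathways classified prognostic (risk or favorable) in every screen.

    Direction is NOT required to agree — a pathway risk in one cohort and
    favorable in another is retained but flagged ``direction_discordant``.
    Returns a DataFrame indexed by pathway with the flag column; the index
    is the intersected pathway set.
    """
    if len(screens) < 2:
        raise ValueError("need at least 2 screens")
    universe = screens[0].index
    for s in screens[1:]:
        if not universe.equals(s.index):
            universe = universe.intersection(s.index)
    if len(universe) == 0:
        raise ValueError("screens share no pathways")

    keep, discordant = [], []
    for name in universe:
        classes = [s.loc[name, "classification"] for s in screens]
        if all(c in (RISK, FAVORABLE) for c in classes):
            keep.append(name)
            discordant.append(len(set(classes)) > 1)
    return pd.DataFrame({"direction_discordant": discordant}, index=pd.Index(keep, name="pathway"))


def correlation_network(scores: pd.DataFrame, rho_threshold: float = 0.5) -> nx.Graph:
    """Thresholded Spearman correlation network over rows of a score matrix.

    Edge (u, v) iff |spearman rho| > threshold; the rho is stored as an edge
    attribute.  A constant row has undefined rho and is left isolated with a
    warning.  Requires ≥3 samples and ≥2 rows.
    """
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    arr = scores.to_numpy(dtype=float)
    names = list(scores.index)
    const = np.ptp(arr, axis=1) == 0
    if const.any():
        warnings.warn(
            f"constant row(s) left isolated (rho undefined): "
            f"{[n for n, c in zip(names, const) if c][:5]}"
        )

    g = nx.Graph()
    g.add_nodes_from(names)
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    for i in range(len(names)):
        if const[i]:
            continue
        for j in range(i + 1, len(names)):
            if const[j]:
                continue
            r = rho[i, j]
            if np.isfinite(r) and abs(r) > rho_threshold:
                g.add_edge(names[i], names[j], rho=float(r))
    return g


@dataclass
class HubRanking:
    per_cohort_top: dict[str, list[str]]
    intersection: set[str]
    mean_degree: pd.Series  # sorted decreasing, all nodes
    k: int


def _node_sort_key(g: nx.Graph):
    deg = dict(g.degree())

    def mean_abs_rho(u):
        rhos = [abs(d["rho"]) for _, _, d in g.edges(u, data=True)]
        return float(np.mean(rhos)) if rhos else 0.0

    return {u: (-deg[u], -mean_abs_rho(u), str(u)) for u in g.nodes}


def hub_ranking(networks: dict[str, nx.Graph], k: int = 10) -> HubRanking:
    """Top-k degree hubs per cohort plus the cross-cohort mean-degree ranking.

    Ties are broken by the mean |rho| of incident edges, then by name.
    ``k`` larger than the node universe is clamped with a warning.
    """
    cohorts = list(networks)
    universe = set(networks[cohorts[0]].nodes)
    for c in cohorts[1:]:
        if set(networks[c].nodes) != universe:
            raise ValueError("networks must share a node universe")
    if k > len(universe):
        warnings.warn(f"k={k} exceeds node count {len(universe)}; clamped")
        k = len(universe)

    per_cohort_top: dict[str, list[str]] = {}
    for c in cohorts:
        key = _node_sort_key(networks[c])
        ranked = sorted(universe, key=lambda u: key[u])
        per_cohort_top[c] = ranked[:k]

    inter = set(per_cohort_top[cohorts[0]])
    for c in cohorts[1:]:
        inter &= set(per_cohort_top[c])

    deg = pd.DataFrame(
        {c: pd.Series(dict(networks[c].degree())) for c in cohorts}
    ).mean(axis=1)
    tiebreak = pd.DataFrame(
        {c: pd.Series({u: -_node_sort_key(networks[c])[u][1] for u in universe})
         for c in cohorts}
    ).mean(axis=1)
    order = sorted(universe, key=lambda u: (-deg[u], -tiebreak[u], str(u)))
    mean_degree = deg.loc[order]
    mean_degree.name = "mean_degree"
    return HubRanking(per_cohort_top, inter, mean_degree, k)


def jaccard_index(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B| for two non-empty sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("jaccard_index requires non-empty sets")
    return len(a & b) / len(a | b)


def gene_hub_screen(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    rho_threshold: float = 0.5,
    k: int = 10,
    endpoint: str = "os",
) -> tuple[pd.DataFrame, HubRanking]:
    """Hub discovery + univariate Cox at gene level within a gene set.

    ``expr`` should already be restricted to the gene set of interest; its
    cohort labels define the per-cohort correlation networks.  The Cox table
    is fitted on the full (merged) sample set, sorted by Wald p.
    """
    networks = {
        label: correlation_network(sub.values, rho_threshold)
        for label, sub in expr.split_by_cohort().items()
    }
    hubs = hub_ranking(networks, k=k)

    aligned = surv.aligned(expr.sample_ids)
    t, e = aligned.endpoint(endpoint)
    rows = []
    for gene, row in expr.values.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, True))
            continue
        fit = cox_univariate(x, t, e)
        rows.append((gene, fit.beta, fit.hr, fit.se, fit.wald_p, False))
    table = pd.DataFrame(
        rows, columns=["gene", "beta", "hr", "se", "wald_p", "degenerate"]
    ).set_index("gene").sort_values("wald_p")
    return table, hubs
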