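"""End-to-end orchestration: simulate-or-load → score → screen → hubs →
cluster → cutpoint → chemo → omics, from a single config.

Each stage draws its randomness from a substream derived as
``SeedSequence([global_seed, STAGE_CODE])`` with a fixed per-stage code, so
toggling one stage never perturbs another's random numbers, and the summary
JSON is byte-identical for identical (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .chemo_response import benefit_test, chemo_stratify
from .clustering import cohen_kappa, consensus_cluster, select_k
from .enrichment import gsva_score
from .multiomics import cnv_burden, score_association, tmb_from_maf
from .screening_network import (
    correlation_network,
    hub_ranking,
    intersect_prognostic,
    prognostic_screen,
)
from .survival_stats import best_cutpoint, dichotomized_km
from .synthetic_data import SimConfig, SimData, simulate_multicohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("matriscore")

STAGE_CODES = {
    "simulate": 1, "score": 2, "screen": 3, "network": 4,
    "cluster": 5, "cutpoint": 6, "chemo": 7, "omics": 8,
}

_DEFAULTS = {
    "seed": 20210927,
    "out_dir": None,
    "simulate": {},          # SimConfig overrides; present => simulate
    "expression": None,      # or: list of paths to load
    "clinical": None,
    "gmt": None,
    "stages": {"screen": True, "network": True, "cluster": True,
               "cutpoint": True, "chemo": True, "omics": True},
    "alpha": 0.05,
    "rho_threshold": 0.5,
    "top_k": 10,
    "min_size": 5,
    "max_size": 2000,
    "minprop": 0.1,
    "cluster_reps": 200,
    "cluster_k_range": [2, 3, 4, 5, 6],
    "cluster_item_frac": 0.8,
    "kappa_perms": 2000,
    "cutpoint_source": "treated-subgroup",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults resolved up front)."""

    options: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        opts = {**_DEFAULTS, **raw}
        if "stages" in raw:
            bad = set(raw["stages"]) - set(_DEFAULTS["stages"])
            if bad:
                raise ValueError(f"unknown stage(s): {sorted(bad)}")
            opts["stages"] = {**_DEFAULTS["stages"], **raw["stages"]}
        if opts["simulate"] is None and opts["expression"] is None:
            raise ValueError("config must provide either 'simulate' or 'expression'")
        if opts["simulate"] is not None:
            SimConfig(**{**opts["simulate"], "seed": 0})  # validate overrides early
        return cls(opts)

    def __getitem__(self, key):
        return self.options[key]


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), STAGE_CODES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run all enabled stages; returns (and optionally writes) the summary.

    Outputs per stage are TSV; the summary JSON collects hub pathways,
    chosen k, the ECM cutpoint, per-stratum HRs and p-values.  A stage
    failure raises with the stage name; earlier outputs remain on disk.
    """
    opts = config.options
    out = Path(out_dir or opts["out_dir"] or ".")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(opts["seed"])
    summary: dict = {"seed": seed, "stages": []}
    stages = opts["stages"]
    timing_log = out / "run_log.txt"
    timing_fh = open(timing_log, "a")

    def _run(stage, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        dt = time.perf_counter() - t0
        summary["stages"].append(stage)
        timing_fh.write(f"{stage}\tseed={seed}\t{dt:.3f}s\n")
        log.info("stage %s: done in %.2fs", stage, dt)
        return result

    # --- inputs -----------------------------------------------------------
    if opts["simulate"] is not None:
        sim_cfg = SimConfig(**{"seed": _stage_seed(seed, "simulate"),
                               **opts["simulate"]})
        data: SimData = _run("simulate", lambda: simulate_multicohort(sim_cfg))
        cohorts = data.cohorts
        clinical = data.clinical
        gene_sets = data.gene_sets
        ecm_set_name = "PLANTED_MODULE"
    else:
        cohorts = [iof.read_expression(p, cohort=f"cohort{i}")
                   for i, p in enumerate(opts["expression"])]
        clinical = iof.read_clinical(opts["clinical"])
        gene_sets = iof.read_gmt(opts["gmt"])
        data = None
        ecm_set_name = gene_sets.names[0]

    merged = iof.merge_cohorts(cohorts) if len(cohorts) > 1 else cohorts[0]
    if merged.cohort_of_sample.nunique() > 1 and \
            merged.cohort_of_sample.value_counts().min() >= 3:
        merged = iof.batch_adjust(merged)

    # --- single-sample scoring -------------------------------------------
    scores = _run("score", lambda: gsva_score(
        merged, gene_sets, min_size=opts["min_size"], max_size=opts["max_size"]))
    scores.scores.to_csv(out / "pathway_scores.tsv", sep="\t")
    ecm = scores.row(ecm_set_name)
    summary["ecm_set"] = ecm_set_name

    surv = clinical.aligned(merged.sample_ids)
    t, e = surv.endpoint("os")

    # --- prognostic screen + intersection ---------------------------------
    if stages["screen"]:
        def _screen():
            per_cohort = []
            for label, cols in merged.cohort_of_sample.groupby(
                    merged.cohort_of_sample).groups.items():
                sub = scores.scores[list(cols)]
                per_cohort.append(prognostic_screen(sub, clinical,
                                                    alpha=opts["alpha"]))
            merged_screen = prognostic_screen(scores.scores, clinical,
                                              alpha=opts["alpha"])
            screens = per_cohort + [merged_screen]
            inter = (intersect_prognostic(screens)
                     if len(screens) >= 2 else merged_screen)
            return merged_screen, inter
        screen_tab, inter = _run("screen", _screen)
        screen_tab.to_csv(out / "screen.tsv", sep="\t")
        inter.to_csv(out / "prognostic_intersection.tsv", sep="\t")
        summary["n_prognostic_intersection"] = int(len(inter))
        summary["ecm_prognostic"] = bool(ecm_set_name in inter.index)

    # --- correlation network / hubs ---------------------------------------
    if stages["network"]:
        def _network():
            nets = {}
            for label, sub in merged.split_by_cohort().items():
                cols = sub.sample_ids
                nets[label] = correlation_network(scores.scores[cols],
                                                  opts["rho_threshold"])
            return hub_ranking(nets, k=opts["top_k"])
        hubs = _run("network", _network)
        hubs.mean_degree.to_csv(out / "hub_degree.tsv", sep="\t")
        summary["hub_top"] = str(hubs.mean_degree.index[0])
        summary["hub_intersection"] = sorted(map(str, hubs.intersection))

    # --- consensus clustering of module-gene expression -------------------
    if stages["cluster"]:
        module_genes = list(gene_sets[ecm_set_name].genes)
        sub = merged.values.loc[[g for g in module_genes
                                 if g in merged.values.index]]

        def _cluster():
            res = consensus_cluster(
                sub.to_numpy(), k_range=opts["cluster_k_range"],
                reps=opts["cluster_reps"], item_frac=opts["cluster_item_frac"],
                seed=_stage_seed(seed, "cluster"), sample_ids=sub.columns)
            k, info = select_k(res)
            return res, k, info
        res, k, info = _run("cluster", _cluster)
        assign = pd.Series(res.assignments[k], index=sub.columns,
                           name="ecm_cluster")
        assign.to_csv(out / "ecm_clusters.tsv", sep="\t")
        summary["chosen_k"] = int(k)
        summary["weak_structure"] = bool(info["weak_structure"])
        # agreement with a score-level partition (tertiles of the ECM score)
        tertiles = pd.qcut(ecm, 3, labels=False, duplicates="drop")
        if tertiles.nunique() >= 2 and assign.nunique() >= 2:
            kappa, kp = cohen_kappa(assign.to_numpy(), tertiles.to_numpy(),
                                    n_perm=opts["kappa_perms"],
                                    seed=_stage_seed(seed, "cluster") + 1)
            summary["cluster_vs_score_kappa"] = round(float(kappa), 6)
            summary["cluster_vs_score_kappa_p"] = float(kp)

    # --- cutpoint + dichotomized survival ---------------------------------
    if stages["cutpoint"]:
        def _cut():
            cp = best_cutpoint(ecm.to_numpy(), t, e, minprop=opts["minprop"])
            fit, p, _ = dichotomized_km(ecm.to_numpy(), cp.cutpoint, t, e)
            return cp, fit, p
        cp, fit, p = _run("cutpoint", _cut)
        summary["ecm_cutpoint"] = round(float(cp.cutpoint), 6)
        summary["ecm_high_vs_low_hr"] = round(float(fit.hr), 6)
        summary["ecm_high_vs_low_ci95"] = [round(float(v), 6) for v in fit.ci95]
        summary["ecm_logrank_p"] = float(p)

    # --- chemotherapy benefit ---------------------------------------------
    if stages["chemo"] and "chemo" in clinical.data.columns:
        def _chemo():
            strata = chemo_stratify(ecm, clinical.data["chemo"], clinical,
                                    cutpoint_source=opts["cutpoint_source"],
                                    minprop=opts["minprop"])
            return strata, benefit_test(strata, clinical)
        strata, benefit = _run("chemo", _chemo)
        strata.strata.to_csv(out / "chemo_strata.tsv", sep="\t")
        summary["chemo_cutpoint"] = round(float(strata.cutpoint), 6)
        for level, res in benefit.items():
            summary[f"chemo_{level.lower()}_logrank_p"] = float(res["logrank_p"])
            if res["cox"] is not None:
                summary[f"chemo_{level.lower()}_hr"] = round(float(res["cox"].hr), 6)
        summary["chemo_benefit_low_only"] = bool(
            benefit.get("Low", {}).get("logrank_p", 1.0) < opts["alpha"]
            and benefit.get("High", {}).get("logrank_p", 1.0) >= opts["alpha"]
        )

    # --- multi-omics couplings --------------------------------------------
    if stages["omics"] and data is not None:
        def _omics():
            tmb = tmb_from_maf(data.maf, sample_ids=merged.sample_ids)
            cnv = cnv_burden(data.cnv)
            return (score_association(ecm, tmb),
                    score_association(ecm, cnv))
        tmb_assoc, cnv_assoc = _run("omics", _omics)
        summary["tmb_spearman_rho"] = round(float(tmb_assoc["rho"]), 6)
        summary["tmb_spearman_p"] = float(tmb_assoc["rho_p"])
        summary["cnv_spearman_rho"] = round(float(cnv_assoc["rho"]), 6)

    timing_fh.close()
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
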