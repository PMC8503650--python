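"""Synthetic multi-cohort generator with planted ground truth.

Every downstream stage of the pipeline assumes a particular statistical
structure; this module generates data carrying exactly that structure so
the whole analysis is testable without any download:

* a standard-normal latent activity ``f`` per sample (the "ECM program"),
  shared across all coupled layers;
* a co-expressed gene module: module gene = loading·f + √(1−loading²)·noise
  on a log2-like baseline, everything else independent N(0, 1) background;
* additive per-cohort batch shifts (per-gene offsets drawn around a cohort
  mean), emulating multi-platform merging;
* exponential survival with hazard λ0·exp(β_f·f), administrative censoring
  at a configurable quantile of the event times;
* a chemotherapy flag whose multiplicative hazard effect θ_low applies only
  when f is below the interaction quantile (θ_high otherwise) — a threshold
  interaction mirroring a dichotomized benefit claim;
* per-sample mutation burden ~ Poisson(exp(a − b·f)) and copy-number calls
  whose alteration probability decreases with f (both negatively coupled to
  the latent activity);
* methylation beta values with planted island hypomethylation in high-f
  samples;
* gene sets: the planted module, overlapping sub-sets (for network degree
  structure) and random decoys.

All randomness flows from one ``numpy`` Generator seeded by the config;
identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SurvivalTable,
)

__all__ = ["SimConfig", "SimTruth", "SimData", "simulate_multicohort",
           "default_fixtures", "FIXTURE_CONFIGS"]


@dataclass
class SimConfig:
    """Planted parameters of a synthetic multi-cohort study.

    Defaults describe a mid-sized multi-cohort expression study: three
    cohorts of 200 samples, 1000 genes of which 60 form the co-expressed
    module (loading 0.8 → pairwise r ≈ 0.64), baseline hazard 0.02/month
    (median OS ≈ 35 months for f = 0), log-hazard 0.7 per latent sd,
    administrative censoring at the 0.7 event-time quantile (≈30% censored),
    40% treated with a protective ×0.5 hazard only below the latent median,
    and mutation burden Poisson(exp(3 − 1.2·f)).
    """

    n_cohorts: int = 3
    samples_per_cohort: tuple[int, ...] = (200, 200, 200)
    n_genes: int = 1000
    module_size: int = 60
    loading: float = 0.8
    baseline_expression: float = 8.0
    batch_shifts: tuple[float, ...] = (0.0, 1.0, -0.5)
    batch_shift_sd: float = 0.5
    batch_scales: tuple[float, ...] = (1.0, 1.0, 1.0)
    # survival
    lambda0: float = 0.02          # events per month at f = 0
    beta_f: float = 0.7            # log-hazard per latent sd
    weibull_shape: float = 1.0     # 1.0 = exponential baseline
    censor_quantile: float = 0.7
    # chemotherapy interaction
    treated_frac: float = 0.4
    theta_low: float = 0.5         # hazard multiplier under treatment, f < q_int
    theta_high: float = 1.0        # hazard multiplier under treatment, f >= q_int
    q_int: float = 0.5             # latent quantile below which theta_low applies
    # omics couplings
    tmb_intercept: float = 3.0
    tmb_slope: float = 1.2         # tmb ~ Poisson(exp(a - b*f + disp*eps))
    tmb_dispersion: float = 2.5    # hypermutator-like log-normal overdispersion
    n_cnv_genes: int = 200
    cnv_base_rate: float = 0.15
    cnv_slope: float = 0.8
    cnv_dispersion: float = 1.5    # per-sample alteration-propensity noise (logit sd)
    n_meth_probes: int = 500
    meth_island_frac: float = 0.4
    meth_delta_island: float = -0.2
    # gene sets
    n_subsets: int = 3
    subset_module_frac: float = 0.6
    n_decoys: int = 30
    decoy_size_range: tuple[int, int] = (20, 50)
    seed: int = 20210927

    def __post_init__(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort length must equal n_cohorts")
        if len(self.batch_shifts) != self.n_cohorts:
            raise ValueError("batch_shifts length must equal n_cohorts")
        if len(self.batch_scales) != self.n_cohorts:
            raise ValueError("batch_scales length must equal n_cohorts")
        if self.module_size >= self.n_genes:
            raise ValueError("module larger than gene universe")
        if not (0 <= self.loading < 1):
            raise ValueError("loading must be in [0, 1)")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        for name in ("treated_frac", "censor_quantile", "q_int"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulation: latent activity and all parameters."""

    config: SimConfig
    latent: pd.Series                 # f per sample
    module_genes: tuple[str, ...]
    true_stratum: pd.Series           # "low" / "high" latent stratum (q_int split)
    cohort_of_sample: pd.Series


@dataclass
class SimData:
    cohorts: list[ExpressionMatrix]
    clinical: SurvivalTable
    gene_sets: GeneSetCollection
    maf: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    probe_annotation: pd.DataFrame
    probe_to_gene: pd.Series
    truth: SimTruth

    def checksum(self) -> str:
        """SHA-256 over the expression blocks and survival columns."""
        h = hashlib.sha256()
        for c in self.cohorts:
            h.update(np.ascontiguousarray(c.values.to_numpy()).tobytes())
        h.update(self.clinical.data["os_time"].to_numpy(dtype=float).tobytes())
        h.update(self.clinical.data["os_event"].to_numpy(dtype=float).tobytes())
        return h.hexdigest()


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sample_names(cohort_idx: int, n: int) -> list[str]:
    return [f"C{cohort_idx}S{i:04d}" for i in range(n)]


def simulate_multicohort(config: SimConfig) -> SimData:
    """Generate a full synthetic study from a :class:`SimConfig`."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    module_genes = tuple(genes[: config.module_size])
    module_idx = np.arange(config.module_size)

    # latent activity and sample bookkeeping
    sample_ids: list[str] = []
    cohort_labels: list[str] = []
    for c, n_c in enumerate(config.samples_per_cohort):
        sample_ids.extend(_sample_names(c, n_c))
        cohort_labels.extend([f"cohort{c}"] * n_c)
    n = len(sample_ids)
    f = rng.standard_normal(n)
    latent = pd.Series(f, index=sample_ids, name="latent_f")
    cohort_series = pd.Series(cohort_labels, index=sample_ids, name="cohort")

    # expression, cohort by cohort, with additive batch structure
    cohorts: list[ExpressionMatrix] = []
    start = 0
    a = config.loading
    for c, n_c in enumerate(config.samples_per_cohort):
        sl = slice(start, start + n_c)
        eps = rng.standard_normal((config.n_genes, n_c))
        X = eps.copy()
        X[module_idx] = a * f[sl][None, :] + np.sqrt(1 - a**2) * eps[module_idx]
        gene_offsets = rng.normal(config.batch_shifts[c], config.batch_shift_sd,
                                  size=config.n_genes)
        X = (X * config.batch_scales[c]
             + config.baseline_expression + gene_offsets[:, None])
        cohorts.append(
            ExpressionMatrix(
                pd.DataFrame(X, index=genes, columns=sample_ids[sl]),
                cohort_series.iloc[sl],
            )
        )
        start += n_c

    # treatment assignment and latent stratum
    treated = (rng.random(n) < config.treated_frac).astype(int)
    f_cut = np.quantile(f, config.q_int)
    low = f < f_cut
    theta = np.where(treated == 1, np.where(low, config.theta_low,
                                            config.theta_high), 1.0)

    # survival: Weibull (shape 1 = exponential) hazard λ0·exp(β_f f)·θ
    rate = config.lambda0 * np.exp(config.beta_f * f) * theta
    u = rng.random(n)
    raw_t = (-np.log(u) / rate) ** (1.0 / config.weibull_shape)
    c_admin = np.quantile(raw_t, config.censor_quantile)
    os_time = np.minimum(raw_t, c_admin)
    os_event = (raw_t <= c_admin).astype(int)

    # relapse-free survival: same latent coupling, faster clock
    rate_rfs = 1.5 * rate
    raw_r = (-np.log(rng.random(n)) / rate_rfs) ** (1.0 / config.weibull_shape)
    c_rfs = np.quantile(raw_r, config.censor_quantile)
    rfs_time = np.minimum(raw_r, c_rfs)
    rfs_event = (raw_r <= c_rfs).astype(int)

    # ordinal stage loosely increasing with f
    stage_latent = f + rng.standard_normal(n) * 0.8
    stage = np.digitize(stage_latent, np.quantile(stage_latent, [0.25, 0.55, 0.85])) + 1

    clinical = SurvivalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "rfs_time": rfs_time,
                "rfs_event": rfs_event,
                "stage": stage,
                "chemo": treated,
                "cohort": cohort_labels,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    gene_sets = _build_gene_sets(config, rng, genes, module_genes)
    maf = _simulate_maf(config, rng, sample_ids, f, genes)
    cnv = _simulate_cnv(config, rng, sample_ids, f, genes)
    meth, annot, probe_to_gene = _simulate_methylation(config, rng, sample_ids,
                                                      f, f_cut, genes)

    truth = SimTruth(
        config=config,
        latent=latent,
        module_genes=module_genes,
        true_stratum=pd.Series(np.where(low, "low", "high"), index=sample_ids,
                               name="true_stratum"),
        cohort_of_sample=cohort_series,
    )
    return SimData(cohorts, clinical, gene_sets, maf, cnv, meth, annot,
                   probe_to_gene, truth)


def _build_gene_sets(config, rng, genes, module_genes) -> GeneSetCollection:
    background = genes[config.module_size:]
    sets: dict[str, GeneSet] = {
        "PLANTED_MODULE": GeneSet(
            "PLANTED_MODULE", "planted co-expressed module", module_genes, "module"
        )
    }
    n_from_module = max(2, int(round(config.subset_module_frac * len(module_genes))))
    for s in range(config.n_subsets):
        part = rng.choice(len(module_genes), size=n_from_module, replace=False)
        extra = rng.choice(len(background),
                           size=max(1, n_from_module // 3), replace=False)
        members = tuple(sorted({*(module_genes[i] for i in part),
                                *(background[i] for i in extra)}))
        name = f"MODULE_SUBSET_{s}"
        sets[name] = GeneSet(name, "overlapping planted sub-pathway", members,
                             "module-subset")
    lo, hi = config.decoy_size_range
    lo = min(lo, len(background) - 1)
    hi = min(hi, len(background) - 1)
    for d in range(config.n_decoys):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(background), size=size, replace=False)
        name = f"DECOY_{d:03d}"
        sets[name] = GeneSet(name, "random decoy set",
                             tuple(sorted(background[i] for i in idx)), "decoy")
    return GeneSetCollection(sets)


def _simulate_maf(config, rng, sample_ids, f, genes) -> pd.DataFrame:
    eps = rng.standard_normal(len(sample_ids))
    log_rate = (config.tmb_intercept - config.tmb_slope * f
                + config.tmb_dispersion * eps)
    tmb = rng.poisson(np.exp(np.clip(log_rate, None, 8.0)))
    silent_extra = rng.poisson(2.0, size=len(sample_ids))
    classes = np.array(["Missense_Mutation", "Nonsense_Mutation",
                        "Frame_Shift_Del", "Splice_Site"])
    gene_arr = np.asarray(genes)
    sample_arr = np.asarray(sample_ids)
    n_nonsilent = int(tmb.sum())
    n_silent = int(silent_extra.sum())
    barcodes = np.concatenate([np.repeat(sample_arr, tmb),
                               np.repeat(sample_arr, silent_extra)])
    hugo = gene_arr[rng.integers(len(gene_arr), size=n_nonsilent + n_silent)]
    vclass = np.concatenate([
        classes[rng.integers(len(classes), size=n_nonsilent)],
        np.repeat("Silent", n_silent),
    ])
    return pd.DataFrame(
        {"Hugo_Symbol": hugo, "Tumor_Sample_Barcode": barcodes,
         "Variant_Classification": vclass}
    )


def _simulate_cnv(config, rng, sample_ids, f, genes) -> pd.DataFrame:
    n = len(sample_ids)
    base_logit = np.log(config.cnv_base_rate / (1 - config.cnv_base_rate))
    eps = rng.standard_normal(n)
    p_alt = 1.0 / (1.0 + np.exp(-(base_logit - config.cnv_slope * f
                                  + config.cnv_dispersion * eps)))
    altered = rng.random((config.n_cnv_genes, n)) < p_alt[None, :]
    sign = rng.choice([-1, 1], size=(config.n_cnv_genes, n))
    magnitude = np.where(rng.random((config.n_cnv_genes, n)) < 0.2, 2, 1)
    calls = np.where(altered, sign * magnitude, 0)
    return pd.DataFrame(calls, index=genes[: config.n_cnv_genes],
                        columns=sample_ids)


def _simulate_methylation(config, rng, sample_ids, f, f_cut, genes):
    n = len(sample_ids)
    n_probes = config.n_meth_probes
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    n_island = int(round(config.meth_island_frac * n_probes))
    status = np.array(["Island"] * n_island
                      + list(rng.choice(["Shore", "Shelf", "OpenSea"],
                                        size=n_probes - n_island)))
    regions = rng.choice(["TSS1500", "TSS200", "5'UTR", "1stExon", "Body",
                          "3'UTR"], size=n_probes)
    base = rng.beta(2, 2, size=n_probes)
    noise = rng.normal(0, 0.05, size=(n_probes, n))
    beta = base[:, None] + noise
    high = (f >= f_cut)
    island = status == "Island"
    beta[np.ix_(island, high)] += config.meth_delta_island
    beta = np.clip(beta, 0.0, 1.0)
    annot = pd.DataFrame(
        {"region": regions, "island_status": status},
        index=pd.Index(probes, name="probe_id"),
    )
    probe_to_gene = pd.Series(
        [genes[i % len(genes)] for i in range(n_probes)],
        index=annot.index, name="gene",
    )
    meth = pd.DataFrame(beta, index=annot.index, columns=sample_ids)
    return meth, annot, probe_to_gene


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

FIXTURE_CONFIGS: dict[str, SimConfig] = {
    # planted prognostic module, no differential chemo effect
    "prognostic": SimConfig(
        n_cohorts=3, samples_per_cohort=(150, 150, 150), n_genes=600,
        theta_low=1.0, theta_high=1.0, seed=11,
    ),
    # chemo benefit only below the latent median
    "interaction": SimConfig(
        n_cohorts=1, samples_per_cohort=(600,), n_genes=600,
        batch_shifts=(0.0,), batch_scales=(1.0,),
        theta_low=0.5, theta_high=1.0, seed=12,
    ),
    # no survival signal, no module co-expression
    "null": SimConfig(
        n_cohorts=3, samples_per_cohort=(150, 150, 150), n_genes=600,
        loading=0.0, beta_f=0.0, theta_low=1.0, theta_high=1.0,
        tmb_slope=0.0, cnv_slope=0.0, meth_delta_island=0.0, seed=13,
    ),
}

# frozen SHA-256 checksums of the fixtures (expression + OS columns)
FIXTURE_CHECKSUMS: dict[str, str] = {
    "prognostic": "d295ae6c224cc9c3194fc5a8958eb4891a58bf31e60ce5c8582540a4b029da80",
    "interaction": "0aff60715f40d6c6c08687ff5b08b10f191392519ab75423be1685d075d21add",
    "null": "6a095a0e06e8d88354fa9cdf9cf39892a089de8799ddbf9af1addc72178e09f5",
}


def default_fixtures(verify: bool = True) -> dict[str, SimData]:
    """The three canned study fixtures: "prognostic", "interaction", "null".

    Regenerated deterministically from fixed seeds; with ``verify`` the
    result is checked against the frozen checksums.
    """
    out = {}
    for name, cfg in FIXTURE_CONFIGS.items():
        data = simulate_multicohort(cfg)
        if verify and FIXTURE_CHECKSUMS.get(name):
            got = data.checksum()
            if got != FIXTURE_CHECKSUMS[name]:
                raise RuntimeError(
                    f"fixture {name!r} checksum mismatch: {got}"
                )
        out[name] = data
    return out
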