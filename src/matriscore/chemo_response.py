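"""Chemotherapy-benefit stratification by ECM score.

The headline analysis: estimate the best ECM-score cutpoint (by default on
the chemotherapy-treated subgroup, whose prognosis the cutpoint is meant to
separate), stratify all samples into Chemo±/ECM-high and Chemo±/ECM-low,
and test treated-vs-untreated survival within each ECM stratum.  A benefit
confined to the ECM-low stratum reproduces the pattern in which patients
with low ECM-program expression respond to chemotherapy while high-ECM
patients do not.

A formal treatment × score Cox interaction Wald p is also available as
supplementary output; stratified log-rank tests are the primary readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SurvivalTable
from .survival_stats import (
    CoxFit,
    best_cutpoint,
    cox_univariate,
    kaplan_meier,
    logrank_test,
)

__all__ = ["ChemoStrata", "chemo_stratify", "benefit_test",
           "interaction_test", "subgroup_forest"]

STRATA = ("Chemo+/High", "Chemo-/High", "Chemo+/Low", "Chemo-/Low")
MIN_TREATED = 20


@dataclass
class ChemoStrata:
    strata: pd.Series             # sample -> stratum label
    cutpoint: float
    cutpoint_source: str          # "treated-subgroup" | "full-cohort"
    max_statistic: float

    def counts(self) -> pd.Series:
        return self.strata.value_counts().reindex(STRATA, fill_value=0)


def chemo_stratify(
    score: pd.Series,
    chemo: pd.Series,
    surv: SurvivalTable,
    cutpoint_source: str = "treated-subgroup",
    endpoint: str = "os",
    minprop: float = 0.1,
) -> ChemoStrata:
    """Estimate the ECM cutpoint and stratify samples by chemo × ECM level.

    The cutpoint is computed on the designated subgroup (treated samples by
    default) and then applied to every sample with a known chemo flag.  A
    treated subgroup smaller than 20 is an error suggesting the full-cohort
    source.
    """
    if cutpoint_source not in ("treated-subgroup", "full-cohort"):
        raise ValueError(f"unknown cutpoint_source {cutpoint_source!r}")
    common = score.index.intersection(chemo.dropna().index)
    score = score.loc[common]
    chemo_flags = chemo.loc[common].astype(int)
    aligned = surv.aligned(common)
    t, e = aligned.endpoint(endpoint)

    if cutpoint_source == "treated-subgroup":
        mask = chemo_flags.to_numpy() == 1
        if mask.sum() < MIN_TREATED:
            raise ValueError(
                f"treated subgroup has {int(mask.sum())} samples (< {MIN_TREATED}); "
                "use cutpoint_source='full-cohort'"
            )
    else:
        mask = np.ones(len(common), dtype=bool)
    cp = best_cutpoint(score.to_numpy()[mask], t[mask], e[mask], minprop=minprop)

    high = score > cp.cutpoint
    labels = np.where(
        chemo_flags.to_numpy() == 1,
        np.where(high, "Chemo+/High", "Chemo+/Low"),
        np.where(high, "Chemo-/High", "Chemo-/Low"),
    )
    return ChemoStrata(
        strata=pd.Series(labels, index=common, name="stratum"),
        cutpoint=cp.cutpoint,
        cutpoint_source=cutpoint_source,
        max_statistic=cp.max_statistic,
    )


def benefit_test(strata: ChemoStrata, surv: SurvivalTable,
                 endpoint: str = "os", compute_km: bool = True) -> dict[str, dict]:
    """Treated-vs-untreated survival comparison within each ECM stratum.

    For each of "High" and "Low": log-rank (chi2, p), Kaplan–Meier curves
    per arm (skippable with ``compute_km=False`` for bulk simulation), and
    the univariate Cox fit of the chemo indicator (HR < 1 means
    chemotherapy benefit).  A stratum with an empty arm or no events is
    skipped with a warning.
    """
    aligned = surv.aligned(strata.strata.index)
    t, e = aligned.endpoint(endpoint)
    out: dict[str, dict] = {}
    labels = strata.strata.to_numpy()
    for level in ("High", "Low"):
        treated = labels == f"Chemo+/{level}"
        untreated = labels == f"Chemo-/{level}"
        if treated.sum() == 0 or untreated.sum() == 0:
            warnings.warn(f"ECM {level}: an arm is empty — test skipped")
            continue
        sel = treated | untreated
        if e[sel].sum() == 0:
            warnings.warn(f"ECM {level}: no events — test skipped")
            continue
        chi2, p, _ = logrank_test(t[sel], e[sel], treated[sel].astype(int))
        try:
            fit: CoxFit | None = cox_univariate(
                treated[sel].astype(float), t[sel], e[sel]
            )
        except ValueError:
            fit = None
        out[level] = {
            "logrank_chi2": chi2,
            "logrank_p": p,
            "cox": fit,
            "n_treated": int(treated.sum()),
            "n_untreated": int(untreated.sum()),
            "km": {
                "treated": kaplan_meier(t[treated], e[treated]),
                "untreated": kaplan_meier(t[untreated], e[untreated]),
            } if compute_km else None,
        }
    return out


def interaction_test(strata: ChemoStrata, surv: SurvivalTable,
                     endpoint: str = "os") -> float:
    """Supplementary Cox Wald p for the chemo × ECM-level interaction.

    Fits h(t) ∝ exp(b1·chemo + b2·high + b3·chemo·high) via lifelines and
    returns the Wald p of b3.  This is a formal interaction test the
    stratified log-rank readout does not provide.
    """
    from lifelines import CoxPHFitter

    aligned = surv.aligned(strata.strata.index)
    t, e = aligned.endpoint(endpoint)
    labels = strata.strata.astype(str)
    df = pd.DataFrame(
        {
            "time": t,
            "event": e,
            "chemo": labels.str.startswith("Chemo+").astype(float).to_numpy(),
            "high": labels.str.endswith("High").astype(float).to_numpy(),
        }
    )
    df["chemo_x_high"] = df["chemo"] * df["high"]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.summary.loc["chemo_x_high", "p"])


def subgroup_forest(subsets, minprop: float = 0.1,
                    endpoint: str = "os") -> pd.DataFrame:
    """Per-subset dichotomized hazard ratio table (forest-plot input).

    ``subsets`` is a list of ``(label, score: pd.Series, surv:
    SurvivalTable)``.  Each subset gets its own best cutpoint and the
    high-vs-low Cox HR with 95% CI; a subset failing a precondition (e.g.
    zero events) produces an NA row carrying the reason.
    """
    from .survival_stats import dichotomized_km

    rows = []
    for label, score, surv in subsets:
        aligned = surv.aligned(score.index)
        t, e = aligned.endpoint(endpoint)
        try:
            cp = best_cutpoint(score.to_numpy(), t, e, minprop=minprop)
            fit, p, _ = dichotomized_km(score.to_numpy(), cp.cutpoint, t, e)
            rows.append((label, fit.hr, fit.ci95[0], fit.ci95[1], p,
                         len(score), int(e.sum()), cp.cutpoint, ""))
        except ValueError as err:
            rows.append((label, np.nan, np.nan, np.nan, np.nan,
                         len(score), int(e.sum()), np.nan, str(err)))
    return pd.DataFrame(
        rows,
        columns=["subset", "hr", "ci_lo", "ci_hi", "logrank_p",
                 "n", "n_events", "cutpoint", "note"],
    ).set_index("subset")
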