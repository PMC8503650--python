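import warnings

import numpy as np
import pandas as pd
import pytest

from matriscore.io_formats import ExpressionMatrix
from matriscore.synthetic_data import SimConfig, simulate_multicohort


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # intentional data-quality warnings (skipped sets, isolated nodes, ...)
    # are asserted explicitly where they matter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_sim():
    """One mid-sized single-cohort simulation shared by read-only tests."""
    cfg = SimConfig(
        n_cohorts=1, samples_per_cohort=(400,), n_genes=300, module_size=30,
        batch_shifts=(0.0,), batch_scales=(1.0,), n_decoys=8,
        n_meth_probes=200, n_cnv_genes=80, seed=101,
    )
    return simulate_multicohort(cfg)


@pytest.fixture(scope="session")
def multi_sim():
    """Three-cohort simulation with batch structure, shared by read-only tests."""
    cfg = SimConfig(
        n_cohorts=3, samples_per_cohort=(150, 150, 150), n_genes=300,
        module_size=30, batch_shifts=(0.0, 1.5, -1.0),
        batch_scales=(1.0, 1.0, 1.0), n_decoys=8,
        n_meth_probes=150, n_cnv_genes=60, seed=202,
    )
    return simulate_multicohort(cfg)


def random_expression(rng, n_genes, n_samples, prefix="G"):
    return ExpressionMatrix(
        pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"{prefix}{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )


def exponential_survival(rng, n, rate=0.05, hr_covariate=None, beta=0.0,
                         censor_quantile=0.75):
    """Exponential survival with optional log-hazard covariate; returns t, e."""
    lin = beta * hr_covariate if hr_covariate is not None else 0.0
    t = rng.exponential(1.0 / (rate * np.exp(lin)))
    if censor_quantile is None:
        return t, np.ones(n, dtype=int)
    c = np.quantile(t, censor_quantile)
    return np.minimum(t, c), (t <= c).astype(int)
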