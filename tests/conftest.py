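"""Shared fixtures: the default synthetic dataset and pipeline outputs.

Heavy artifacts (default dataset, QC cascade, taxonomy) are session-
scoped so the acceptance-level tests share one computation.
"""

import warnings

import numpy as np
import pytest

from striatax import qc, synthetic
from striatax.config import GeneratorConfig, PopulationSpec, QCThresholds
from striatax.pipeline import classify_cells, default_pipeline_config


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 14 subclasses + glia + MSN, 5% doublets."""
    return synthetic.simulate_default(seed=0)


@pytest.fixture(scope="session")
def qc_output(default_dataset):
    counts, _truth = default_dataset
    cfg = default_pipeline_config(seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, funnel, types = qc.run_qc_cascade(counts, cfg.qc, seed=0)
    return filtered, funnel, types


@pytest.fixture(scope="session")
def taxonomy_output(qc_output):
    filtered, _, _ = qc_output
    cfg = default_pipeline_config(seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return classify_cells(filtered, cfg.taxonomy, cfg.qc, seed=0)


def small_config(
    n_pops=2,
    n_genes=400,
    cells_per_sample=250,
    seed=0,
    marker_log_fold=6.0,
    heterogeneity=1.2,
    samples=None,
    **kwargs,
):
    """A small two-region config with well-separated populations."""
    pops = []
    for i in range(n_pops):
        pops.append(
            PopulationSpec(
                name=f"P{i}",
                marker_genes=[f"GENE{j + 1:05d}" for j in range(10 * i, 10 * i + 10)],
                marker_log_fold=marker_log_fold,
                proportion_by_region={"CN": 1 / n_pops, "Pu": 1 / n_pops},
                correlation_block=i,
            )
        )
    samples = samples or [("CN1", "CN"), ("Pu1", "Pu")]
    return GeneratorConfig(
        n_genes=n_genes,
        populations=pops,
        samples=samples,
        cells_per_sample=cells_per_sample,
        heterogeneity_sigma=heterogeneity,
        seed=seed,
        **kwargs,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
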