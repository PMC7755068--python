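"""Shared fixtures: synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

import wheatgp as wg


@pytest.fixture(scope="session")
def small_sim():
    """80-line, 300-marker, 3-environment dataset for structural tests."""
    cfg = wg.SimConfig(n_founders=10, n_lines=80, n_generations=3,
                       n_markers=300, n_chromosomes=5, n_environments=3,
                       n_replicates=4, seed=1)
    return wg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def big_sim():
    """Study-scale dataset: 600 lines x 3 environments x 5 replicates at the
    combined anther-count variance components (panel scaled to 2,000 SNPs
    for runtime)."""
    cfg = wg.SimConfig(n_lines=600, n_markers=2000, seed=1)
    return wg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def big_blue_records(big_sim):
    """Per-environment BLUEs of the study-scale dataset as model records."""
    blues = wg.compute_blues(big_sim.records, "AC")
    rec = blues.rename(columns={"blue": "value"}).assign(replicate="blue")
    return rec[["line", "environment", "replicate", "trait", "value"]]


@pytest.fixture(scope="session")
def big_g_kernel(big_sim):
    filtered = wg.filter_markers(big_sim.markers)
    return wg.genomic_relationship(wg.impute_missing(filtered),
                                   scale="vanraden")


@pytest.fixture()
def toy_records():
    """Balanced 3 lines x 2 environments x 2 replicates."""
    rows = []
    rng = np.random.default_rng(0)
    for line in ["l1", "l2", "l3"]:
        for env in ["e1", "e2"]:
            for rep in ["r1", "r2"]:
                rows.append((line, env, rep, "AC", float(rng.normal(50, 5))))
    return pd.DataFrame(rows, columns=["line", "environment", "replicate",
                                       "trait", "value"])
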