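import numpy as np
import pandas as pd
import pytest

from daarep import CountDataset, SimulationConfig, simulate_dataset, simulate_null_dataset
from daarep.datasets import CASE, CONTROL, GROUP_COLUMN


def make_dataset(counts, case_mask, taxon_ids=None, covariates=None):
    """Assemble a CountDataset from a raw array and a boolean case mask."""
    counts = np.asarray(counts)
    t, n = counts.shape
    taxon_ids = taxon_ids or [f"t{i}" for i in range(t)]
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {GROUP_COLUMN: np.where(case_mask, CASE, CONTROL)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if covariates is not None:
        for name, values in covariates.items():
            meta[name] = values
    return CountDataset(
        counts=pd.DataFrame(counts, index=pd.Index(taxon_ids, name="taxon_id"), columns=sample_ids),
        metadata=meta,
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def signal_dataset():
    """Default-sized simulated dataset with planted effects."""
    ds, truth = simulate_dataset(SimulationConfig(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null simulated dataset (no differential taxa)."""
    ds, truth = simulate_null_dataset(SimulationConfig(seed=12))
    return ds, truth


@pytest.fixture(scope="session")
def small_dataset():
    """Small dataset for fast per-taxon model checks."""
    ds, _ = simulate_dataset(
        SimulationConfig(n_case=20, n_control=20, n_taxa=40, seed=13)
    )
    return ds
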