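"""Shared fixtures: one mid-size simulated dataset reused across modules."""

import numpy as np
import pandas as pd
import pytest

from lenscape.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=300,
        n_peaks=900,
        chrom_sizes={"chr1": 3_000_000, "chr2": 2_000_000},
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genes, rna, atac, peaks, truth) at a scale that runs in seconds."""
    genes = simulate_annotation(small_config)
    rna, atac, peaks, truth = simulate_counts(small_config, genes)
    return genes, rna, atac, peaks, truth


@pytest.fixture()
def tiny_counts():
    """A hand-sized count matrix with two conditions, two replicates each."""
    from lenscape.io import CountMatrix

    counts = pd.DataFrame(
        {
            "rna_IMD_1": [10, 100, 40, 7],
            "rna_IMD_2": [12, 90, 44, 9],
            "rna_D0_1": [11, 95, 400, 8],
            "rna_D0_2": [10, 105, 360, 8],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    meta = pd.DataFrame(
        {
            "condition": ["IMD", "IMD", "D0", "D0"],
            "replicate": [1, 2, 1, 2],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, meta)
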