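import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fibroscope import CountMatrix, SimulationConfig, simulate_cohorts


@pytest.fixture
def tiny_count_matrix() -> CountMatrix:
    """3 cells × 4 genes, hand-checkable, including a mito gene."""
    counts = np.array(
        [
            [0, 1, 2, 0],
            [3, 0, 0, 1],
            [1, 1, 1, 1],
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2"],
            "cohort_id": ["c1", "c1", "c1"],
            "disease_status": ["control", "control", "ILD"],
            "cell_type": ["A", "B", "A"],
        }
    )
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=np.array(["cell1", "cell2", "cell3"], dtype=object),
        gene_ids=np.array(["G1", "G2", "MT-ND1", "G3"], dtype=object),
        cell_meta=meta,
    )
    return cm.validate()


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_cohorts=3,
        samples_per_cohort_per_arm=3,
        cells_per_sample=(50, 70),
        n_genes=400,
        n_proteins=120,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def simulated_cohort():
    """One medium simulated dataset shared across read-only tests."""
    cfg = SimulationConfig(
        n_cohorts=3,
        samples_per_cohort_per_arm=4,
        cells_per_sample=(60, 90),
        n_genes=500,
        n_proteins=150,
    )
    cm, samples, truth = simulate_cohorts(cfg, seed=11)
    return cm, samples, truth
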