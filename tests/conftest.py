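import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from clonescape.io import CountMatrix, LRPair, LigandReceptorDB, flag_genes
from clonescape.simulate import SimulationConfig, simulate_counts


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 4 cells, deterministic, with one mitochondrial gene."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 4],
            [1, 1, 1, 0],
        ]
    )
    genes = ["GENE1", "GENE2", "MT-ND1"]
    cells = ["c1", "c2", "c3", "c4"]
    return CountMatrix(sp.csr_matrix(counts), genes, cells)


@pytest.fixture
def small_db() -> LigandReceptorDB:
    return LigandReceptorDB(
        [
            LRPair("L1", "R1"),
            LRPair("L2", "R2"),
            LRPair("L3", "R3", subunits=("R3A", "R3B")),
            LRPair("L4", "R4"),
        ]
    )


@pytest.fixture(scope="session")
def clustered_sim():
    """Two clusters of 80 cells with planted markers; reused across tests."""
    cfg = SimulationConfig(
        n_clusters=2,
        cells_per_cluster=80,
        n_genes=120,
        baseline_mean=2.0,
        nb_dispersion=0.4,
        marker_spec={"C0": [("G0005", 8.0), ("G0006", 6.0)],
                     "C1": [("G0010", 8.0)]},
        seed=11,
    )
    m, truth = simulate_counts(cfg)
    return m, truth, cfg
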