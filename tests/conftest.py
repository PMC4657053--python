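import numpy as np
import pandas as pd
import pytest

from lineagescore.containers import (
    ChannelMode,
    ExpressionMatrix,
    LineageWeightSet,
    ReplicateMap,
)
from lineagescore.simulate import SimConfig, simulate_cohort, simulate_lineages


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal compendium + cohort shared across tests."""
    cfg = SimConfig(
        n_genes=300, n_celltypes=5, module_size=10, n_patients=40, seed=11
    )
    lineages, reps, truth = simulate_lineages(cfg)
    patients, clinical = simulate_cohort(cfg, truth)
    return cfg, lineages, reps, truth, patients, clinical


@pytest.fixture
def toy_reference():
    """3-gene, 2-cell-type (2 replicates each) raw reference matrix."""
    df = pd.DataFrame(
        {
            "A#1": [5.0, 1.0, 3.0],
            "A#2": [5.2, 1.2, 3.1],
            "B#1": [1.0, 5.0, 3.0],
            "B#2": [0.8, 5.1, 2.9],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(df, ChannelMode.REFERENCE), ReplicateMap.infer(df.columns)


def constant_weight_set(genes, cell_types, up=0.4, down=0.3):
    """Weight set with constant entries, bypassing the prep pipeline."""
    u = pd.DataFrame(up, index=genes, columns=cell_types, dtype=float)
    d = pd.DataFrame(down, index=genes, columns=cell_types, dtype=float)
    return LineageWeightSet(u, d)
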