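import numpy as np
import pandas as pd
import pytest

from syndromirnet import ExpressionMatrix, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_mirnas=100,
        n_genes=300,
        group_sizes={"Normal": 7, "LGDHS": 3},
        n_de_per_group=10,
        de_log2fc=1.0,
        n_gene_sets=10,
        planted_enriched_sets=2,
        gene_set_size=(10, 30),
        seed=1,
    )


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    ids = [f"miR-{i}" for i in range(50)]
    samples = [f"A_{i}" for i in range(4)] + [f"B_{i}" for i in range(4)]
    groups = pd.Series({s: s.split("_")[0] for s in samples})
    values = pd.DataFrame(rng.normal(8, 1, size=(50, 8)), index=ids, columns=samples)
    return ExpressionMatrix(values=values, groups=groups)
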