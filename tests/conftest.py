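import numpy as np
import pandas as pd
import pytest

import cryogill as cg


def make_table(ant_values, oth_values, orthologs=None):
    """Build a small OrthologExpressionTable from per-group value arrays
    (orthologs x species)."""
    ant = np.atleast_2d(np.asarray(ant_values, dtype=float))
    oth = np.atleast_2d(np.asarray(oth_values, dtype=float))
    n = ant.shape[0]
    orthologs = orthologs or [f"og{i}" for i in range(n)]
    cols = {f"ant_{j}": ant[:, j] for j in range(ant.shape[1])}
    cols.update({f"oth_{j}": oth[:, j] for j in range(oth.shape[1])})
    values = pd.DataFrame(cols, index=orthologs)
    groups = pd.Series(
        {c: ("antarctic" if c.startswith("ant") else "other") for c in values.columns}
    )
    return cg.OrthologExpressionTable(values=values, groups=groups)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic cross-species dataset (6 vs 8 species,
    2000 orthologs, 5% planted at fold 10, noise_sd 0.3) at a fixed seed,
    with the assembled ortholog table and full DEG analysis."""
    params = cg.SimulationParams(seed=1)
    matrices, config, truth = cg.simulate_cross_species(params)
    table = cg.build_ortholog_table(
        matrices, cg.identity_membership(matrices), config
    )
    deg = cg.differential_expression(table)
    return {
        "params": params,
        "matrices": matrices,
        "config": config,
        "truth": truth,
        "table": table,
        "deg": deg,
    }


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic 5-tissue panel with planted gill-specific
    genes at fold 50, fixed seed."""
    panel, truth = cg.simulate_tissue_panel(seed=1)
    return panel, truth
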