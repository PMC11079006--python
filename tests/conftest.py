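import numpy as np
import pandas as pd
import pytest

from regage.core_io import ExpressionMatrix
from regage.synthdata import SimulationConfig, simulate_all


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down study used where full-size power is not under test."""
    base = dict(
        n_genes=300,
        n_samples_per_condition=(8, 3),
        n_regulons=2,
        regulon_roles=[{"role": "repressor", "condition": "aged"}] * 2,
        targets_per_regulon=20,
        planted_rank_quantile=0.1,
        motif_db_size=40,
        n_cells_per_group=60,
        sc_min_genes=100,
        n_mirnas=12,
        targets_per_mirna=10,
        decoy_targets_per_db=10,
        n_background_de_genes=20,
        n_indirect_response_genes=30,
        n_terms=20,
        term_size_range=(10, 20),
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def default_study():
    return simulate_all(SimulationConfig(seed=5))


def make_expr(values, conditions, batches=None, unit="count", genes=None):
    """Small ExpressionMatrix builder for hand-constructed examples."""
    values = np.asarray(values)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = [f"s{j+1}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "batch": batches if batches is not None else ["b1"] * len(samples),
        },
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta, unit)
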