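import numpy as np
import pandas as pd
import pytest

from xaratio import (
    ExpressionMatrix,
    SimulationParams,
    partition_genes,
    preimplantation_schedule,
    simulate_expression,
    simulate_timecourse,
)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 samples, handcrafted values."""
    values = pd.DataFrame(
        [[1.0, 2.0], [0.0, 0.5], [4.0, 4.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def sim_params():
    return SimulationParams(seed=20260920)


@pytest.fixture(scope="session")
def sim_expression(sim_params):
    """Expression-only dataset under the default study conditions."""
    ds = simulate_expression(sim_params, n_samples=8)
    partition = partition_genes(ds.matrix, ds.annotation)
    return ds, partition


@pytest.fixture(scope="session")
def sim_timecourse():
    """Reduced 3-stage preimplantation time-course with allelic counts."""
    params = SimulationParams(seed=42)
    ds = simulate_timecourse(params, preimplantation_schedule(n_cells_scale=0.3))
    partition = partition_genes(ds.matrix, ds.annotation)
    return ds, partition


@pytest.fixture(autouse=True)
def _quiet_small_group_warning():
    """The bootstrap warns when a filtered group is smaller than n_sample;
    that is expected throughout the synthetic single-cell runs."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="unique group size", category=UserWarning
        )
        yield


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
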