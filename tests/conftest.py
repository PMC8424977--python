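import numpy as np
import pandas as pd
import pytest

from marrms.design import AbundanceTable
from marrms.simulate import run_study, sim_I_grid, sim_II_grid

#: dataset count per setting for the simulation-study tests; large enough for
#: stable Monte-Carlo means, small enough to keep the suite fast.
N_DATASETS = 100
STUDY_SEED = 20260930


@pytest.fixture(scope="session")
def sim_I_results() -> pd.DataFrame:
    """All 24 bivariate-normal study settings scored at M=2860."""
    return run_study(
        sim_I_grid(), study="I", n_datasets=N_DATASETS,
        alpha=0.05, master_seed=STUDY_SEED,
    )


@pytest.fixture(scope="session")
def sim_II_results() -> pd.DataFrame:
    """All 12 rank-dependent-correlation study settings scored at M=2860."""
    return run_study(
        sim_II_grid(), study="II", n_datasets=N_DATASETS,
        alpha=0.05, master_seed=STUDY_SEED,
    )


def make_table(values: np.ndarray, layers: dict | None = None) -> AbundanceTable:
    """Small helper: wrap a plain array into an AbundanceTable."""
    m, n = values.shape
    features = [f"met{i + 1}" for i in range(m)]
    samples = [f"s{j + 1}" for j in range(n)]
    coords = pd.DataFrame(
        layers if layers is not None else {"replicate": samples},
        index=samples,
    )
    return AbundanceTable(
        values=pd.DataFrame(values, index=features, columns=samples),
        coordinates=coords,
    )


@pytest.fixture
def triple_layer_table() -> AbundanceTable:
    """Toy 3-operator x 3-spike-in x 3-replicate design with 30 features."""
    rng = np.random.default_rng(42)
    samples, rows = [], []
    for op in range(3):
        for sp in range(3):
            for rep in range(3):
                samples.append(f"op{op + 1}_sp{sp + 1}_r{rep + 1}")
                rows.append(
                    {
                        "operator": f"op{op + 1}",
                        "spikein": f"sp{sp + 1}",
                        "replicate": f"r{rep + 1}",
                    }
                )
    values = rng.lognormal(mean=3.0, sigma=0.5, size=(30, 27))
    return AbundanceTable(
        values=pd.DataFrame(
            values,
            index=[f"met{i + 1}" for i in range(30)],
            columns=samples,
        ),
        coordinates=pd.DataFrame(rows, index=samples),
    )
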