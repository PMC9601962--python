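import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias import datasets, pipeline


@pytest.fixture(scope="session")
def zmc_beta() -> pd.DataFrame:
    return datasets.zmc_bias_estimates()


@pytest.fixture(scope="session")
def zmc_matrix_beta() -> pd.DataFrame:
    return datasets.zmc_matrix_bias_estimates()


@pytest.fixture(scope="session")
def mock_study() -> mb.SimulatedStudy:
    """ZMC-like layout (4 protocols x 4 replicates) simulated from the
    published bias estimates at depth 1e5."""
    beta = datasets.zmc_bias_estimates()
    cfg = mb.SimulationConfig(
        truth=datasets.zymo_truth(tuple(beta.columns)),
        beta_true=beta.to_numpy(),
        taxa=tuple(beta.columns),
        depth=1e5,
        seed=3,
    )
    return mb.simulate_counts(cfg)


@pytest.fixture(scope="session")
def prepared(mock_study):
    """(clr matrix, metadata, truth clr, design) for the mock study."""
    Y, meta = pipeline.prepare_clr(mock_study.counts, mock_study.meta)
    truth = pd.Series(
        mock_study.truth.iloc[0].to_numpy() / mock_study.truth.iloc[0].sum(),
        index=Y.columns,
    )
    t_clr = pipeline.truth_clr(truth, Y.columns)
    design = mb.build_design(meta)
    design.index = Y.index
    return Y, meta, t_clr, design


@pytest.fixture(scope="session")
def null_study() -> mb.SimulatedStudy:
    """Unbiased (beta = 0) mock layout at the default depth."""
    return mb.simulate_counts(mb.SimulationConfig(seed=11))


def random_composition(rng: np.random.Generator, n: int) -> np.ndarray:
    p = rng.dirichlet(np.ones(n) * 2.0)
    return np.clip(p, 1e-9, None) / np.clip(p, 1e-9, None).sum()
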