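import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from retinotarget import SimulationConfig
from retinotarget.io import ExpressionMatrix, sample_meta_from_ids
from retinotarget import synth


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_expression(default_config):
    return synth.generate_expression(default_config)


@pytest.fixture(scope="session")
def sim_peaks(default_config):
    return synth.generate_peaks(default_config)


@pytest.fixture(scope="session")
def sim_catalog(default_config):
    return synth.generate_pathway_catalog(default_config)


def make_matrix(values: np.ndarray, gene_ids, sample_ids) -> ExpressionMatrix:
    """Small hand-built expression matrix from encoded sample IDs."""
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_meta=sample_meta_from_ids(sample_ids),
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """5 genes x 9 samples: one context, 3 doses x 3 replicates."""
    rng = np.random.default_rng(42)
    sample_ids = [f"TRC_d{d:g}_r{r}" for d in (0.0, 1.0, 5.0) for r in (1, 2, 3)]
    return make_matrix(
        rng.normal(8, 1, size=(5, 9)), [f"G{i}" for i in range(5)], sample_ids
    )
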