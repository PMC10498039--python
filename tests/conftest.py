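import numpy as np
import pandas as pd
import pytest

from gxeprot import TruthParams, generate_design, simulate_intensities


@pytest.fixture(scope="session")
def design72() -> pd.DataFrame:
    """The study layout: 12 isolines x 2 diets x 3 replicates, five 16-plexes."""
    return generate_design(12, 2, 3, 16, seed=0)


@pytest.fixture(scope="session")
def small_design() -> pd.DataFrame:
    """4 isolines x 2 diets x 2 replicates in two plexes: quick model checks."""
    return generate_design(4, 2, 2, 10, seed=0)


@pytest.fixture()
def clean_log2(design72):
    """Simulated log2 matrix with no batch/loading structure (pre-normalized)."""
    params = TruthParams(n_proteins=60, dropout=(60, 0, 0),
                         batch_sd=0.0, loading_sd=0.0)
    matrix, truth = simulate_intensities(design72, params, seed=42)
    return np.log2(matrix), truth
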