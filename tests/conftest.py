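import numpy as np
import pandas as pd
import pytest

from proteoreg import builtin_design, make_truth, simulate


@pytest.fixture(scope="session")
def design():
    return builtin_design()


@pytest.fixture(scope="session")
def clean_matrix(design):
    """Noise-free 16-variable matrix with 8 planted clusters."""
    truth = make_truth(
        n_vars=16, n_clusters=8, effect_size_range=(0.8, 2.0),
        noise_sd=0.0, missing_rate=0.0, seed=101, design=design,
    )
    return truth, simulate(design, truth, seed=102)


@pytest.fixture(scope="session")
def noisy_matrix(design):
    """Moderate-noise matrix with spots and assays and a few missing cells."""
    truth = make_truth(
        n_vars=24, n_clusters=8, effect_size_range=(0.8, 2.0),
        noise_sd=0.15, missing_rate=0.02, seed=103, design=design, n_assays=5,
    )
    return truth, simulate(design, truth, seed=104)


def series_for(matrix, var_id) -> pd.Series:
    y = matrix.data.loc[var_id].copy()
    y.index = matrix.run_ids
    return y


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
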