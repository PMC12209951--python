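import math

import numpy as np
import pandas as pd
import pytest

from scpqb import synthetic
from scpqb.report_io import AbundanceMatrix, pivot_matrix
from scpqb.synthetic import NoiseConfig


@pytest.fixture(scope="session")
def small_catalog():
    return synthetic.simulate_catalog(50, (1, 2), 3.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_cfg():
    """All noise off, everything detected: the generator's exact mean model."""
    return NoiseConfig(
        technical_cv=0.0,
        ions_per_signal=math.inf,
        background_per_pg=0.0,
        loss_bias_exponent=1.0,
        response_exponent_sd=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def noise_free_report(small_catalog, noise_free_cfg):
    return synthetic.simulate_dilution_series(
        small_catalog, [10, 20, 40, 50, 100], replicates=2, cfg=noise_free_cfg
    )


@pytest.fixture(scope="session")
def noise_free_matrix(noise_free_report):
    return pivot_matrix(noise_free_report, quant_level="MS1")


@pytest.fixture()
def toy_matrix():
    """4 peptides x 4 runs (two loads x two replicates) with one missing cell."""
    values = pd.DataFrame(
        {
            "a_r1": [100.0, 200.0, 50.0, 10.0],
            "a_r2": [110.0, 190.0, np.nan, 12.0],
            "b_r1": [210.0, 390.0, 100.0, 18.0],
            "b_r2": [190.0, 410.0, 105.0, 22.0],
        },
        index=["pep1", "pep2", "pep3", "pep4"],
    )
    meta = pd.DataFrame(
        {
            "load_pg": [50.0, 50.0, 100.0, 100.0],
            "replicate": [1, 2, 1, 2],
        },
        index=values.columns,
    )
    return AbundanceMatrix(values, meta)
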