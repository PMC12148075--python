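import numpy as np
import pytest

from mlrabm import DonorPhenotype, ModelParameters, SimulationConfig


@pytest.fixture
def donor() -> DonorPhenotype:
    return DonorPhenotype(
        donor_id="D1",
        pct_pd1_cd4=30.0,
        pct_pd1_cd8=25.0,
        geo_mean_pd1=5.0,
        pct_pdl1_mono=8.0,
        geo_mean_pdl1=3.0,
        mlr_days=4,
    )


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def small_config(donor) -> SimulationConfig:
    """A desk-scale well small enough for sub-second runs."""
    return SimulationConfig(
        donor=donor,
        seed=7,
        n_tcells=60,
        n_monocytes=100,
        volume_scale=0.001,
        duration_h=24.0,
        readout_times_h=[24.0],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
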