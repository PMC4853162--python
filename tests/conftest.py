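import numpy as np
import pandas as pd
import pytest

from ambientgxe.config import ExposureConfig, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exposure_cfg():
    return ExposureConfig()


@pytest.fixture
def small_sim():
    """A fast, small cohort configuration for unit tests."""
    return SimConfig(n_cases=120, n_controls=130, seed=42)


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale pipeline run, shared across tests."""
    from ambientgxe.pipeline import run_pipeline

    manifest, tables = run_pipeline(SimConfig(seed=7), ExposureConfig())
    return manifest, tables


def make_applications(rows):
    """Small applications frame from (pesticide, class, year, x, y, lb, ac)."""
    return pd.DataFrame(
        rows,
        columns=[
            "pesticide_id",
            "chemical_class",
            "year",
            "x_m",
            "y_m",
            "pounds",
            "acres",
        ],
    )
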