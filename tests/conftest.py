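import warnings

import numpy as np
import pandas as pd
import pytest

from qstorm import QuenchModel
from qstorm.scene import make_scene

# scipy optimizers warn about unreliable covariance on individual noisy
# profile fits; the metrics aggregate over many fits so this is expected
warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def cy3b_model() -> QuenchModel:
    """Monolayer-GO quenching model for Cy3B emission."""
    return QuenchModel(a=2.6e-8, wavelength_nm=570.0)


@pytest.fixture(scope="session")
def fibre_scene():
    """Six smooth fibres over a half-field GO flake, 4x4 um."""
    return make_scene("fibres_over_flake", seed=5, field_nm=4000.0, n_fibres=6)


@pytest.fixture()
def small_table() -> pd.DataFrame:
    """Five bright localizations in a 1x1 um field."""
    return pd.DataFrame(
        {
            "frame": [1, 2, 3, 4, 5],
            "x_nm": [100.0, 200.0, 300.0, 400.0, 500.0],
            "y_nm": [100.0, 150.0, 200.0, 250.0, 300.0],
            "sigma_nm": 150.0,
            "photons": 1000.0,
            "uncertainty_nm": 8.0,
        }
    )


def assert_tables_equal(a: pd.DataFrame, b: pd.DataFrame) -> None:
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
    )
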