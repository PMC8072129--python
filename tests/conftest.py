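import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_table():
    """Ten patients, one analyte, some missing values and labels."""
    return pd.DataFrame({
        "sex": [0, 1, 1, 0, 1, 0, 0, 1, 1, 0],
        "age": [25, 40, 33, 61, 55, 47, 29, 70, 35, 50],
        "fld": [0, 1, np.nan, 0, 1, np.nan, 0, 1, np.nan, 0],
        "TG": [1.1, 2.4, np.nan, 1.0, 3.1, 1.2, np.nan, 2.8, 1.5, 0.9],
    })


@pytest.fixture
def labelled_cohort():
    """A small fully labelled cohort with planted class separation."""
    rng = np.random.default_rng(42)
    n = 400
    y = (rng.random(n) < 0.3).astype(float)
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n),
        "age": rng.integers(20, 80, n).astype(float),
        "fld": y,
        "TG": np.exp(0.3 + 0.8 * y + 0.4 * rng.standard_normal(n)),
        "ALT": np.exp(3.0 + 0.6 * y + 0.5 * rng.standard_normal(n)),
        "noiseA": rng.lognormal(1.0, 0.5, n),
        "noiseB": rng.lognormal(2.0, 0.3, n),
    })
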