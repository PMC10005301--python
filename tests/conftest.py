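import numpy as np
import pandas as pd
import pytest

from chromlogd import datasets

#: published univariate calibration lines (compounds 1-14):
#: pH -> (slope, se_slope, intercept, se_intercept, adjusted R2)
UNIVARIATE_PUBLISHED = {
    7.0: (1.13, 0.14, -0.44, 0.23, 0.825),
    8.0: (1.02, 0.07, -0.21, 0.12, 0.943),
    9.0: (1.01, 0.05, -0.22, 0.09, 0.968),
    10.0: (1.01, 0.05, -0.26, 0.09, 0.969),
}

PH_GRID = (7.0, 8.0, 9.0, 10.0)


@pytest.fixture(scope="session")
def compounds():
    return datasets.load_compounds()


@pytest.fixture(scope="session")
def model_compounds(compounds):
    return [c for c in compounds if c.role == "model"]


@pytest.fixture(scope="session")
def verification_compounds(compounds):
    return [c for c in compounds if c.role == "verification"]


@pytest.fixture(scope="session")
def logkw_matrix():
    return datasets.load_logkw()


@pytest.fixture(scope="session")
def logd_published():
    return datasets.load_logd()


@pytest.fixture(scope="session")
def validation_table():
    return datasets.load_validation_table()


@pytest.fixture(scope="session")
def univariate_design(logkw_matrix, logd_published):
    """Per-pH (y, X) for the 14-compound univariate calibration."""
    ids = [str(i) for i in range(1, 15)]
    out = {}
    for ph in PH_GRID:
        y = logd_published.loc[ids, ph].to_numpy()
        X = pd.DataFrame({"logkw": logkw_matrix.loc[ids, ph].to_numpy()}, index=ids)
        out[ph] = (y, X)
    return out
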